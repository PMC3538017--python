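"""Low-level DNA string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: IUPAC ambiguity codes mapped to the set of unambiguous bases they cover.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, alphabet: str = "ACGTN") -> str:
    """Upper-case ``seq`` and raise ``ValueError`` naming the first offending
    position if any character falls outside ``alphabet``."""
    seq = seq.upper()
    allowed = set(alphabet)
    for i, c in enumerate(seq):
        if c not in allowed:
            raise ValueError(f"invalid base {c!r} at position {i}")
    return seq


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True if two IUPAC codes can denote the same unambiguous base."""
    try:
        return bool(IUPAC[primer_base] & IUPAC[template_base])
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None
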