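"""Microsatellite (SSR) mining from EST sequences.

Detects exact tandem repeats of di-, tri- and tetranucleotide units in
transcript sequences, pools motifs into strand/rotation-invariant canonical
classes, and turns repeat loci with adequate flanking sequence into named
candidate PCR markers (fragment-length polymorphism markers whose primers
would sit in the flanks).

Scanning semantics: for each unit length independently, the sequence is
scanned left to right and the first qualifying maximal run is reported, after
which scanning resumes past its end ("leftmost-greedy").  A unit must be
primitive — not itself a tandem repeat of a shorter unit — so homopolymer
runs and e.g. (AT)x2 disguised as a tetranucleotide are never reported.
Runs containing N are never reported: an ambiguous base cannot confirm a
repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import revcomp, validate_dna

#: Minimum tandem-repeat counts per unit length (di/tri/tetra).
DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 5}

DEFAULT_FLANK_LEN = 150
DEFAULT_MIN_FLANK = 50


@dataclass(frozen=True)
class ESTRecord:
    """One expressed sequence tag: an id and a DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("EST id must be non-empty")
        if not self.sequence:
            raise ValueError(f"EST {self.id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class SSRLocus:
    """A detected tandem repeat inside one EST.

    ``start``/``end`` are 0-based half-open offsets; the substring
    ``seq[start:end]`` is exactly ``unit * repeat_count``.
    """

    unit: str
    canonical_class: str
    repeat_count: int
    start: int
    end: int
    est_id: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.unit) * self.repeat_count:
            raise ValueError("locus span inconsistent with unit x repeat_count")


@dataclass(frozen=True)
class CandidateMarker:
    """A flank-anchored SSR marker candidate.

    ``primers`` is a pass-through slot for externally designed primer pairs;
    primer design itself (Tm/GC optimisation) is out of scope here.
    """

    name: str
    est_id: str
    locus: SSRLocus
    left_flank: str
    right_flank: str
    primers: tuple[str, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError(f"marker {self.name!r}: flanks must be non-empty")


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_ssrs(seq: str,
              min_repeats: Mapping[int, int] | None = None) -> list[SSRLocus]:
    """Find qualifying SSR loci in ``seq``.

    Parameters
    ----------
    seq : DNA string over {A,C,G,T,N}; case-insensitive.
    min_repeats : minimum repeat count per unit length, default
        ``{2: 6, 3: 5, 4: 5}``.

    Returns loci sorted by start position (then end, then unit length).
    An empty sequence yields an empty list; characters outside the alphabet
    raise ``ValueError`` naming the offending position.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    if not seq:
        return []
    seq = validate_dna(seq, "ACGTN")
    n = len(seq)
    loci: list[SSRLocus] = []
    for unit_len, min_r in sorted(min_repeats.items()):
        i = 0
        while i + unit_len * min_r <= n:
            unit = seq[i:i + unit_len]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            k = 1
            while seq[i + k * unit_len:i + (k + 1) * unit_len] == unit:
                k += 1
            if k >= min_r:
                loci.append(SSRLocus(unit=unit,
                                     canonical_class=canonical_motif_class(unit),
                                     repeat_count=k,
                                     start=i, end=i + k * unit_len))
                i += k * unit_len
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, l.end, len(l.unit)))
    return loci


def canonical_motif_class(unit: str) -> str:
    """Canonical representative of an SSR motif class.

    Motif classes pool all rotations of a unit together with all rotations of
    its reverse complement (e.g. GAA, AGA, CTT all belong to class AAG, the
    lexicographically smallest member).  Idempotent by construction.
    """
    unit = validate_dna(unit, "ACGT")
    if not 2 <= len(unit) <= 4:
        raise ValueError(f"unit length must be 2-4, got {len(unit)}")
    rc = revcomp(unit)
    candidates = [unit[i:] + unit[:i] for i in range(len(unit))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def _dedup_key(left: str, right: str) -> tuple[str, str]:
    # A marker read on the opposite strand has flanks (revcomp(right), revcomp(left)).
    return min((left, right), (revcomp(right), revcomp(left)))


def build_markers(ests: Iterable[ESTRecord],
                  min_repeats: Mapping[int, int] | None = None,
                  flank_len: int = DEFAULT_FLANK_LEN,
                  min_flank: int = DEFAULT_MIN_FLANK) -> list[CandidateMarker]:
    """Mine all ESTs and emit non-redundant, flank-anchored candidate markers.

    A locus is retained only if both flanks reach ``min_flank`` bp (flanks are
    truncated to ``flank_len``).  Redundancy removal keeps the first marker in
    input order among any set whose flank pair is identical, directly or after
    reverse complement.  Names are ``CaES`` + zero-padded ordinal, assigned in
    input order to the retained markers.
    """
    if not flank_len >= min_flank >= 1:
        raise ValueError("require flank_len >= min_flank >= 1")
    seen: set[tuple[str, str]] = set()
    markers: list[CandidateMarker] = []
    for est in ests:
        seq = validate_dna(est.sequence, "ACGTN")
        for locus in find_ssrs(seq, min_repeats):
            left = seq[max(0, locus.start - flank_len):locus.start]
            right = seq[locus.end:locus.end + flank_len]
            if len(left) < min_flank or len(right) < min_flank:
                continue
            key = _dedup_key(left, right)
            if key in seen:
                continue
            seen.add(key)
            markers.append(CandidateMarker(
                name=f"CaES{len(markers) + 1:04d}",
                est_id=est.id,
                locus=replace(locus, est_id=est.id),
                left_flank=left,
                right_flank=right,
            ))
    return markers


def motif_summary(markers: Sequence[CandidateMarker]) -> pd.DataFrame:
    """Tabulate marker counts per (unit length, canonical motif class).

    Percentages are of the total marker count, so the unit-length shares
    obtained by summing within each unit length add up to 100.
    Empty input yields an empty table.
    """
    cols = ["unit_length", "canonical_class", "count", "percent"]
    if not markers:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame({
        "unit_length": [len(m.locus.unit) for m in markers],
        "canonical_class": [m.locus.canonical_class for m in markers],
    })
    out = (df.value_counts(["unit_length", "canonical_class"])
             .rename("count").reset_index()
             .sort_values(["unit_length", "canonical_class"])
             .reset_index(drop=True))
    out["percent"] = 100.0 * out["count"] / len(markers)
    return out[cols]


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> list[ESTRecord]:
    """Read a multi-FASTA (wrapped or unwrapped; case-insensitive)."""
    return [ESTRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def markers_to_frame(markers: Sequence[CandidateMarker]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": m.name, "est_id": m.est_id, "unit": m.locus.unit,
        "canonical_class": m.locus.canonical_class,
        "repeat_count": m.locus.repeat_count,
        "start": m.locus.start, "end": m.locus.end,
        "left_flank": m.left_flank, "right_flank": m.right_flank,
    } for m in markers], columns=["name", "est_id", "unit", "canonical_class",
                                  "repeat_count", "start", "end",
                                  "left_flank", "right_flank"])
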