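"""Plastid DNA barcoding: in-silico PCR, SNP haplotypes, cytonuclear checks.

The two standard plant barcode loci, chloroplast matK and rbcL, are
amplified in silico with the universal barcode primer pairs.  The amplicon
insert (primer sequences excluded) is read at configured SNP sites and the
bases are concatenated into a haplotype string; in Capsicum three sites are
informative — matK positions 129 (C/A) and 312 (T/C) and rbcL position 392
(A/G) — giving haplotypes such as "CTA".  SNP positions are 1-based indices
within the primer-excluded insert.

Because plastids are maternally inherited, a line whose haplotype does not
match its nuclear cluster's expected haplotype set points to an
interspecific hybridization with the plastid donor as the maternal parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._seq import iupac_match, revcomp, validate_dna

IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers, both written 5'->3' on their own strands."""

    gene: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if not p:
                raise ValueError("primers must be non-empty")
            validate_dna(p, IUPAC_ALPHABET)


#: Universal plant-barcode primer pairs.
MATK_PRIMERS = PrimerPair("matK", "CGTACAGTACTTTTGTGTTTACGAG",
                          "ACCCAGTCCATCTGGAAATCTTGGTTC")
RBCL_PRIMERS = PrimerPair("rbcL", "ATGTCACCACAAACAGAGACTAAAGC",
                          "GTAAAATCAAGTCCACCRCG")


@dataclass(frozen=True)
class SNPSite:
    """A scored SNP: 1-based position within the primer-excluded insert."""

    gene: str
    position: int
    alleles: frozenset[str]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("site position is 1-based (>= 1)")
        if not set(self.alleles) <= set("ACGT"):
            raise ValueError("site alleles must be unambiguous bases")


#: The three informative Capsicum plastid SNP sites, in reporting order.
DEFAULT_SITES = (SNPSite("matK", 129, frozenset("CA")),
                 SNPSite("matK", 312, frozenset("TC")),
                 SNPSite("rbcL", 392, frozenset("AG")))


@dataclass(frozen=True)
class AmpliconResult:
    """Outcome of one in-silico PCR.

    ``status`` is "ok", "no amplification" or "multiple products";
    ``products`` lists (start, end) template coordinates of each full
    product (primers included, 0-based half-open)."""

    status: str
    insert: str | None
    products: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class HaplotypeCall:
    """Joint base string over the ordered SNP sites, e.g. "CTA".

    ``novel_sites`` names sites whose observed base falls outside the
    expected allele set (the call is flagged, not rejected)."""

    line: str
    haplotype: str
    novel_sites: tuple[str, ...] = ()

    @property
    def is_novel(self) -> bool:
        return bool(self.novel_sites)


def _primer_matches(template: str, primer: str, max_mismatch: int) -> list[int]:
    hits = []
    plen = len(primer)
    for i in range(len(template) - plen + 1):
        mismatches = 0
        for p, t in zip(primer, template[i:i + plen]):
            if not iupac_match(p, t):
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def in_silico_pcr(template: str, primers: PrimerPair,
                  max_mismatch: int = 0) -> AmpliconResult:
    """Amplify ``template`` with a primer pair and return the insert.

    The forward primer is matched on the given strand and the reverse primer
    as its reverse complement downstream; IUPAC degeneracy is honoured on
    both sides (R matches A or G, etc.).  The insert excludes both primer
    sequences.  Zero products give status "no amplification", more than one
    "multiple products" (with all product coordinates).
    """
    template = validate_dna(template, IUPAC_ALPHABET)
    fwd_sites = _primer_matches(template, primers.forward, max_mismatch)
    rev_sites = _primer_matches(template, revcomp(primers.reverse), max_mismatch)
    products = []
    for f in fwd_sites:
        insert_start = f + len(primers.forward)
        for r in rev_sites:
            if r >= insert_start:
                products.append((f, r + len(primers.reverse)))
    if not products:
        return AmpliconResult("no amplification", None, ())
    if len(products) > 1:
        return AmpliconResult("multiple products", None, tuple(products))
    f, end = products[0]
    insert = template[f + len(primers.forward):end - len(primers.reverse)]
    return AmpliconResult("ok", insert, tuple(products))


def call_haplotype(matk_insert: str, rbcl_insert: str,
                   sites: Sequence[SNPSite] = DEFAULT_SITES,
                   line: str = "") -> HaplotypeCall:
    """Read the configured SNP sites and concatenate their bases.

    The output order is fixed — matK sites by ascending position, then rbcL
    sites — regardless of the order of ``sites``.  An insert shorter than a
    site's position raises ``ValueError`` naming the site.
    """
    ordered = sorted(sites, key=lambda s: ({"matK": 0, "rbcL": 1}.get(s.gene, 2),
                                           s.position))
    by_gene = {"matK": matk_insert.upper(), "rbcL": rbcl_insert.upper()}
    bases, novel = [], []
    for site in ordered:
        insert = by_gene.get(site.gene)
        if insert is None:
            raise ValueError(f"no insert supplied for gene {site.gene!r}")
        if len(insert) < site.position:
            raise ValueError(
                f"insert too short for site {site.gene}{site.position}: "
                f"{len(insert)} bp")
        base = insert[site.position - 1]
        bases.append(base)
        if base not in site.alleles:
            novel.append(f"{site.gene}{site.position}")
    return HaplotypeCall(line=line, haplotype="".join(bases),
                         novel_sites=tuple(novel))


def haplotype_cluster_contingency(calls: Mapping[str, HaplotypeCall | str],
                                  clusters: Mapping[str, str]) -> pd.DataFrame:
    """Counts of lines per (haplotype, cluster); marginals conserve lines."""
    records = []
    for line, call in calls.items():
        hap = call.haplotype if isinstance(call, HaplotypeCall) else str(call)
        records.append({"haplotype": hap, "cluster": clusters[line]})
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame(records)
    return pd.crosstab(df["haplotype"], df["cluster"])


def flag_cytonuclear_mismatch(clusters: Mapping[str, str],
                              calls: Mapping[str, HaplotypeCall | str],
                              expected: Mapping[str, set[str]] | None = None
                              ) -> list[str]:
    """Lines whose plastid haplotype conflicts with their nuclear cluster.

    ``expected`` maps cluster -> accepted haplotype set; when omitted it is
    learned as each cluster's majority haplotype (ties broken
    lexicographically).  Returns the flagged line names, sorted.
    """
    haps = {line: (c.haplotype if isinstance(c, HaplotypeCall) else str(c))
            for line, c in calls.items()}
    if expected is None:
        expected = {}
        for cluster in sorted(set(clusters[ln] for ln in haps)):
            counts: dict[str, int] = {}
            for ln in haps:
                if clusters[ln] == cluster:
                    counts[haps[ln]] = counts.get(haps[ln], 0) + 1
            top = max(counts.values())
            expected[cluster] = {min(h for h, v in counts.items() if v == top)}
    return sorted(ln for ln, hap in haps.items()
                  if hap not in expected.get(clusters[ln], set()))
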