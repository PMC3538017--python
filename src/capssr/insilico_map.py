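"""Marker placement on a reference genome from translated-similarity hits.

Consumes the common 12-column tabular hit format (query, subject, identity,
alignment length, mismatches, gap opens, q.start, q.end, s.start, s.end,
E-value, bit score), filters hits at an E-value cutoff, derives one map
position per marker from its best hit, and selects an evenly spaced marker
panel per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_EMAX = 1e-50

HIT_COLUMNS = ["query_id", "subject_id", "identity", "aln_length", "mismatches",
               "gap_opens", "q_start", "q_end", "s_start", "s_end",
               "e_value", "bit_score"]


@dataclass(frozen=True)
class SimilarityHit:
    """One tabular hit. ``s_start`` may exceed ``s_end`` on the minus strand."""

    query_id: str
    subject_id: str
    e_value: float
    s_start: int
    s_end: int

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")
        if self.s_start < 1 or self.s_end < 1:
            raise ValueError("subject coordinates are 1-based (>= 1)")

    @property
    def span(self) -> int:
        return abs(self.s_end - self.s_start) + 1


@dataclass(frozen=True)
class Placement:
    """A marker's single map position: the midpoint of its best hit."""

    marker: str
    chrom: str
    position: float


def read_hits_tsv(path: str | Path) -> list[SimilarityHit]:
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                     comment="#")
    return [SimilarityHit(query_id=str(r.query_id), subject_id=str(r.subject_id),
                          e_value=float(r.e_value),
                          s_start=int(r.s_start), s_end=int(r.s_end))
            for r in df.itertuples(index=False)]


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "length"], comment="#")
    return {str(r.chrom): int(r.length) for r in df.itertuples(index=False)}


def filter_significant(hits: Iterable[SimilarityHit],
                       emax: float = DEFAULT_EMAX) -> list[SimilarityHit]:
    """Keep exactly the hits with E-value strictly below ``emax``, in order."""
    if not emax > 0:
        raise ValueError("emax must be positive")
    return [h for h in hits if h.e_value < emax]


def place_markers(hits: Iterable[SimilarityHit],
                  report_secondary: bool = False):
    """One placement per query: the midpoint of its best (lowest-E) hit.

    Ties on E-value are broken by larger alignment span, then lexicographic
    (subject_id, s_start).  The midpoint is orientation-free, so strand is
    collapsed.  With ``report_secondary`` a second list of the non-best hits
    is also returned.
    """
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    placements, secondary = [], []
    for query, group in by_query.items():
        best = min(group, key=lambda h: (h.e_value, -h.span, h.subject_id, h.s_start))
        placements.append(Placement(marker=query, chrom=best.subject_id,
                                    position=(best.s_start + best.s_end) / 2.0))
        secondary.extend(h for h in group if h is not best)
    if report_secondary:
        return placements, secondary
    return placements


def select_uniform_panel(placements: Sequence[Placement],
                         chrom_lengths: Mapping[str, int],
                         k: int = 8) -> dict[str, list[dict]]:
    """Select up to ``k`` markers per chromosome at constant intervals.

    For a chromosome of length L the target grid is t_i = (i - 0.5) * L / k,
    i = 1..k.  In grid order, each target greedily takes the nearest
    still-unassigned placement (ties: smaller position, then marker name).
    Chromosomes with fewer than k placements contribute all of them.

    Returns chrom -> list of rows with keys
    ``grid_index, target_bp, marker, position``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        if p.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {p.chrom!r} in placements")
        by_chrom.setdefault(p.chrom, []).append(p)
    panel: dict[str, list[dict]] = {}
    for chrom in sorted(by_chrom):
        length = chrom_lengths[chrom]
        available = sorted(by_chrom[chrom], key=lambda p: (p.position, p.marker))
        rows = []
        for i in range(1, k + 1):
            if not available:
                break
            target = (i - 0.5) * length / k
            chosen = min(available,
                         key=lambda p: (abs(p.position - target), p.position, p.marker))
            available.remove(chosen)
            rows.append({"grid_index": i, "target_bp": target,
                         "marker": chosen.marker, "position": chosen.position})
        panel[chrom] = rows
    return panel


def placements_to_frame(placements: Sequence[Placement]) -> pd.DataFrame:
    return pd.DataFrame([{"marker": p.marker, "chrom": p.chrom,
                          "position": p.position} for p in placements],
                        columns=["marker", "chrom", "position"])


def panel_to_frame(panel: Mapping[str, Sequence[dict]]) -> pd.DataFrame:
    rows = [{"chrom": chrom, **row} for chrom in panel for row in panel[chrom]]
    return pd.DataFrame(rows, columns=["chrom", "grid_index", "target_bp",
                                       "marker", "position"])
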