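"""Fragment-analysis genotype matrices: marker typing and diversity statistics.

A genotype call for one line at one marker is either an allele set of one or
two fragment sizes (a marker is assumed to amplify a single locus, so two
fragments = a heterozygote), NULL (no amplification — the null allele), or
MULTIBAND (more than two fragments, which voids the marker).

Markers are classified into four types:

* I   codominant polymorphic — polymorphic fragments, no nulls
* II  codominant + dominant  — polymorphic fragments plus null alleles
* III monomorphic            — one fragment size everywhere, no nulls
* IV  dominant polymorphic   — one fragment size, presence/absence
* na  excluded               — any MULTIBAND call, or no amplification at all

Expected heterozygosity per marker is HZ = 1 - sum_i p_i^2 over the allele
frequencies p_i; heterozygous lines contribute half a weight to each of
their two alleles, and NULL/MULTIBAND lines are excluded from the
denominator (HZ is a statistic of the fragment alleles of the codominant
markers).  Setting ``null_as_allele=True`` in :func:`allele_frequencies`
instead counts NULL as one extra allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: No amplification (the null allele).
NULL = _Sentinel("NULL")
#: More than two fragments; voids the whole marker.
MULTIBAND = _Sentinel("MULTIBAND")

MARKER_TYPES = ("I", "II", "III", "IV", "na")

Call = object  # tuple of 1-2 allele values | NULL | MULTIBAND


def make_call(*alleles) -> tuple:
    """Build an allele-set call from one or two fragment sizes (or haplotype
    strings), sorted and deduplicated."""
    values = tuple(sorted(set(alleles), key=lambda v: (str(type(v)), v)))
    if not 1 <= len(values) <= 2:
        raise ValueError("an allele set holds one or two values")
    return values


@dataclass
class GenotypeTable:
    """Lines x markers matrix of genotype calls.

    ``calls[line][marker]`` is a tuple of allele values, NULL, or MULTIBAND.
    Allele values are fragment sizes in bp (int) or haplotype strings.
    """

    lines: list[str]
    markers: list[str]
    calls: dict[str, dict[str, Call]]

    def __post_init__(self) -> None:
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("duplicate line names")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")

    def column(self, marker: str) -> list[Call]:
        return [self.calls[line][marker] for line in self.lines]

    def call(self, line: str, marker: str) -> Call:
        return self.calls[line][marker]

    def subset_markers(self, markers: Sequence[str]) -> "GenotypeTable":
        keep = [m for m in self.markers if m in set(markers)]
        return GenotypeTable(
            lines=list(self.lines), markers=keep,
            calls={ln: {m: self.calls[ln][m] for m in keep} for ln in self.lines})

    def with_marker(self, marker: str, column: Mapping[str, Call]) -> "GenotypeTable":
        """Return a copy with one extra marker column (e.g. a plastid
        haplotype genotype)."""
        calls = {ln: dict(self.calls[ln]) for ln in self.lines}
        for ln in self.lines:
            calls[ln][marker] = column[ln]
        return GenotypeTable(lines=list(self.lines),
                             markers=list(self.markers) + [marker], calls=calls)

    # -- text round-trip ----------------------------------------------------

    def to_frame(self, null_token: str = "-", multiband_token: str = "*",
                 allele_sep: str = "/") -> pd.DataFrame:
        def fmt(call: Call) -> str:
            if call is NULL:
                return null_token
            if call is MULTIBAND:
                return multiband_token
            return allele_sep.join(str(a) for a in call)

        data = {m: [fmt(self.calls[ln][m]) for ln in self.lines]
                for m in self.markers}
        return pd.DataFrame(data, index=pd.Index(self.lines, name="line"))

    def to_tsv(self, path: str | Path, **tokens) -> None:
        self.to_frame(**tokens).to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, null_token: str = "-",
                   multiband_token: str = "*",
                   allele_sep: str = "/") -> "GenotypeTable":
        def parse(cell: str) -> Call:
            cell = str(cell).strip()
            if cell == null_token:
                return NULL
            if cell == multiband_token:
                return MULTIBAND
            parts = cell.split(allele_sep)
            try:
                values = [int(p) for p in parts]
            except ValueError:
                values = parts
            return make_call(*values)

        lines = [str(i) for i in df.index]
        markers = [str(c) for c in df.columns]
        calls = {ln: {m: parse(df.at[idx, col])
                      for m, col in zip(markers, df.columns)}
                 for ln, idx in zip(lines, df.index)}
        return cls(lines=lines, markers=markers, calls=calls)

    @classmethod
    def from_tsv(cls, path: str | Path, **tokens) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
        return cls.from_frame(df, **tokens)


@dataclass(frozen=True)
class MarkerProfile:
    marker: str
    type: str
    alleles: tuple
    p: tuple[float, ...]
    HZ: float
    null_count: int

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def classify_marker_type(column: Sequence[Call]) -> str:
    """Assign one of {I, II, III, IV, na} to a marker column."""
    if len(column) == 0:
        raise ValueError("empty marker column")
    if any(c is MULTIBAND for c in column):
        return "na"
    informative = [c for c in column if c is not NULL]
    if not informative:
        return "na"
    distinct = {a for call in informative for a in call}
    poly = len(distinct) >= 2
    nulls = len(informative) < len(column)
    if poly:
        return "II" if nulls else "I"
    return "IV" if nulls else "III"


def allele_frequencies(column: Sequence[Call],
                       null_as_allele: bool = False) -> pd.Series:
    """Allele frequencies for one marker column.

    Each fragment size in a call contributes weight 1/|allele set| for its
    line; by default NULL and MULTIBAND lines are excluded from the
    denominator.  With ``null_as_allele`` NULL counts as one extra allele
    (weight 1, labelled ``"null"``).
    """
    weights: dict = {}
    n_lines = 0
    for call in column:
        if call is MULTIBAND:
            continue
        if call is NULL:
            if null_as_allele:
                weights["null"] = weights.get("null", 0.0) + 1.0
                n_lines += 1
            continue
        n_lines += 1
        w = 1.0 / len(call)
        for a in call:
            weights[a] = weights.get(a, 0.0) + w
    if n_lines == 0:
        raise ValueError("no alleles: column has no scorable calls")
    alleles = sorted(weights, key=lambda a: (str(type(a)), a))
    p = pd.Series([weights[a] / n_lines for a in alleles], index=alleles,
                  dtype=float, name="p")
    return p


def expected_heterozygosity(p: Sequence[float]) -> float:
    """HZ = 1 - sum(p_i^2) for a probability vector p."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0 or abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - np.sum(arr ** 2))


def profile_markers(table: GenotypeTable) -> tuple[list[MarkerProfile], dict]:
    """Profile every marker and summarise over the conventional type subsets.

    The summary reports counts per type, the mean allele number and mean HZ
    over the codominant polymorphic markers (types I and II), and the mean
    null-allele count over the dominant markers (types II and IV).  ``na``
    markers are excluded from all summaries.
    """
    profiles: list[MarkerProfile] = []
    for marker in table.markers:
        col = table.column(marker)
        mtype = classify_marker_type(col)
        null_count = sum(1 for c in col if c is NULL)
        if mtype == "na":
            profiles.append(MarkerProfile(marker, "na", (), (), float("nan"),
                                          null_count))
            continue
        p = allele_frequencies(col)
        profiles.append(MarkerProfile(
            marker=marker, type=mtype, alleles=tuple(p.index),
            p=tuple(float(x) for x in p.to_numpy()),
            HZ=expected_heterozygosity(p.to_numpy()), null_count=null_count))

    counts = {t: sum(1 for pr in profiles if pr.type == t) for t in MARKER_TYPES}
    codominant = [pr for pr in profiles if pr.type in ("I", "II")]
    dominant = [pr for pr in profiles if pr.type in ("II", "IV")]
    summary = {
        "counts_per_type": counts,
        "mean_alleles_codominant": (float(np.mean([pr.n_alleles for pr in codominant]))
                                    if codominant else float("nan")),
        "mean_HZ_codominant": (float(np.mean([pr.HZ for pr in codominant]))
                               if codominant else float("nan")),
        "mean_null_dominant": (float(np.mean([pr.null_count for pr in dominant]))
                               if dominant else float("nan")),
    }
    return profiles, summary


def profiles_to_frame(profiles: Iterable[MarkerProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "marker": pr.marker, "type": pr.type, "n_alleles": pr.n_alleles,
        "HZ": pr.HZ, "null_count": pr.null_count,
    } for pr in profiles], columns=["marker", "type", "n_alleles", "HZ",
                                    "null_count"])
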