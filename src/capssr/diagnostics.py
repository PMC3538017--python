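"""Cluster-diagnostic genotypes: frequency tables, specificity, classification.

A genotype here is a (marker, value) pair — a fragment size in bp, or a
plastid haplotype state such as matK "AC".  Its frequency in a cluster is
the percentage of the cluster's lines that carry the value (a heterozygous
line carries both of its values).  A genotype is diagnostic for a cluster
when it is frequent there (>= theta_in) and rare in every other cluster
(< theta_out); unknown lines can then be classified by majority vote over
the diagnostic genotypes they carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genotype_typing import GenotypeTable, MULTIBAND, NULL

DEFAULT_THETA_IN = 0.80
DEFAULT_THETA_OUT = 0.15


@dataclass(frozen=True)
class DiagnosticGenotype:
    marker: str
    genotype: object
    cluster: str
    in_pct: float
    max_out_pct: float


def genotype_frequencies(table: GenotypeTable,
                         clusters: Mapping[str, str],
                         markers: Sequence[str] | None = None,
                         labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-cluster carrier percentages for every observed (marker, value).

    Lines assigned to cluster "N" (not classifiable) are excluded.  Returns a
    wide table indexed by (marker, genotype) with one percentage column per
    cluster.  ``labels`` fixes the cluster columns explicitly (default: the
    labels observed among the lines); an empty cluster raises ``ValueError``
    naming it.
    """
    if markers is None:
        markers = table.markers
    if labels is None:
        labels = sorted({clusters[ln] for ln in table.lines} - {"N"})
    else:
        labels = sorted(set(labels) - {"N"})
    members = {lbl: [ln for ln in table.lines if clusters[ln] == lbl]
               for lbl in labels}
    for lbl, lines in members.items():
        if not lines:
            raise ValueError(f"cluster {lbl!r} is empty")
    rows: dict[tuple, dict[str, float]] = {}
    for marker in markers:
        values: set = set()
        for ln in table.lines:
            call = table.call(ln, marker)
            if call is not NULL and call is not MULTIBAND:
                values.update(call)
        for value in sorted(values, key=lambda v: (str(type(v)), v)):
            freq = {}
            for lbl in labels:
                carriers = sum(
                    1 for ln in members[lbl]
                    if (call := table.call(ln, marker)) is not NULL
                    and call is not MULTIBAND and value in call)
                freq[lbl] = 100.0 * carriers / len(members[lbl])
            rows[(marker, value)] = freq
    out = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    out.index = pd.MultiIndex.from_tuples(rows.keys(), names=["marker", "genotype"]) \
        if rows else pd.MultiIndex.from_tuples([], names=["marker", "genotype"])
    return out


def find_cluster_specific(freqs: pd.DataFrame,
                          theta_in: float = DEFAULT_THETA_IN,
                          theta_out: float = DEFAULT_THETA_OUT
                          ) -> list[DiagnosticGenotype]:
    """Flag genotypes frequent in one cluster and rare in all others.

    ``freqs`` is a wide percentage table as produced by
    :func:`genotype_frequencies` (index (marker, genotype), one column per
    cluster).  A (marker, genotype) is diagnostic for cluster X iff its
    frequency in X is >= ``theta_in * 100`` and its frequency in every other
    cluster is < ``theta_out * 100``.  With ``theta_in > 0.5`` a genotype can
    be diagnostic for at most one cluster.
    """
    if not 0 < theta_out < theta_in <= 1:
        raise ValueError("require 0 < theta_out < theta_in <= 1")
    found: list[DiagnosticGenotype] = []
    for (marker, genotype), row in freqs.iterrows():
        for cluster in freqs.columns:
            others = row.drop(cluster)
            if row[cluster] >= theta_in * 100 and (others < theta_out * 100).all():
                found.append(DiagnosticGenotype(
                    marker=marker, genotype=genotype, cluster=cluster,
                    in_pct=float(row[cluster]),
                    max_out_pct=float(others.max()) if len(others) else 0.0))
    return found


def classify_by_diagnostics(line_calls: Mapping[str, object],
                            diagnostics: Sequence[DiagnosticGenotype]
                            ) -> tuple[str, dict[str, int]]:
    """Vote-based cluster prediction for one line.

    ``line_calls`` maps marker -> genotype call (allele tuple, NULL or
    MULTIBAND).  Each diagnostic genotype the line carries casts one vote for
    its cluster; the prediction is the argmax, with ties or zero votes giving
    "unassigned".
    """
    if not diagnostics:
        raise ValueError("no diagnostic genotypes supplied")
    votes: dict[str, int] = {}
    for diag in diagnostics:
        call = line_calls.get(diag.marker)
        if call is None or call is NULL or call is MULTIBAND:
            continue
        if diag.genotype in call:
            votes[diag.cluster] = votes.get(diag.cluster, 0) + 1
    if not votes:
        return "unassigned", votes
    top = max(votes.values())
    leaders = [c for c, v in votes.items() if v == top]
    return (leaders[0] if len(leaders) == 1 else "unassigned"), votes


def diagnostics_to_frame(diagnostics: Sequence[DiagnosticGenotype]) -> pd.DataFrame:
    return pd.DataFrame([{
        "marker": d.marker, "genotype": d.genotype, "cluster": d.cluster,
        "in_pct": d.in_pct, "max_out_pct": d.max_out_pct,
    } for d in diagnostics], columns=["marker", "genotype", "cluster",
                                      "in_pct", "max_out_pct"])
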