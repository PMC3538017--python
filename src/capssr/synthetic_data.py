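"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline's inputs end to end:

* :func:`simulate_ests` — transcript-like sequences with planted di/tri/tetra
  SSRs at known coordinates over a repeat-free background, for the mining
  stage;
* :func:`simulate_population` — a K-cluster diploid population genotyped at
  fragment-length markers of all four marker types, with cluster-private
  alleles (divergence), null alleles, optional excluded (multiband) markers,
  per-line plastid matK/rbcL templates carrying three-site haplotypes, and
  cytonuclear-hybrid lines (nuclear genotype from one cluster, plastid from
  another);
* :func:`simulate_hits` — a 12-column tabular hit file whose sub-threshold
  hits encode known map positions, plus non-significant decoys.

Every generator is a pure function of its parameters and seed, so outputs
are byte-for-byte reproducible.  Allele sizes sit on a fragment grid
(80-400 bp in steps of the repeat unit length) so matrices look like
fragment-analysis data.  Hybrids are pure nuclear-cluster lines with a
foreign plastid; nuclear admixture is a documented extension, not modelled.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .barcode import DEFAULT_SITES, MATK_PRIMERS, RBCL_PRIMERS, in_silico_pcr
from .genotype_typing import NULL, MULTIBAND, GenotypeTable, make_call
from .insilico_map import HIT_COLUMNS, Placement
from .ssr_mining import (DEFAULT_MIN_REPEATS, ESTRecord, SSRLocus,
                         canonical_motif_class, find_ssrs)

_BASES = np.array(list("ACGT"))

#: Real amplicon insert lengths (primer sequences excluded) used for the
#: synthetic plastid templates.
MATK_INSERT_LEN = 837
RBCL_INSERT_LEN = 553

#: Cluster label -> plastid haplotype over (matK129, matK312, rbcL392).
def _cluster_haplotype(label: str) -> str:
    return {"A": "CTG", "B": "ACG"}.get(label, "CTA")


def cluster_labels(k: int) -> list[str]:
    """Cluster label sequence A, B, C, F, then remaining letters (N is
    reserved for unclassifiable lines)."""
    base = ["A", "B", "C", "F"]
    extras = [c for c in string.ascii_uppercase if c not in set(base) | {"N"}]
    labels = base + extras
    if k > len(labels):
        raise ValueError("too many clusters requested")
    return labels[:k]


# ---------------------------------------------------------------------------
# ESTs

def _random_repeat_free(rng: np.random.Generator, length: int,
                        min_repeats: Mapping[int, int]) -> str:
    for _ in range(200):
        seq = "".join(rng.choice(_BASES, size=length))
        if not find_ssrs(seq, min_repeats):
            return seq
    raise RuntimeError("could not generate a repeat-free background")


def simulate_ests(n: int = 100, length: int = 1000,
                  motif_class_probs: Mapping[str, float] | None = None,
                  planted_per_est: int = 1, seed: int = 0,
                  min_repeats: Mapping[int, int] | None = None,
                  margin: int = 60) -> tuple[list[ESTRecord], list[SSRLocus]]:
    """Generate ESTs with planted SSRs and return the truth table.

    Each EST is a repeat-free random background (rejection-sampled against
    the mining thresholds) into which ``planted_per_est`` SSRs are written at
    known offsets, one per equal-width segment, each at least ``margin`` bp
    from the segment edges.  Repeat counts are drawn a little above the
    mining threshold.  After planting, the sequence is re-scanned and
    accepted only if mining reports exactly the planted loci, so the truth
    table is exact by construction.
    """
    if motif_class_probs is None:
        motif_class_probs = {"AAG": 0.4, "AT": 0.3, "AAT": 0.3}
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    total = sum(motif_class_probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("motif class probabilities must sum to 1")
    units = sorted(motif_class_probs)
    probs = np.array([motif_class_probs[u] for u in units]) / total
    max_span = max((len(u) * (min_repeats[len(u)] + 4) for u in units),
                   default=0)
    if planted_per_est and length < planted_per_est * (max_span + 2 * margin):
        raise ValueError(
            f"length {length} too short for {planted_per_est} planted SSRs")

    rng = np.random.default_rng(seed)
    ests: list[ESTRecord] = []
    truth: list[SSRLocus] = []
    for e in range(n):
        est_id = f"EST{e + 1:05d}"
        for _ in range(100):
            seq = _random_repeat_free(rng, length, min_repeats)
            planted: list[SSRLocus] = []
            segment = length // planted_per_est if planted_per_est else length
            chars = list(seq)
            ok = True
            for s in range(planted_per_est):
                unit = units[int(rng.choice(len(units), p=probs))]
                reps = int(rng.integers(min_repeats[len(unit)] + 1,
                                        min_repeats[len(unit)] + 4))
                span = len(unit) * reps
                lo = s * segment + margin
                hi = (s + 1) * segment - margin - span
                if hi < lo:
                    ok = False
                    break
                start = int(rng.integers(lo, hi + 1))
                chars[start:start + span] = list(unit * reps)
                planted.append(SSRLocus(unit=unit,
                                        canonical_class=canonical_motif_class(unit),
                                        repeat_count=reps, start=start,
                                        end=start + span, est_id=est_id))
            if not ok:
                continue
            candidate = "".join(chars)
            found = find_ssrs(candidate, min_repeats)
            if sorted((l.start, l.end, l.unit) for l in found) == \
               sorted((l.start, l.end, l.unit) for l in planted):
                ests.append(ESTRecord(id=est_id, sequence=candidate))
                truth.extend(sorted(planted, key=lambda l: l.start))
                break
        else:
            raise RuntimeError(f"could not plant SSRs into {est_id}")
    return ests, truth


def write_fasta(records: Sequence[ESTRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Population

@dataclass
class PopulationDesign:
    """Parameters of the synthetic K-cluster diversity panel.

    ``divergence`` is the probability mass a cluster places on its own
    private allele at a codominant marker; the remainder is spread uniformly
    over ``shared_alleles`` alleles common to all clusters.  ``type_mix``
    defaults to the proportions of the four marker types (plus excluded
    markers) observed in a 96-marker Capsicum screen: 16 I, 27 II, 17 III,
    17 IV, 19 na.
    """

    K: int = 4
    n_per_cluster: int = 30
    n_markers: int = 60
    shared_alleles: int = 3
    divergence: float = 0.9
    null_rate: float = 0.05
    type_mix: dict[str, float] = field(default_factory=lambda: {
        "I": 16 / 96, "II": 27 / 96, "III": 17 / 96, "IV": 17 / 96,
        "na": 19 / 96})
    hybrid_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "null_rate", "hybrid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.K, self.n_per_cluster, self.n_markers) < 1:
            raise ValueError("K, n_per_cluster and n_markers must be >= 1")
        if self.shared_alleles < 1:
            raise ValueError("shared_alleles must be >= 1")
        if any(p < 0 for p in self.type_mix.values()) or \
                abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("type_mix must be a probability distribution")


@dataclass
class PopulationSim:
    """A simulated panel plus every piece of ground truth about it."""

    design: PopulationDesign
    table: GenotypeTable
    clusters: dict[str, str]              # line -> true cluster label
    haplotypes: dict[str, str]            # line -> true plastid haplotype
    plastid: dict[str, dict[str, str]]    # line -> gene -> PCR template
    hybrids: list[str]                    # lines with a foreign plastid
    marker_types: dict[str, str]          # marker -> intended type
    private_alleles: dict[str, dict[str, int]]  # marker -> cluster -> size


def _apportion(mix: Mapping[str, float], total: int) -> dict[str, int]:
    order = ["I", "II", "III", "IV", "na"]
    raw = {t: mix.get(t, 0.0) * total for t in order}
    counts = {t: int(np.floor(raw[t])) for t in order}
    for t in sorted(order, key=lambda t: -(raw[t] - counts[t])):
        if sum(counts.values()) == total:
            break
        counts[t] += 1
    return counts


def _fragment_grid_base(rng: np.random.Generator, unit_len: int,
                        n_alleles: int) -> int:
    hi = 400 - unit_len * n_alleles
    return int(rng.integers(80, hi + 1))


def _plastid_backbones(rng: np.random.Generator) -> dict[str, list[str]]:
    backbones = {}
    for gene, primers, ins_len in (("matK", MATK_PRIMERS, MATK_INSERT_LEN),
                                   ("rbcL", RBCL_PRIMERS, RBCL_INSERT_LEN)):
        for _ in range(20):
            insert = list(rng.choice(_BASES, size=ins_len))
            template = primers.forward + "".join(insert) + revcomp(primers.reverse)
            if in_silico_pcr(template, primers).status == "ok":
                backbones[gene] = insert
                break
        else:
            raise RuntimeError(f"could not build a clean {gene} backbone")
    return backbones


def simulate_population(design: PopulationDesign) -> PopulationSim:
    """Draw a clustered diploid panel with plastid templates and full truth.

    Cluster k's allele-frequency vector at a codominant marker puts
    ``divergence`` on the k-private allele and the rest uniformly on the
    shared alleles; two allele draws per line give a one- or two-size call.
    NULL is injected at ``null_rate`` on type II markers; type IV markers are
    presence/absence with a random carrier-cluster subset; "na" markers carry
    one MULTIBAND call so downstream typing excludes them.  Hybrid lines keep
    their cluster's nuclear genotypes but take the plastid haplotype of a
    cluster with a different haplotype.
    """
    if design.divergence == 0:
        warnings.warn("divergence is 0: clusters carry no private-allele "
                      "signal, diagnostic recovery is impossible", stacklevel=2)
    rng = np.random.default_rng(design.seed)
    labels = cluster_labels(design.K)
    lines = [f"{lbl}{i + 1:03d}" for lbl in labels
             for i in range(design.n_per_cluster)]
    clusters = {ln: ln[0] for ln in lines}

    type_counts = _apportion(design.type_mix, design.n_markers)
    marker_names = [f"CaES{i + 1:04d}" for i in range(design.n_markers)]
    type_list = [t for t in ("I", "II", "III", "IV", "na")
                 for _ in range(type_counts[t])]
    rng.shuffle(type_list)
    marker_types = dict(zip(marker_names, type_list))

    calls: dict[str, dict[str, object]] = {ln: {} for ln in lines}
    private_alleles: dict[str, dict[str, int]] = {}
    unit_len = 3  # trinucleotide grid, the dominant EST-SSR class

    for marker in marker_names:
        mtype = marker_types[marker]
        if mtype in ("I", "II"):
            s = design.shared_alleles
            base = _fragment_grid_base(rng, unit_len, s + design.K)
            shared = [base + unit_len * i for i in range(s)]
            private = {lbl: base + unit_len * (s + k)
                       for k, lbl in enumerate(labels)}
            private_alleles[marker] = private
            for ln in lines:
                lbl = clusters[ln]
                pool = shared + [private[lbl]]
                p = np.full(s + 1, (1 - design.divergence) / s)
                p[-1] = design.divergence
                a, b = rng.choice(pool, size=2, p=p)
                call = make_call(int(a), int(b))
                if mtype == "II" and rng.random() < design.null_rate:
                    call = NULL
                calls[ln][marker] = call
        elif mtype == "III":
            size = _fragment_grid_base(rng, unit_len, 1)
            for ln in lines:
                calls[ln][marker] = make_call(size)
        elif mtype == "IV":
            size = _fragment_grid_base(rng, unit_len, 1)
            n_carrier = int(rng.integers(1, design.K)) if design.K > 1 else 1
            carriers = set(rng.choice(labels, size=n_carrier, replace=False))
            for ln in lines:
                present_p = (1 - design.null_rate if clusters[ln] in carriers
                             else design.null_rate)
                calls[ln][marker] = (make_call(size)
                                     if rng.random() < present_p else NULL)
        else:  # na: one multiband call voids the marker
            size = _fragment_grid_base(rng, unit_len, 1)
            victim = lines[int(rng.integers(len(lines)))]
            for ln in lines:
                calls[ln][marker] = MULTIBAND if ln == victim else make_call(size)

    table = GenotypeTable(lines=list(lines), markers=list(marker_names),
                          calls=calls)

    # plastid haplotypes and hybrid lines
    haplotypes = {ln: _cluster_haplotype(clusters[ln]) for ln in lines}
    n_hybrids = int(round(design.hybrid_fraction * len(lines)))
    hybrids: list[str] = []
    if n_hybrids:
        candidates = [str(x) for x in
                      rng.choice(lines, size=len(lines), replace=False)]
        for ln in candidates:
            if len(hybrids) == n_hybrids:
                break
            own = _cluster_haplotype(clusters[ln])
            donors = sorted({_cluster_haplotype(l) for l in labels
                             if _cluster_haplotype(l) != own})
            if not donors:
                continue
            haplotypes[ln] = donors[int(rng.integers(len(donors)))]
            hybrids.append(ln)
    hybrids.sort()

    backbones = _plastid_backbones(rng)
    site_map = {("matK", s.position): i for i, s in enumerate(DEFAULT_SITES)
                if s.gene == "matK"}
    plastid: dict[str, dict[str, str]] = {}
    for ln in lines:
        hap = haplotypes[ln]
        matk = list(backbones["matK"])
        for site in DEFAULT_SITES:
            if site.gene == "matK":
                matk[site.position - 1] = hap[site_map[("matK", site.position)]]
        rbcl = list(backbones["rbcL"])
        for site in DEFAULT_SITES:
            if site.gene == "rbcL":
                rbcl[site.position - 1] = hap[2]
        plastid[ln] = {
            "matK": MATK_PRIMERS.forward + "".join(matk) + revcomp(MATK_PRIMERS.reverse),
            "rbcL": RBCL_PRIMERS.forward + "".join(rbcl) + revcomp(RBCL_PRIMERS.reverse),
        }

    return PopulationSim(design=design, table=table, clusters=clusters,
                         haplotypes=haplotypes, plastid=plastid,
                         hybrids=hybrids, marker_types=marker_types,
                         private_alleles=private_alleles)


# ---------------------------------------------------------------------------
# Similarity hits

def simulate_hits(true_placements: Sequence[Placement], decoy_count: int = 0,
                  emax: float = 1e-50, seed: int = 0) -> pd.DataFrame:
    """One significant hit per placed marker plus non-significant decoys.

    The significant hit's subject interval midpoint equals the true position
    exactly and its E-value falls strictly below ``emax``; decoys draw
    E-values at or above ``emax`` so that filtering and placement recover the
    truth exactly.  Returns a 12-column hit table (shuffled row order).
    """
    rng = np.random.default_rng(seed)
    chroms = sorted({p.chrom for p in true_placements}) or ["T01"]
    rows = []

    def _row(query, subject, s_start, s_end, e_value):
        aln = abs(s_end - s_start) + 1
        return {"query_id": query, "subject_id": subject,
                "identity": round(float(rng.uniform(70, 100)), 2),
                "aln_length": aln,
                "mismatches": int(rng.integers(0, 30)),
                "gap_opens": int(rng.integers(0, 5)),
                "q_start": 1, "q_end": aln,
                "s_start": s_start, "s_end": s_end,
                "e_value": float(e_value),
                "bit_score": round(float(rng.uniform(100, 500)), 1)}

    for p in true_placements:
        pos = int(p.position)
        half = min(int(rng.integers(50, 151)), max(pos - 1, 0))
        s_start, s_end = pos - half, pos + half
        if rng.random() < 0.5:  # minus strand: midpoint unchanged
            s_start, s_end = s_end, s_start
        rows.append(_row(p.marker, p.chrom, s_start, s_end,
                         emax * 10 ** -float(rng.uniform(1, 30))))
    for _ in range(decoy_count):
        query = true_placements[int(rng.integers(len(true_placements)))].marker \
            if true_placements else f"DECOY{_ + 1}"
        start = int(rng.integers(1, 1_000_000))
        rows.append(_row(query, chroms[int(rng.integers(len(chroms)))],
                         start, start + int(rng.integers(50, 300)),
                         emax * 10 ** float(rng.uniform(0.3, 10))))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sample(frac=1.0, random_state=int(rng.integers(2 ** 31))
                     ).reset_index(drop=True)


def write_hits_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
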