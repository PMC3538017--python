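# Methods

This note records the scientific conventions, defaults and design choices
behind `capssr`, in the order the pipeline runs them.

## SSR mining

An SSR locus is an exact tandem repeat of a primitive unit (a unit that is
not itself a repeat of a shorter unit, so homopolymers and (AT)₂-style
"tetranucleotides" are excluded) of length 2–4 bp. Scanning is
leftmost-greedy per unit length: the sequence is walked left to right, the
first run meeting the repeat-count threshold is reported, and scanning
resumes past its end. This makes the output deterministic and identical to
an exhaustive all-start/all-unit-length enumeration followed by a greedy
non-overlap sweep (the test suite verifies this equivalence on thousands of
random sequences). Runs containing N are never reported, because an
ambiguous base cannot confirm a repeat.

Defaults (configurable): minimum repeats di ≥ 6, tri ≥ 5, tetra ≥ 5 —
common EST–SSR mining practice, giving repeats of ≥ 10–12 bp; flank length
150 bp with ≥ 50 bp required on both sides, enough sequence for primer
design while retaining most loci on typical ESTs. Motif classes pool all
rotations of a unit and of its reverse complement and are named by the
lexicographically smallest member (GAA, AGA, CTT → AAG); there are exactly
4 dinucleotide and 10 trinucleotide classes. Marker redundancy is removed
by exact or reverse-complement identity of the (left, right) flank pair —
cheap and deterministic; sequence-clustering dedup is out of scope.
Adjacent different-unit (compound) repeats are reported as separate loci.
Primer design proper (Tm/GC optimisation) is reduced to flank extraction;
a pass-through field stores externally designed primers.

## In-silico mapping

Hits arrive in the common 12-column tabular format; columns 1, 2, 9, 10, 11
are consumed. Significance is E < emax with emax = 10⁻⁵⁰ by default, strict
inequality. A marker's single map position is the midpoint
(s_start + s_end)/2 of its best hit (smallest E; ties by larger aligned
span, then lexicographic subject and start) — the midpoint is
orientation-free, so strand is collapsed. Panel selection places k mid-cell
grid targets tᵢ = (i − ½)L/k on each chromosome of length L and greedily
assigns each target the nearest unassigned marker (ties: smaller position,
then name). Greedy mid-cell assignment is a simple, reproducible reading of
"constant intervals"; it is not an optimal 1-D assignment, and the
difference is immaterial when markers outnumber targets.

## Genotype typing

A marker is assumed to amplify a single locus, so one or two fragment sizes
per line are read as a homozygote or heterozygote; more than two fragments
anywhere voids the marker (`na`), as does amplification failure in every
line. Otherwise the type is determined by two booleans — polymorphic
fragment sizes, and presence of null alleles: I (poly, no nulls), II (poly +
nulls), III (mono, no nulls), IV (mono + nulls, i.e. dominant
presence/absence).

Allele frequencies weight each fragment size by 1/|allele set| per line
(a heterozygote contributes ½ to each of its two alleles) and exclude
NULL/MULTIBAND lines from the denominator; expected heterozygosity is
HZ = 1 − Σ pᵢ². NULL is a single state covering both the null allele and
missing data — the two are indistinguishable in fragment analysis — and is
excluded from p by default because HZ is a statistic of the visible
fragment alleles of codominant markers; `null_as_allele=True` instead
counts it as one extra allele. Summary statistics follow the conventional
subsets: allele counts and HZ averaged over types I + II, null counts over
types II + IV.

## Diversity and trees

Band scoring: each distinct fragment size of an informative marker (types
I, II, IV) is one band; a line scores 1 per size carried, NULL scores 0 for
all of that marker's bands. Type III markers carry no information and are
dropped. Distance is d = 1 − J with J = n₁₁/(n₁₁ + n₁₀ + n₀₁) — shared
absences ignored, the standard treatment of dominant band data; 1 − J is a
metric (verified by exhaustive triangle checks). A pair of lines with no
bands at all cannot be compared and raises an error rather than returning a
silent 0 or 1.

Neighbor joining is the classical Saitou–Nei agglomeration: join the pair
minimising Q(i,j) = (r − 2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), with branch
lengths from the standard two-point formulas and ties broken by the
smallest (i, j) index pair. The result is exact on additive matrices (the
module's core oracle: random trees → path metric → NJ → identical patristic
distances) and is returned as an unrooted tree with a trifurcating root.
Negative branch lengths are retained — clamping would break additivity —
but can be listed (`negative_branches`) or zeroed for display
(`clamp_negative_branches`).

Cluster delimitation on a dendrogram is a by-eye step in practice; two
reproducible modes replace it: cutting the k − 1 longest internal branches
(fixed k), and majority labelling of the resulting blocks from a-priori
species labels. Blocks below `min_size` are labelled "N" (not
classifiable).

## Diagnostic genotypes

freq(marker, value, cluster) is the percentage of the cluster's lines
carrying the value (heterozygotes carry both values; "N" lines are
excluded). A genotype is diagnostic for cluster X iff freq ≥ θ_in·100 in X
and < θ_out·100 in every other cluster. Defaults θ_in = 0.80, θ_out = 0.15:
published cluster-specific genotypes in Capsicum panels run 82–100 % inside
their cluster and 0–6 % outside, so these thresholds flag all of them while
θ_in > 0.5 guarantees at most one cluster per genotype. The diagnostic set
is monotone in both thresholds (tested). Plastid haplotype states (e.g.
matK "AC") are admitted as genotype values alongside fragment sizes.
Unknown lines are classified by majority vote over the diagnostic genotypes
they carry; ties and empty votes return "unassigned".

## Barcoding

In-silico PCR matches the forward primer on the given strand and the
reverse primer as its reverse complement downstream, honouring IUPAC
degeneracy on both primer and template (match = non-empty intersection of
the coded base sets); mismatches are disallowed by default with a
configurable allowance. Zero or multiple products return an explicit
status, never a silent guess. The three SNP sites are 1-based positions
within the primer-excluded insert — amplicon sizes are conventionally
reported excluding primers (matK 837 bp, rbcL 553 bp), and site positions
are user-configurable to absorb the alternative full-amplicon convention.
A base outside a site's expected allele set yields a call flagged "novel"
rather than an error. Cytonuclear mismatch flags lines whose haplotype is
not in their cluster's expected set; the expectation can be supplied or
learned as each cluster's majority haplotype.

## Synthetic data

The generators emulate the structure of a real diversity panel, not its
sequence content. Defaults are the study conditions used throughout the
tests: K = 4 clusters × 30 lines, 60 markers, divergence δ = 0.9,
null rate 0.05, hybrid fraction 0.02, and a marker-type mix in the
proportions observed in a 96-marker Capsicum screen (16 I : 27 II : 17 III
: 17 IV : 19 na). At a codominant marker, cluster k draws alleles with
probability δ on its private allele and (1 − δ)/s on each of s = 3 shared
alleles; sizes sit on an 80–400 bp grid in steps of 3 bp (the dominant
trinucleotide class). Type IV markers are presence/absence over a random
carrier-cluster subset; `na` markers carry one MULTIBAND call so typing
excludes them. Plastid templates embed the real universal primer sequences
around random backbones of the real insert lengths (837/553 bp), with the
three SNP sites set per cluster haplotype (A → CTG, B → ACG, others → CTA);
hybrids keep their nuclear cluster but take a foreign haplotype. EST
backgrounds are rejection-sampled to be repeat-free at the mining
thresholds, and planted loci are re-scanned so the truth table is exact.

What passing tests therefore show: the algorithms are exact on their
defined inputs and recover planted structure under clean cluster
separation. What they do not show: performance on real panels with
admixture, genotyping error, allele-size homoplasy, or weak divergence —
the generator models none of these (an admixture knob is a documented
extension), and mutation/coalescent realism is out of scope.

## Numerical and interface choices

Problem sizes in the default test and acceptance runs (120-line panels,
500–1000 bp ESTs, 6–8-leaf oracle trees) were chosen as the smallest sizes
at which every property is non-trivially exercised. All randomness flows
through `numpy.random.default_rng(seed)`; identical seeds reproduce outputs
byte for byte, and the pipeline's `summary.json` excludes timing for that
reason (timings go to `run.log`). TSV outputs carry a `# capssr <stage>`
header comment naming the producing stage and parameters; FASTA, Newick and
JSON outputs do not, since those formats have no lossless comment channel.
Genotype-frequency comparisons use exact thresholds on percentages computed
from integer counts, so no tolerance is needed; HZ input vectors must sum
to 1 within 10⁻⁶.

## Known limitations

- The redundancy rule is textual flank identity; diverged copies of the
  same locus survive dedup.
- Cluster cutting assumes between-cluster branches dominate within-cluster
  ones; it can mis-cut trees with long terminal branches (hence the "N"
  safety valve and the reference-label mode).
- In-silico PCR scans both primer orientations on one strand only; a
  template supplied in reverse orientation should be reverse-complemented
  first.
- The distance is fixed to 1 − Jaccard on band presence; other band-sharing
  coefficients (Dice, simple matching) are not implemented, and reported
  maxima are sensitive to this choice.
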