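# Methods

## Scope and data model

The package analyses a two-genotype (WT vs KO) chromatin study in which
the knocked-out enzyme writes a broad histone mark (H3K4me1) at
enhancers.  Inputs are post-alignment abstractions: aligned-tag intervals
in BED (0-based, half-open), a gene table (TSS + strand), bulk count
tables, and a cell-by-gene matrix with cluster labels.  Spike-in
(exogenous species) tags are recognised purely by a chromosome-name
prefix, mirroring a combined two-species alignment index.  A single
overlap predicate (`a.start < b.end and b.start < a.end`, configurable
minimum overlap) is used everywhere intervals meet.

## Spike-in (ChIP-Rx) normalization

The normalization target is the spike tag **count**, not the spike
coverage profile: the experimental design fixes the amount of exogenous
chromatin per IP, so the exogenous yield measures IP efficiency per
sample.  `scale(s) = n_spike(ref)/n_spike(s)` with `ref` the sample with
the smallest spike count under `"auto"`, so scaling only down-weights.
Scale factors are therefore invariant to endogenous read content, and
doubling a sample's spike count exactly halves its scale.  Expression
(RNA) samples are normalized by ordinary library-size CPM; spike scaling
applies to the ChIP samples.  Whether an input/control sample should also
be spike-scaled is exposed as a choice; the default treats inputs with
library-size scaling only.

## Island calling

Fixed non-overlapping windows of `window_size` bp tile each chromosome.
Each tag's position is its 5′ end shifted `fragment_shift` bp toward the
3′ end (strand-aware; default 75 bp = half the 150 bp fragment length,
which sits inside the protocol's 100–300 bp fragment range), clamped at
chromosome bounds.  The background rate is
`λ_bg = n_endogenous_tags × window_size / effective_genome_length`
(total endogenous length by default) — a deliberate overestimate of pure
background, since enriched tags inflate it, making eligibility slightly
conservative.  A window with count `c` is eligible when the Poisson
upper tail `P(X ≥ c; λ_bg) ≤ p0` (default `p0 = 0.2`, the broad-mark
convention).  Eligible windows separated by at most `gap_size` bp of
ineligible windows (gap must be a multiple of the window) merge into
islands; the island interval is grid-aligned from the first to the last
eligible window and its tag count includes gap windows.  The island
score is `Σ −ln Poisson(c_i; λ_bg)` over eligible windows — additive and
non-negative.

Defaults: window/gap 200/200 bp for the histone mark; 50/50 bp for the
enzyme mark, whose binding is sharper.  Redundant tags (identical
chromosome, 5′ position, strand) are collapsed to one before counting
(configurable), a minimal PCR-duplicate guard.

**Significance.** With a control sample, each island's p-value is the
Poisson upper tail of its tag count under a control-derived expectation
(control count in the island × library-size ratio; a zero control count
is replaced by a pseudo-count of 1), with Benjamini–Hochberg control at
`fdr` across islands.  Without a control, islands are kept when their
score reaches a threshold calibrated so that the expected number of
pure-background islands does not exceed an E-value.  The calibration is a
Monte-Carlo simulation of Poisson background windows under a fixed
internal seed — deterministic across runs — rather than an analytic
score-distribution recursion; the two agree in contract (expected
background islands ≤ E).  The E-value default is 100, chosen for the
tens-of-megabases genomes this artifact analyses (an E of 1000, the
convention for ~3 Gb mammalian genomes, would tolerate one background
island per 20 kb here); it is a config knob.

## Differential signal and integration

Per-island fold change is `(scaled WT + ε)/(scaled KO + ε)` with
`ε = 0.5`; `ε = 0.5` is used wherever a ratio of counts is formed, so
double-zero cases are neutral (fc = 1).  Islands overlapping any
TSS ± 2 kb window are promoter-class; all others are enhancer-class and
are linked to the gene with the smallest edge-to-TSS distance within
100 kb (ties to the lexicographically smallest gene id; unlinked islands
are dropped and counted).  Both the promoter half-width and the distance
cap are conventional values and configurable.

The dual filter keeps a gene iff its expression fold change (mean WT CPM
vs mean KO CPM, ε = 0.5) **and** its linked enhancer fold change are both
≥ 1.6 — inclusive, reading "at least" literally.  A gene with several
linked enhancers is evidenced by its most-changed enhancer (max rule;
mean available behind a flag), and only reductions (WT > KO) are filtered
by default, with a direction flag for the reverse.  A passing gene is
"bound" when its evidencing enhancer overlaps (≥ 1 bp) any binding
island of the enzyme.  The report always carries `n_pass`,
`n_pass_bound` and `bound_fraction` (0 with an explicit `n_pass = 0` in
the degenerate case) so a real-data run is a drop-in replacement for a
synthetic one.

## GSEA

Classic weighted Kolmogorov–Smirnov statistic on a ranking sorted by a
signed metric (descending, ties by gene id; the default ranking metric in
the CLI is whatever the supplied table contains — log2 fold change in
typical use).  Hits add `|metric|^p` normalized over hits (`p = 1`
default), misses subtract `1/(N − N_hits)`; the ES is the running sum's
value at its first maximum absolute deviation.  If every hit's metric is
exactly zero the hit weights degenerate to uniform.  The null is the ES
of `n_perm` random same-size gene sets (gene-tag permutation — phenotype
permutation is degenerate at the 2–3 replicates this design provides);
NES divides the ES by the mean magnitude of same-sign null scores, the
p-value is one-sided empirical with +1 smoothing, and q is BH across
sets.  A set is flagged significant at NES ≥ 1.5 and q < 0.10
(configurable).  The +1 smoothing makes the p-value slightly
conservative by construction, which the calibration test accounts for
with a binomial tolerance band.

## Single-cell DE filter

Counts are normalized per cell to 10⁴ and log1p-transformed (the
standard toolkit convention this filter is meant to slot behind).  A
gene is differentially expressed in the tested cluster iff: expressed
(count > 0) in ≥ 30 % of that cluster's cells, mean fold change ≥ 1.2,
and BH-FDR of a two-sample Student's t-test (equal-variance; Welch
behind a flag) on the log-normalized values ≤ 5 % — all boundaries
inclusive.  The fold change is the ratio of mean normalized expression
with a pseudo-count of 1, the same offset log1p implies.  The three
thresholds only ever filter, so loosening any of them never removes a
discovery.

## The synthetic-data generator

The generator is first-class, tested code; it defines the study
conditions under which the pipeline's guarantees are demonstrated.

**Genome.** Genes on a regular grid with ≥ 10 kb TSS spacing (a sizing
error names the constraint when they do not fit); each enhancer (1 kb)
is assigned a distinct target gene, placed 5–100 kb downstream of its
TSS, bounded so that its own target stays its nearest TSS and clear of
the target's ±2 kb promoter window.  Baseline expression is lognormal
(median 100, σ = 0.5 on the log scale).

**ChIP emission.** Tags arise from a mixture of uniform genome-wide
background and per-feature enrichment: every promoter at fold 3 (so the
promoter/enhancer classifier is exercised), every enhancer at fold 30
over background — a strong-enhancer regime in which a 200 k-tag library
yields ~100 tags per enhancer, enough that a 2.5-fold planted change is
separable from Poisson noise at the 1.6 threshold.  Positions are
uniform within the feature; fragments are fixed-length (150 bp) and tags
record the 5′ end and strand.  Spike-in tags are uniform on the spike
chromosomes (only their total matters downstream).

**Depletions and sequencing yield.** `depth` is the nominal yield of an
unperturbed sample.  The expected spike yield is `depth × spike_fraction`
(default 10 %) for every sample, while the expected endogenous yield
scales with the sample's total emission weight relative to WT — i.e.
the KO's global H3K4me1 depletion reduces its endogenous yield uniformly
without touching the spike-in.  This is exactly the regime spike-in
normalization exists for: the spike-scaled KO/WT ratio recovers the
planted global factor, while the per-library CPM ratio is 1 regardless.
Per-enhancer planted factors deplete the enrichment component of
individual enhancers on top of the global term.  KO samples of the
enzyme mark emit background only (the protein is absent), giving the
caller a true-negative channel.  RNA counts are negative binomial
(dispersion α = 0.05 default, variance μ + αμ²; α = 0 degenerates to
Poisson) with the planted expression factor multiplying the KO mean, so
the expected KO/WT ratio equals the factor exactly.

**Single-cell matrix.** Two clusters (resting/stimulated), Poisson
counts at ~2000 per cell, the planted signature folds applied to the
stimulated cluster.  The `dropout` parameter zeroes entries
independently for stress-testing sparsity; its default is 0 because
droplet UMI counts are adequately described by Poisson sampling without
extra zero-inflation, and the planted-signature recovery guarantee is
stated under that regime.

**Reference scenario** (`default_scenario`): 2 × 10 Mb endogenous
chromosomes plus a 10 Mb spike chromosome, 1000 genes with one enhancer
each, 100 planted dual-effect genes at factor 0.4 (2.5-fold), 60 % of
enhancers bound by the enzyme — stratified so that exactly 60 % of the
affected enhancers are bound — and a 50-gene fold-3 single-cell
signature.  ChIP depth 2 × 10⁵ tags/sample, enzyme mark 10⁵, RNA
5 × 10⁶ counts × 3 replicates/genotype, 200 cells/cluster.  These sizes
keep a full pipeline run to a few seconds while leaving the planted
effects statistically unambiguous.

**What passing the synthetic suite shows — and what it does not.**
The generator demonstrates that the statistics are implemented correctly
and that the pipeline recovers planted effects under its own model:
uniform-within-feature enrichment, no GC/mappability bias, no
fragment-length variation, exact per-feature emission rates, independent
cells.  Real data violate all of these; sensitivity/precision measured
here bound what the pipeline can do under ideal conditions, not what it
will achieve on a given experiment.  The study-scale headline counts of
a real experiment depend on its deposited raw data and are not
reproducible from synthetic inputs; the pipeline instead guarantees the
same three summary numbers are emitted so the real-data run slots in.

## Numerical and design notes

- Poisson tails and pmfs via scipy; BH via statsmodels; both are
  cross-checked in the test suite against direct summation / a hand-rolled
  BH on small instances.
- The eligibility search walks `c` upward from 0 — exact, no closed-form
  inversion.
- Island intervals stay window-grid-aligned even at chromosome ends (the
  final window may extend past the last base; counts are clamped, the
  interval is not).
- In the GSEA running sum, an exact tie between the positive maximum and
  the negative minimum leaves the ES sign floating-point-degenerate; the
  implementation takes the first extremum by position, and the oracle
  tests compare magnitudes when the two extrema coincide within 1e−9.
- Empirical p-values use +1 smoothing and can never be exactly zero.
- All generators and the Monte-Carlo score calibration are pure
  functions of their arguments and seeds; CLI outputs are byte-stable
  for a fixed config and seed.

## Known limitations

- No local background (input-free calling assumes a homogeneous genome);
  no duplicate-aware statistics beyond the one-per-position filter; no
  multi-replicate ChIP designs or IDR.
- Enhancer–gene linking is nearest-TSS within a cap; no chromatin-contact
  or eQTL evidence.
- The single-cell filter consumes cluster labels; clustering itself,
  highly-variable-gene selection and embeddings are out of scope.
- Gene sets are user-supplied (GMT); no ontology retrieval.
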