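# Methods

This note records the models behind `dhsdyn`, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmark does and
does not establish about real data.

## Study design being modeled

Four developmental stages (labeled E12, E13, E14, E16 and coded at their
embryonic-day times 12, 13, 14, 16 so the unequal final gap is honored),
two biological replicates per stage, with three read-outs per study:
DNase cut-site tracks per stage/replicate, H3K4me3 and H3K27me3 ChIP
tracks for the starting (NPC) stage, and a gene × sample RNA-seq count
matrix. All genomic coordinates are 0-based half-open; the TSS of a −
strand gene is the last base of its span.

## Peak calling

The cut-density model is a kernel density estimate: each cut contributes a
Gaussian kernel of bandwidth *b* normalized to unit mass, truncated at 5*b*
(mass loss 5.7×10⁻⁷), evaluated on a regular grid.

* `bandwidth` (100 bp for DNase, 200 bp for the broader ChIP marks): the
  smoothing scale that resolves promoter-sized windows; order of what
  kernel-density DNase peak callers use.
* `grid_step` (10 bp): fine enough that grid sampling error of a 100 bp
  kernel is negligible (the Riemann sum of a Gaussian at σ/10 spacing is
  exact to machine precision); every grid profile is checked against direct
  per-point kernel summation in the tests.
* `p` (10⁻⁶): per-grid-point tail probability defining the calling
  threshold.
* `min_length` (50 bp) and `merge_gap` (50 bp): runs above threshold closer
  than the gap merge first, then runs shorter than the minimum drop.

**The null.** Under uniform cutting at rate λ per bp the KDE height at a
point has mean μ = λ and variance σ² = λ/(2b√π). `background_threshold`
returns the Gaussian-approximation threshold μ + z(1−p)·σ. However, the
height is a *compound Poisson* sum — at λ = 0.01/bp and b = 100 only ~3.5
cuts sit under a kernel footprint — and its right tail is far heavier than
Gaussian: the measured exceedance frequency at the nominal 10⁻⁶ Gaussian
threshold is ≈2×10⁻⁴. `call_peaks` therefore thresholds, by default,
against the exact compound-Poisson distribution of the height, evaluated
with the Lugannani–Rice saddlepoint approximation (verified against
empirical null quantiles to within the Monte-Carlo error); the Gaussian
null remains available as `null="gaussian"`. Near the mean (where the
saddlepoint formula degenerates) the code falls back to the Gaussian — only
the far tail matters for calling.

Tracks with fewer than 10 cuts return no peaks rather than applying the
degenerate null (with n = 0 the threshold is 0 and any density would
"exceed" it). `effective_length` is the genome length minus excluded bases
(blacklist-style exclusion regions remove both cuts and overlapping called
regions; sex-chromosome removal is expressed as exclusion regions covering
those chromosomes).

**Reproducibility rule.** A DHS is any pair of ≥1 bp-overlapping peaks
across the two replicates; its span is the union of the pair (conservative
inclusion for downstream overlap tests; intersection is an option), and
overlapping spans merge. Peaks private to one replicate are discarded.

## Genome partition and feature assignment

Features are painted per chromosome in increasing priority order —
distal < downstream < intron < exon < promoter — into a byte array, so the
final label of a base is the highest-priority feature covering it; the
result is exact (labels disjoint, lengths sum to the chromosome) and
independent of gene order. Promoter = [TSS−1000, TSS+500) strand-aware;
downstream = 1 kb past the transcription end (leftward for − strand genes);
intron = transcribed span minus exons. A region is assigned the
highest-priority label it overlaps by ≥1 bp (bp-majority is an option;
the priority rule matches the partition hierarchy and keeps a promoter-
touching DHS a promoter DHS). Enhancer–gene links are counted per
(DHS, enhancer) pair, so a DHS spanning two enhancers of one gene counts
twice, matching per-enhancer link tables.

## Gene-level chromatin states

A gene is DHS-positive at a stage iff ≥1 DHS overlaps its promoter window.
With k stages the presence/absence patterns form 2ᵏ−1 gene sets (the
all-absent pattern is flagged "no-DHS" and excluded); the sets partition the
DHS-positive genes. Opening/closing is defined from the two endpoint
stages: absent-then-present is opening, present-then-absent closing;
per-region calls between any two DHS sets use ≥1 bp overlap as the
cross-stage correspondence (the simplest testable rule). Bivalency reuses
the both-replicate rule on each ChIP mark: a gene is bivalent iff
reproducible H3K4me3 *and* H3K27me3 peaks overlap its promoter window, with
K4-only / K27-only / neither as the other categories.

## Expression

TMM scaling factors are computed against a reference sample (the one whose
0.75 quantile of depth-normalized counts is closest to the mean such
quantile): M = log₂ ratio of depth-normalized counts, genes with zeros
excluded, the extreme 30% of M-values and 5% of A-values rank-trimmed, and
the rest averaged with precision weights. Two deliberate properties of this
variant:

* weights are computed on count *proportions* (the deep-sequencing limit of
  the binomial M-variance weights), so the factors depend only on library
  composition — multiplying one library's counts by a constant provably
  leaves every expression value unchanged, an invariant the test suite
  checks exactly;
* factors are rescaled to geometric mean 1. `library_sizes` defaults to
  column sums; passing equal sizes reduces M-values to raw count ratios
  (in which case a library with exactly doubled counts gets factors
  (1/√2, √2) — the closed form used in the tests).

Expression value = count / (library_size × factor) × 10⁶ / (length/1000),
i.e. a length-corrected per-million measure; display plots use value+1 so
zeros survive a log axis, and the same pseudocount enters the twofold rule
for single-replicate comparisons ((b+1)/(a+1) > 2).

**Time-course test.** Per gene, log(value+1) is regressed on a polynomial
in stage time of degree min(3, n_stages−1) (centered time, ordinary least
squares across all genes at once) and the full model is tested against the
intercept with an F-test; q-values are Benjamini–Hochberg and DEGs are
q < 0.05. This is a single-step simplification of the two-step
polynomial-regression packages used for such designs (global fit, then
stepwise per-term selection): with four stages and the cubic saturating the
stage means, the omnibus F-test captures the same "any temporal change"
question the downstream analysis needs, and its null calibration is exact
under Gaussian noise (checked on 2000 null genes). Degenerate genes (zero
variance and zero trend) get p = 1 by convention; an exactly-interpolated
trend with zero residual gets p = 0. DEG profiles (per-gene stage means,
z-scored; zero-variance profiles map to the zero vector) are clustered with
k-means, k = 9, 25 restarts under a fixed seed — a deterministic,
well-understood choice for grouping smooth temporal shapes.

## Overlap statistics and GSEA

Fisher's exact test is one-sided ("greater", enrichment) by default, with
two-sided available and the sidedness recorded in the result; family ×
family matrices are BH-corrected across all cells jointly (raw p is also
reported). GSEA is preranked: hits advance the running sum by
|score|^weight (normalized over hits; an all-zero-score set falls back to
unweighted), misses retreat by 1/(N−|S|); ES is the maximum deviation, the
null permutes gene labels (the ranking is a precomputed input, so phenotype
permutation is unavailable by construction), NES divides by the mean |null
ES| of the same sign and p is the add-one same-sign tail. Gene sets equal
to the whole list or disjoint from it are rejected.

## The synthetic benchmark

The generator plants, per gene, a dynamic accessibility class (stably
open/closed, or opening/closing at each later stage), an expression
trajectory, histone-mark flags and a regulator-binding flag, then simulates:

* **Cut sites**: homogeneous Poisson background (`background_rate`,
  default 0.02 cuts/bp — the per-bp depth a >20-million-fragment mouse
  library implies — scaled per replicate by `library_size_factors`,
  default (1.0, 1.2), to exercise normalization), with promoter windows of
  stage-accessible genes at `background_rate × accessible_enrichment`
  (default 8×, i.e. 240 expected cuts per accessible 1.5 kb promoter per
  replicate). Open enhancers get the same enrichment at all stages.
* **Mark tracks**: the same Poisson model with 1.5 kb windows centered on
  promoters of K4/K27-flagged genes (bivalent genes carry both marks).
* **Counts**: negative binomial (gamma–Poisson) with mean = trajectory
  value × gene base rate × exonic length × library factor, globally scaled
  to `library_size` (10⁶) expected reads, dispersion 0.05 (var = μ+0.05μ²;
  Poisson in the →0 limit). Trajectories: flat, 4× geometric rise, its
  mirror, and a ~3× transient; stably closed genes are flat at 0.2× the
  base scale, mirroring the lower expression of promoter-DHS-negative
  genes.

Class fractions are applied by exact largest-remainder quota over a
shuffled gene order, so planted counts are deterministic (default: 35%
always open, 25% never open, 20% opening and 20% closing split evenly over
the later stages). Bivalent (15%) and regulator-bound (15%) genes are drawn
with a 4× preference for opening genes, so the planted overlap structure
resembles the biology the overlap matrices are meant to detect. Genes sit
in disjoint slots on a regular grid, so promoter windows never overlap
between genes, and a sizing error is raised when the request cannot fit.
All randomness flows from one master seed through named child seeds
(seed, purpose, stage, replicate), making every bundle byte-reproducible.

**What the benchmark does not emulate**: sequence content and mappability
(no nucleotides are generated), fragment-size effects, overlapping or
nested genes, inhomogeneous background (GC or accessibility covariates),
copy-number, and trans effects between genes. Passing the planted-recovery
checks therefore demonstrates the *pipeline logic* — calling, the
replicate rule, window arithmetic, categorization, normalization and
testing — under the stated noise model, not robustness to the artifacts of
real libraries.

## Problem sizes

The default study is 1000 genes on a 2 × 5 Mb genome with 4 × 2 DNase
tracks (~10⁵–10⁶ cuts each), sizes at which the full analysis runs in
seconds on one CPU while every expected promoter still carries hundreds of
cuts; the statistical regime (cuts per promoter, enrichment fold, replicate
count) matches the study design rather than its genome scale. The
uniform-track specificity check uses 20 tracks of 10⁵ cuts over 10 Mb; at
the exact 10⁻⁶ per-grid-point threshold, ~1 supra-threshold grid point per
track is expected by construction, and the ≥50 bp run-length filter leaves
a called false peak in roughly one run in twenty.

## Known limitations

* The exact null assumes a homogeneous background; real DNase background is
  locally structured, so genome-wide thresholds are optimistic on real
  data (F-Seq-style local background estimation is not implemented).
* The omnibus F-test does not classify *which* polynomial term drives a
  gene; profile shape comes only from the subsequent clustering.
* TMM's proportion-based weights sacrifice a small amount of efficiency at
  very low counts in exchange for exact depth invariance.
* With two replicates the both-replicate rule is the only reproducibility
  criterion offered; no IDR-style ranking consistency is computed.
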