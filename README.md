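# dhsdyn

Chromatin-accessibility and transcriptome dynamics across a neuronal
differentiation time course.

During corticogenesis, neural precursor cells (NPCs) differentiate into
deep-layer excitatory neurons within a few embryonic days, and both their
transcriptome and their chromatin accessibility landscape reorganize.
`dhsdyn` is a desk-scale, fully testable reimplementation of the analysis
workflow behind such studies: DNase cut-site tracks from staged samples are
smoothed into density profiles, DNase-hypersensitive sites (DHSs) are called
against an analytic background null and filtered by a both-replicate
reproducibility rule, genes are categorized by the presence/absence of
promoter DHSs at each stage (the 2⁴−1 = 15 pattern gene sets of a four-stage
course), opening/closing and bivalent (H3K4me3⁺ H3K27me3⁺) promoters are
identified, RNA-seq counts are normalized into length-corrected expression
values and tested for temporal regulation, and the resulting gene families
are compared with Fisher's exact test and preranked GSEA.

Because such studies rarely deposit reusable raw data, the package ships a
first-class synthetic-data generator that plants a known ground truth
(which genes open, close, are bivalent, follow which expression trajectory),
so every stage of the pipeline can be scored for recall and precision.

## The core methods

**Peak calling.** Cuts at positions *cᵢ* are smoothed with a Gaussian kernel
of bandwidth *b* (default 100 bp), giving a density
*f(x) = Σᵢ φ((x−cᵢ)/b)/b* evaluated on a 10 bp grid. Under a uniform
(Poisson) null with *n* cuts over length *L*, the height at a point has mean
*μ = n/L* and variance *σ² = n/(L·2b√π)*. Peaks are maximal grid runs whose
density exceeds the height whose null tail probability is *p* (default
10⁻⁶); the tail is evaluated exactly for the compound-Poisson height
distribution (saddlepoint approximation), because the Gaussian approximation
badly underestimates it at realistic depths. Runs closer than 50 bp merge,
runs under 50 bp drop, and a DHS is a peak detected in both replicates
(union span).

**Genome partition.** Every base is labeled promoter (−1 kb/+0.5 kb of the
TSS, strand-aware) > exon > intron > downstream (1 kb past the gene) >
distal, and a DHS takes the highest-priority label it overlaps.

**Expression.** Counts are scaled by a TMM (trimmed mean of M-values)
variant whose precision weights depend only on count proportions, then
converted to `count / (library_size × factor) × 10⁶ / (length_kb)`
("expression value"). Per gene, a polynomial in stage time (degree ≤ 3 over
days 12, 13, 14, 16) is fitted to log(value+1) and tested against the
constant model with an F-test; Benjamini–Hochberg FDR < 0.05 defines the
differentially expressed genes, which k-means (k = 9) groups into temporal
profiles.

**Set statistics.** Overlaps between gene-set families are tested cell by
cell with Fisher's exact test (one-sided enrichment by default) and jointly
BH-corrected; preranked GSEA uses the weighted Kolmogorov–Smirnov running
sum with a gene-permutation null.

## Worked example

```sh
dhsdyn run-all --out demo --seed 9 --config tiny.yaml
```

with `tiny.yaml` containing a 15-gene, 300 kb study
(`{seed: 9, n_genes: 15, n_chroms: 1, chrom_length: 300000, n_enhancers: 5}`)
prints, among the log lines, the run summary:

```json
{
  "config_sha": "29cba371e5f1",
  "n_dhs_by_stage": {"E12": 9, "E13": 9, "E14": 9, "E16": 9},
  "dhs_total_width_by_stage": {"E12": 13320, "E13": 13280, "E14": 13210, "E16": 13270},
  "n_deg": 7,
  "n_genes": 15,
  "recovery": {
    "opening_precision": 1.0, "opening_recall": 1.0,
    "closing_precision": 1.0, "closing_recall": 1.0,
    "bivalent_precision": 1.0, "bivalent_recall": 1.0
  }
}
```

Nine DHSs per stage match the planted accessibility: of 15 genes, about a
quarter are stably closed and the rest carry a promoter DHS at any given
stage (plus open enhancers, some of which merge with neighboring promoter
peaks). `recovery` compares the pipeline's
opening/closing and bivalency calls with the planted truth — at default
depth and 8-fold enrichment every planted gene is recovered with no false
calls. `demo/` also receives the per-replicate narrowPeak files, DHS BEDs,
the genome partition, the per-gene stage-pattern and dynamics tables, the
bivalency table, the DEG table and the Fisher overlap matrices, each with
its coordinate convention and config hash in the header. The same steps are
available piecemeal (`simulate`, `callpeaks`, `annotate`, `dynamics`,
`bivalent`, `deg`, `overlap`, `gsea`) and as library functions.

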