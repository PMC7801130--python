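# Methods

## Synthetic data model

The generator produces gene × cell UMI count matrices for 3 donors × 2
product conditions (unstimulated, antigen-stimulated), plus separate
leukapheresis samples, with exact per-cell ground truth.

**Counts.** Each cell's expected expression is built in log space:
log-normal baseline gene weights (σ = 2.0, giving the heavy-tailed expression
distribution of real transcriptomes, where a few genes absorb most of the
library), times a per-donor per-gene log-normal factor (σ = 0.15), times
multiplicative program shifts, renormalized per cell to a log-normal library
size (mean 1,500 UMIs, σ = 0.35) and sampled as gamma–Poisson (negative
binomial, dispersion φ = 0.25, Var = μ + φμ²). Mitochondrial genes (10
``MT-`` features) are pinned to a 5% share of the expected library so QC's
mito-fraction criterion is exercised. Named program genes are forced to a
moderate baseline (~2× the median weight, jittered) so programs act on
detectably expressed genes.

**Populations.** Every planted fraction is allocated exactly by floor +
largest remainder, so configured fractions are reproduced deterministically:

| parameter | default | meaning |
|---|---|---|
| `car_fraction` | 0.225 | product cells carrying the CAR |
| `responder_fraction` | 0.5 | stimulated CAR+ cells switching on the activation program |
| `exhausted_fraction` | 0.07 | responders additionally carrying the exhaustion program |
| `pre_activated_fraction` | 0.07 | unstimulated CAR+ cells already activated |
| `cycling_fraction` | 0.25 | cells given an S or G2/M module (split evenly) |
| `contaminant_fraction` | 0.02 | CD3E⁻ NK-like cells in leukapheresis |

Baseline identity is one of five CD4/CD8 × CCR7/SELL memory programs (8
marker genes each, +2.0 natural-log shift). Responders drop their baseline
program and gain the activation program (13 genes up +1.5, SELL/CD3D/CD3E/
CD3G/B2M down −1.2); exhausted responders additionally gain a 26-gene
exhaustion program (+2.5). CAR+ cells receive CAR UMIs on a ``CAR-3LTR``
pseudo-feature row (NB, mean 5, dispersion 0.1; exhausted cells' mean ×2),
CAR− cells receive 0 — modelling vector-derived transcript detection at the
count level rather than the read level.

The effect sizes are free parameters: no quantitative program effect sizes
are available for the system being emulated, so they were chosen once to make
the planted populations separable by the pipeline's own machinery (markers a
few-fold above baseline, as for real T-cell subset markers), and are exposed
in `SimConfig` rather than claimed as measured values. Default cohort size
(6,316 cells/condition/donor ≈ 37.9k product cells) mirrors the emulated
study; the gene universe (2,000 genes) and library (~1,500 UMIs/cell) are
scaled down ~10× together from full transcriptome depth to keep simulation
tractable; tests run smaller cohorts of the same structure.

**What the simulator does not emulate:** ambient RNA, doublets, batch
chemistry effects, read-level structure (FASTQ), continuous differentiation
gradients between states, or realistic gene–gene correlation beyond the
planted programs. Passing recovery tests therefore demonstrate that the
pipeline's statistics are correctly implemented and calibrated under an
idealized overdispersed-count model — not that they would recover the same
fractions from arbitrary real data.

## Scale-dependent analysis parameters

Two printed parameter sets assume full-scale libraries and are kept as
defaults but must be rescaled on the reduced synthetic universe:

* **HVG mean window** (0.02 < mean < 3 on the cp10k scale): per-gene cp10k
  means are inversely proportional to the universe size, so the synthetic-
  scale configuration widens the ceiling to 30. The window's role (drop
  near-silent and saturated genes) is unchanged.
* **QC floors** (≥400/1,000 genes, >10,000/30,000 UMIs): these presuppose
  deep libraries; `RunConfig.default_synthetic` uses 150–200 genes and
  300–400 UMIs for the ~1,500-UMI synthetic libraries. The boundary
  *semantics* (≥ for genes, strict < for mito fraction, strict > for UMIs)
  are fixed and tested regardless of scale.

## Statistics

**QC.** Three cell criteria applied jointly, then genes with total UMIs < 2
dropped (computed after cell filtering). The report counts per-criterion
failures (overlaps allowed) and the union separately; QC is idempotent.

**Normalization.** Per cell, counts scaled so the cell total equals 10,000
and ln(1+x)-applied. The CAR pseudo-feature is excluded from the per-cell
total (a vector-derived feature is not a cellular transcript for
normalization), and from HVG selection and DE; it is scaled by the same
per-cell factor so CAR-level comparisons remain meaningful.

**HVG selection.** Per batch: per-gene mean and dispersion (variance/mean) of
expm1 expression; genes binned by mean into 20 equal-frequency bins (rank
bins rather than equal-width cuts — stable under heavy-tailed mean
distributions); dispersions z-scored within bins; flagged when inside the
mean window with normalized dispersion ≥ 0.5. Merge across batches: flagged
in ≥ 1 batch, ranked by (batches flagged, median normalized dispersion).

**Regression.** Per-gene OLS on read depth, genes detected, mitochondrial
counts and S/G2M scores, with intercept; residuals feed PCA. Constant
covariates are absorbed by the intercept; genuinely collinear covariates are
an error naming the offending columns.

**Clustering.** PCA component signs are fixed (largest-|loading| gene
positive). The kNN graph (default k = 15; the within-dataset k is not
dictated by the emulated protocol, only the integration k of 7) connects i–j
when either lists the other among its k nearest; edge weight is the shared-
neighbor count / k with each node's neighbor set augmented by itself so
every edge has positive weight. Leiden (RB-configuration modularity, seeded)
or Louvain. The resolution scan reports (resolution, clusters, modularity)
over 0.1–2.0 and suggests the largest resolution within 1% of the maximum
modularity — an automatable proxy; the judgment call between modularity and
biological granularity remains a config override.

**Label transfer.** For each query cell, its 7 nearest reference cells in a
shared PCA space (reference and query concatenated on shared HVGs after
per-dataset cell-cycle regression, then jointly decomposed); the assigned
label is the neighbor mode, ties resolved by the label of the single nearest
tied-label neighbor (deterministic and distance-respecting).

**Differential expression.** Welch's t per gene with two-sided p from the
Welch–Satterthwaite t distribution; BH step-up q across genes. Zero-variance
genes: equal means → t = 0, p = 1; unequal means → p = 0 with a degenerate
flag (never NaN). Conventions fixed here because the emulated analysis does
not print its formulas: log2FC = log2((mean_A+ε)/(mean_B+ε)) of group means
of expm1 expression; base mean = log2(pooled expm1 mean + ε); ε = 1e-9.
"Most upregulated" ranks by ascending q then descending log2FC.

**Signature scoring.** Control genes are drawn per signature gene from its
expression bin (25 rank bins over the gene-mean distribution), 50 per gene,
excluding signature genes, using a generator keyed on (seed, gene id) — so
scores are reproducible and invariant to gene order and to adding a constant
to the matrix. Scores are computed on ln-normalized (not regressed)
expression by default: regression residuals are mean-shifted per gene, which
distorts bin assignment and the fixed 0.6 threshold; a caller may score any
`ExprMatrix`. Classification is strictly score > 0.6. Extreme-cell selection
(top/bottom n by score) breaks ties by barcode order.

**Enrichment.** The hypergeometric upper tail is summed from x to min(k, m)
(the only upper bound making the distribution proper) via log-gamma
binomials. The up/down ratio for significant terms is log2-transformed; a
zero denominator yields a +inf sentinel with a capped plotting value (±6
default), zero/zero is left undefined (NaN).

**Pre-ranked GSEA.** Classic statistic only (+1/n_hits at members,
−1/(n_total−n_hits) elsewhere; the weighted variant is deliberately not
offered); ES is the signed maximum deviation, with an exact tie between the
positive and negative extremes resolving to the positive one. Null: gene-tag
permutation (random same-size sets, seeded). Nominal p is the same-sign null
tail; NES divides by the mean |null ES| of the matching sign; collection FDR
is the standard normalized-null ratio, capped at 1. Size window 15–500 by
default; out-of-window sets are skipped with a reason, not an error. For a
single set, FDR is reported as NaN (it is a collection-level quantity).

**Composition report.** Every percentage is recomputed from its count pair,
never stored; rounding is half-up at the printed precision (integer or one
decimal). The "activated" compartment is detected as all clusters in which
stimulated CAR+ cells form the majority (the responder compartment can split
into a main activated cluster plus small subclusters such as the exhausted
one), falling back to the largest share if none dominates.

## Determinism

Every stochastic stage takes an explicit seed (simulation, control-gene
sampling, Leiden/Louvain, UMAP, GSEA permutations); the pipeline writes a
manifest with SHA-256 hashes of all artifacts, and two runs with identical
config and seed are hash-identical. UMAP coordinates are for visualization
only; nothing downstream consumes them.

## Known limitations

* The packaged exhaustion signature is a synthetic stand-in (canonical
  exhaustion-associated symbols padded to 107 genes), not a published list;
  substitute a real GMT for real data.
* The cell-cycle gene modules are short default S/G2M marker lists,
  configurable via GMT.
* The hypergeometric test, GSEA FDR and composition percentages are exact
  re-implementations of standard procedures, but dataset-level findings of
  any particular study (cluster identities, specific enrichment p-values)
  require that study's data and are out of scope.
* Welch's t on ln-normalized counts is anti-conservative for very small
  groups and zero-inflated genes; the null-calibration test covers the
  default group sizes only.
* `read_10x_mtx` handles MatrixMarket/TSV (v2 and v3, gzipped or plain) but
  not HDF5; conversion upstream is required for .h5 inputs.
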