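# cartography

Single-cell transcriptomic characterization of CAR T-cell products.

CAR (chimeric antigen receptor) T-cell products are heterogeneous mixtures:
only a fraction of cells carry the CAR, only a fraction of those respond to
antigen, and a small minority of responders drift toward T-cell exhaustion — a
dysfunctional state marked by inhibitory receptors (LAG3, HAVCR2/TIM-3,
CTLA4, TIGIT) that matters clinically because exhausted CAR T-cells lose
anti-tumor activity.  `cartography` is a tested, reusable pipeline for
quantifying this structure from droplet scRNA-seq of product and
leukapheresis (starting-material) samples:

* **CAR-expressing cell calling** from a CAR pseudo-feature: transcripts
  mapped to the region upstream of the 3'LTR polyadenylation site of the
  retroviral vector mark transduced cells independently of insertion point; a
  cell is CAR+ when its CAR UMI count ≥ 1.
* **QC, normalization, HVG selection, covariate regression** — cells kept with
  genes detected ≥ *g*, mitochondrial UMI fraction < 8%, total UMIs > *u*;
  counts scaled to 10,000 UMIs per cell and ln(1+x)-transformed; highly
  variable genes by binned normalized dispersion per batch; OLS residuals on
  read depth, gene count, mitochondrial counts and cell-cycle scores.
* **Clustering and label transfer** — PCA (50 components) → kNN graph →
  Leiden/Louvain with a modularity scan over resolutions 0.1–2.0; query cells
  (leukapheresis) are assigned the most frequent cluster among their 7
  nearest reference (product) cells in a shared PCA space, ties broken by the
  nearest tied-label neighbor.
* **Differential expression** — per-gene Welch's *t* with
  Welch–Satterthwaite degrees of freedom, Benjamini–Hochberg adjustment, and
  the three-criterion filter FDR < 0.05, |log2FC| > 1, log2 base mean > −5
  (all strict); top-200 upregulated lists; binary-overlap Ward clustering of
  signatures.
* **Exhaustion scoring** — Tirosh-style binned-control signature scoring:
  score = mean expression of signature genes − mean of expression-matched
  control genes (25 bins, 50 controls/gene, seeded); cells with score > 0.6
  are classified as having high exhaustion potential; the signature is first
  intersected with the dataset's HVGs.
* **Enrichment** — hypergeometric over-representation
  P(X ≥ x) = Σᵢ C(m,i)·C(N−m,k−i)/C(N,k) with BH correction and the
  up/down overlap ratio log2(|up∩term| / |down∩term|); pre-ranked GSEA with
  the classic (unweighted) running-sum statistic, gene-tag permutation null,
  NES, and collection-level FDR, genes ranked by (1/q)·sign(log2FC).
* **Synthetic data** — a first-class negative-binomial simulator that plants
  the cellular structure above (22.5% CAR+, 50% responders, 7% exhausted, 7%
  pre-activated, CD4/CD8 memory programs, cell-cycle modules, donor effects)
  with exact per-cell ground truth for recovery testing.

## Worked example

```python
from cartography.pipeline import RunConfig, run_pipeline

cfg = RunConfig.default_synthetic(seed=5, cells_per_condition_per_donor=500,
                                  n_genes=800)
report = run_pipeline(cfg, "out/")
for name, p in report.percentages.items():
    print(f"{name}: {p['printed']} ({p['count']}/{p['total']})")
```

prints

```
overall_car: 22.4% (664/2970)
unstim_car_in_activated_cluster: 7% (22/332)
exhausted_among_responders: 7% (12/164)
```

Reading the numbers: of the 2,970 post-QC product cells, 664 (22.4%) carry
the CAR — close to the planted 22.5%.  Among unstimulated CAR+ cells, 7%
already sit in the activated cluster (pre-activated before antigen
encounter).  Among stimulated CAR+ cells in the activated compartment — the
antigen responders — 7% are classified as exhausted by the signature score at
threshold 0.6, recovering the planted exhausted fraction.  The same run's
differential expression between responders and non-responding stimulated CAR+
cells returns exactly the 13 planted activation-program genes (IL2RA, MYC,
GZMB, IL2, IL3, IL4, IL5, IL8, IL13, CSF2, CCR4, BATF3, IRF4), and
pre-ranked GSEA gives ES = 1.00 for the activation program (FDR < 0.005).

Every artifact (QC report, CAR summary, cluster labels, resolution scan,
transferred labels, DE tables, exhaustion scores, enrichment and GSEA tables,
composition report) is written as TSV/JSON together with a `manifest.json`
of config, seeds and SHA-256 content hashes; two runs with the same config
and seed are hash-identical.

A CLI mirrors the library:

```bash
cartography simulate --seed 0 --outdir sim/          # 10X-style directory + truth
cartography run --seed 0 --outdir out/               # full pipeline
cartography score --indir sim/ --out scores.tsv      # exhaustion scoring only
```

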