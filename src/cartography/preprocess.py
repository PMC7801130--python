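"""QC filtering, CAR+ cell calling, normalization, HVGs, regression, cell cycle.

Quality control keeps cells with *at least* ``min_genes_per_cell`` genes
detected, *less than* ``max_mito_fraction`` of UMIs in mitochondrial genes and
*more than* ``min_total_umis`` total UMIs (boundary semantics follow that
wording literally), then drops genes with fewer than ``min_gene_total_umis``
total UMIs computed after cell filtering.  Normalization scales each cell to
``target_sum`` UMIs (excluding the CAR pseudo-feature) and applies ln(1+x).
Highly variable genes are selected per batch by binned normalized dispersion
and merged across batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import (
    CAR_FEATURE_ID,
    ConfigError,
    CountMatrix,
    ExprMatrix,
    GeneSet,
    IntegrityError,
)

logger = logging.getLogger(__name__)

#: features excluded from per-cell totals, HVG selection and DE
DEFAULT_EXCLUDE = (CAR_FEATURE_ID,)


@dataclass
class QCThresholds:
    """Cell/gene QC cutoffs.

    Defaults are the product-sample values; :meth:`leukapheresis` gives the
    starting-material values.  Semantics: genes detected >= min_genes_per_cell,
    mito fraction < max_mito_fraction (strict), total UMIs > min_total_umis
    (strict), gene kept if total UMIs >= min_gene_total_umis.
    """

    min_genes_per_cell: int = 1000
    max_mito_fraction: float = 0.08
    min_total_umis: int = 30000
    min_gene_total_umis: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ConfigError("max_mito_fraction must be in [0, 1]")
        if min(self.min_genes_per_cell, self.min_total_umis, self.min_gene_total_umis) < 0:
            raise ConfigError("QC thresholds must be non-negative")

    @classmethod
    def product(cls) -> "QCThresholds":
        return cls(min_genes_per_cell=1000, min_total_umis=30000)

    @classmethod
    def leukapheresis(cls) -> "QCThresholds":
        return cls(min_genes_per_cell=400, min_total_umis=10000)


@dataclass
class HVGParams:
    """Mean/dispersion cutoffs for highly-variable-gene selection."""

    min_mean: float = 0.02
    max_mean: float = 3.0
    min_disp: float = 0.5
    n_bins: int = 20
    batch_key: str = "sample_id"

    def __post_init__(self) -> None:
        if self.min_mean >= self.max_mean:
            raise ConfigError("min_mean must be < max_mean")


@dataclass
class QCReport:
    cells_in: int
    cells_removed_by_criterion: dict
    cells_out: int
    genes_in: int
    genes_out: int
    union_removed: int = 0

    def to_dict(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_removed_by_criterion": dict(self.cells_removed_by_criterion),
            "union_removed": self.union_removed,
            "cells_out": self.cells_out,
            "genes_in": self.genes_in,
            "genes_out": self.genes_out,
        }


def mito_mask(m: CountMatrix, mito_genes: "GeneSet | None" = None,
              prefix: str = "MT-") -> np.ndarray:
    """Boolean gene mask of mitochondrial genes (explicit set or symbol prefix)."""
    if mito_genes is not None:
        ids = set(m.resolve_symbols(mito_genes.genes, missing="drop"))
        return np.array([g in ids for g in m.gene_ids])
    return np.array([str(n).startswith(prefix) for n in m.gene_names])


def apply_qc(
    m: CountMatrix,
    t: QCThresholds,
    mito_genes: "GeneSet | None" = None,
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, QCReport]:
    """Filter cells by the three QC criteria, then drop low-count genes."""
    counts = sp.csc_matrix(m.counts)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    genes_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = mito_mask(m, mito_genes, mito_prefix)
    mito_counts = np.asarray(counts[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    fail_genes = genes_detected < t.min_genes_per_cell
    fail_mito = mito_frac >= t.max_mito_fraction
    fail_umis = totals <= t.min_total_umis
    keep_cells = ~(fail_genes | fail_mito | fail_umis)

    report = QCReport(
        cells_in=m.n_cells,
        cells_removed_by_criterion={
            "min_genes_per_cell": int(fail_genes.sum()),
            "max_mito_fraction": int(fail_mito.sum()),
            "min_total_umis": int(fail_umis.sum()),
        },
        union_removed=int((~keep_cells).sum()),
        cells_out=int(keep_cells.sum()),
        genes_in=m.n_genes,
        genes_out=0,
    )
    if report.cells_out == 0:
        warnings.warn("QC removed all cells; returning an empty CountMatrix")
    filtered = m.subset_cells(keep_cells)
    gene_totals = np.asarray(filtered.counts.sum(axis=1)).ravel()
    keep_genes = gene_totals >= t.min_gene_total_umis
    filtered = filtered.subset_genes(keep_genes)
    report.genes_out = filtered.n_genes
    return filtered, report


def detect_car_cells(
    m: CountMatrix,
    car_feature_id: str = CAR_FEATURE_ID,
    min_car_umis: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag CAR-expressing cells (CAR UMIs >= ``min_car_umis``).

    Returns the per-cell boolean mask plus a summary table of CAR+ counts and
    percentages overall and per sample.
    """
    try:
        gi = m.gene_index(car_feature_id)
    except KeyError as err:
        raise KeyError(f"CAR feature {car_feature_id!r} not present in matrix") from err
    car_umis = np.asarray(m.counts[gi, :].todense()).ravel()
    mask = car_umis >= min_car_umis
    groups = (
        m.cell_meta["sample_id"]
        if "sample_id" in m.cell_meta.columns
        else pd.Series("all", index=m.cell_meta.index)
    )
    rows = [("all", m.n_cells, int(mask.sum()))]
    for s, idx in pd.Series(np.arange(m.n_cells), index=groups).groupby(level=0, observed=True):
        sel = idx.to_numpy()
        rows.append((s, len(sel), int(mask[sel].sum())))
    summary = pd.DataFrame(rows, columns=["sample", "n_cells", "n_car_positive"])
    summary["pct_car_positive"] = 100.0 * summary["n_car_positive"] / summary["n_cells"].clip(lower=1)
    return mask, summary


def normalize_log(
    m: CountMatrix,
    target_sum: float = 10000.0,
    exclude_features: tuple = DEFAULT_EXCLUDE,
) -> ExprMatrix:
    """Scale each cell to ``target_sum`` UMIs then apply ln(1+x).

    The CAR pseudo-feature (and any other excluded feature) does not count
    toward the per-cell total; its values are scaled by the same per-cell
    factor as the cellular transcripts.  Cells with a zero total (excluding
    the excluded features) are dropped with a warning.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ConfigError("cannot normalize an empty matrix")
    excl = np.array([g in set(exclude_features) for g in m.gene_ids])
    counts = sp.csc_matrix(m.counts, dtype=np.float64)
    totals = np.asarray(counts[~excl, :].sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zero-total cells before normalization")
        m = m.subset_cells(~zero)
        counts = sp.csc_matrix(m.counts, dtype=np.float64)
        totals = totals[~zero]
    scale = target_sum / totals
    vals = counts.multiply(sp.csr_matrix(scale[None, :])).tocsr()
    vals.data = np.log1p(vals.data)
    return ExprMatrix(
        values=vals,
        gene_ids=m.gene_ids,
        gene_names=m.gene_names,
        barcodes=m.barcodes,
        cell_meta=m.cell_meta,
        transform_log=[f"cp{int(target_sum)}", "log1p"],
    )


def _dispersion_stats(values, cell_idx: np.ndarray):
    """Per-gene mean and dispersion (var/mean) of expm1(expression)."""
    sub = values[:, cell_idx]
    if sp.issparse(sub):
        sub = sub.copy()
        sub.data = np.expm1(sub.data)
        mean = np.asarray(sub.mean(axis=1)).ravel()
        sq = np.asarray(sub.multiply(sub).mean(axis=1)).ravel()
    else:
        sub = np.expm1(sub)
        mean = sub.mean(axis=1)
        sq = (sub**2).mean(axis=1)
    n = len(cell_idx)
    var = (sq - mean**2) * n / max(n - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    return mean, disp


def select_hvgs(
    e: ExprMatrix,
    p: "HVGParams | None" = None,
    exclude_features: tuple = DEFAULT_EXCLUDE,
) -> list[str]:
    """Highly variable genes per batch, merged across batches.

    Per batch: genes are binned into ``n_bins`` equal-frequency bins of mean
    expm1 expression; dispersions are z-scored within bins; a gene is flagged
    when ``min_mean < mean < max_mean`` and normalized dispersion >=
    ``min_disp``.  Merge rule: flagged in at least one batch, ranked by
    (number of batches flagged, median normalized dispersion).
    """
    p = p or HVGParams()
    if p.batch_key in e.cell_meta.columns:
        batches = e.cell_meta[p.batch_key].astype(str)
    else:
        batches = pd.Series("all", index=e.cell_meta.index)
    excl = np.array([g in set(exclude_features) for g in e.gene_ids])
    n_genes = e.n_genes
    flagged = np.zeros(n_genes, dtype=int)
    norm_disps: list[np.ndarray] = []
    for b, idx in pd.Series(np.arange(e.n_cells), index=batches.to_numpy()).groupby(level=0):
        cell_idx = idx.to_numpy()
        if len(cell_idx) < 2:
            warnings.warn(f"batch {b!r} has fewer than 2 cells; skipped")
            continue
        mean, disp = _dispersion_stats(e.values, cell_idx)
        order = np.argsort(mean, kind="stable")
        bin_of = np.empty(n_genes, dtype=int)
        bin_of[order] = np.arange(n_genes) * p.n_bins // n_genes
        z = np.zeros(n_genes)
        for bi in range(p.n_bins):
            members = bin_of == bi
            if members.sum() < 2:
                continue
            mu, sd = disp[members].mean(), disp[members].std(ddof=1)
            if sd > 0:
                z[members] = (disp[members] - mu) / sd
        ok = (mean > p.min_mean) & (mean < p.max_mean) & (z >= p.min_disp) & ~excl
        flagged += ok.astype(int)
        norm_disps.append(z)
    if not norm_disps:
        raise ConfigError("no batch with >= 2 cells; cannot select HVGs")
    median_z = np.median(np.vstack(norm_disps), axis=0)
    hv = np.flatnonzero(flagged > 0)
    order = hv[np.lexsort((-median_z[hv], -flagged[hv]))]
    return [e.gene_ids[i] for i in order]


def regress_out(e: ExprMatrix, covariates: pd.DataFrame) -> ExprMatrix:
    """Per-gene OLS of expression on covariates (with intercept); residuals."""
    if len(covariates) != e.n_cells:
        raise IntegrityError("covariate table must have one row per cell")
    if covariates.isna().any().any():
        raise IntegrityError("covariates contain missing values")
    # constant covariates are absorbed by the intercept
    keep = [c for c in covariates.columns if covariates[c].nunique() > 1]
    X = np.column_stack([np.ones(e.n_cells), covariates[keep].to_numpy(dtype=float)])
    names = ["intercept", *keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = [X[:, 0]]
        for j in range(1, X.shape[1]):
            trial = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(names[j])
            else:
                cols.append(X[:, j])
        raise IntegrityError(f"rank-deficient covariates: {bad}")
    Y = e.dense().T  # cells x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    return ExprMatrix(
        values=resid,
        gene_ids=e.gene_ids,
        gene_names=e.gene_names,
        barcodes=e.barcodes,
        cell_meta=e.cell_meta,
        transform_log=list(e.transform_log) + [f"regress_out({list(covariates.columns)})"],
    )


def standard_covariates(m: CountMatrix, e: ExprMatrix,
                        mito_genes: "GeneSet | None" = None) -> pd.DataFrame:
    """Read depth, genes detected and mitochondrial counts per cell, aligned
    to the cells of ``e`` (the usual technical covariates to regress out)."""
    counts = sp.csc_matrix(m.counts)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = mito_mask(m, mito_genes)
    mito_counts = np.asarray(counts[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros(m.n_cells)
    df = pd.DataFrame(
        {"total_umis": totals, "n_genes": n_genes, "mito_counts": mito_counts},
        index=pd.Index(m.barcodes, name="barcode"),
    )
    return df.loc[e.barcodes]


def cellcycle_score(
    e: ExprMatrix,
    s_genes: GeneSet,
    g2m_genes: GeneSet,
    params=None,
) -> pd.DataFrame:
    """S and G2M signature scores per cell plus the inferred stage.

    Stage is the argmax of (S, G2M) when either score is positive, else G1;
    ties at zero resolve to G1.
    """
    from .signatures import ScoreParams, score_signature

    params = params or ScoreParams()
    present = set(e.gene_ids)
    s_in = [g for g in s_genes.genes if g in present]
    g2m_in = [g for g in g2m_genes.genes if g in present]
    if not s_in and not g2m_in:
        raise ConfigError("neither S nor G2M genes are present in the matrix")
    s_score = (
        score_signature(e, GeneSet("S", s_in), params)
        if s_in else np.zeros(e.n_cells)
    )
    g2m_score = (
        score_signature(e, GeneSet("G2M", g2m_in), params)
        if g2m_in else np.zeros(e.n_cells)
    )
    stage = np.full(e.n_cells, "G1", dtype=object)
    pos = (s_score > 0) | (g2m_score > 0)
    stage[pos & (s_score >= g2m_score)] = "S"
    stage[pos & (g2m_score > s_score)] = "G2M"
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "stage": stage},
        index=pd.Index(e.barcodes, name="barcode"),
    )
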