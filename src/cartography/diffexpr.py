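"""Two-group differential expression with Welch's t-test and the three-criterion filter.

Per gene, an unequal-variance t statistic with Welch-Satterthwaite degrees of
freedom gives a two-sided p-value; p-values are Benjamini-Hochberg adjusted
across genes.  Genes count as differentially expressed only when all of
FDR < ``max_fdr``, |log2 fold change| > ``min_abs_log2fc`` and base mean
expression > ``min_log2_mean`` hold (strict inequalities).

Conventions (the source analyses do not print their formulas, so these are
fixed here): log2 fold change is log2((meanA + eps) / (meanB + eps)) of group
means of expm1(ln-normalized expression); base mean expression is log2 of the
pooled mean of expm1 expression plus eps, with eps = 1e-9.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import ConfigError, ExprMatrix

EPS = 1e-9

DE_COLUMNS = ["gene_id", "log2fc", "log2_mean", "t", "p", "q", "degenerate"]


@dataclass
class DEFilter:
    """The three-criterion differential-expression filter."""

    max_fdr: float = 0.05
    min_abs_log2fc: float = 1.0
    min_log2_mean: float = -5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_fdr <= 1.0:
            raise ConfigError("max_fdr must be in (0, 1]")


def _group_stats(values, idx: np.ndarray):
    sub = values[:, idx]
    n = len(idx)
    if sp.issparse(sub):
        mean = np.asarray(sub.mean(axis=1)).ravel()
        sq = np.asarray(sub.multiply(sub).mean(axis=1)).ravel()
    else:
        sub = np.asarray(sub)
        mean = sub.mean(axis=1)
        sq = (sub**2).mean(axis=1)
    var = np.maximum(sq - mean**2, 0.0) * n / (n - 1)
    return mean, var, n


def _expm1_means(values, idx: np.ndarray) -> np.ndarray:
    sub = values[:, idx]
    if sp.issparse(sub):
        sub = sub.copy()
        sub.data = np.expm1(sub.data)
        return np.asarray(sub.mean(axis=1)).ravel()
    return np.expm1(np.asarray(sub)).mean(axis=1)


def welch_ttest_by_gene(
    e: ExprMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> pd.DataFrame:
    """Welch's t-test per gene between two disjoint cell groups.

    ``group_a``/``group_b`` are boolean masks or integer indices over cells.
    Returns a DataFrame with columns ``gene_id, log2fc, log2_mean, t, p, q,
    degenerate`` (q is BH-adjusted across all genes tested).  Zero-variance
    genes: equal means give t=0, p=1; unequal means give p=0 and the
    degenerate flag.
    """
    a = _as_index(group_a, e.n_cells)
    b = _as_index(group_b, e.n_cells)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs at least 2 cells")
    if np.intersect1d(a, b).size:
        raise ConfigError("groups overlap")

    mean_a, var_a, na = _group_stats(e.values, a)
    mean_b, var_b, nb = _group_stats(e.values, b)
    se2 = var_a / na + var_b / nb
    diff = mean_a - mean_b
    degenerate = (se2 == 0) & (diff != 0)
    equal_flat = (se2 == 0) & (diff == 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
        )
    t = np.where(equal_flat, 0.0, t)
    p = np.ones(e.n_genes)
    ok = ~(degenerate | equal_flat)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[degenerate] = 0.0
    t[degenerate] = np.sign(diff[degenerate]) * np.inf

    em_a = _expm1_means(e.values, a)
    em_b = _expm1_means(e.values, b)
    log2fc = np.log2((em_a + EPS) / (em_b + EPS))
    pooled = (em_a * na + em_b * nb) / (na + nb)
    log2_mean = np.log2(pooled + EPS)

    out = pd.DataFrame(
        {
            "gene_id": e.gene_ids,
            "log2fc": log2fc,
            "log2_mean": log2_mean,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
            "degenerate": degenerate,
        }
    )
    out.attrs["group_sizes"] = (na, nb)
    return out


def _as_index(group, n: int) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        if group.size != n:
            raise ConfigError("boolean group mask length must equal n_cells")
        return np.flatnonzero(group)
    return group.astype(int)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ConfigError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def apply_de_filter(results: pd.DataFrame, f: "DEFilter | None" = None):
    """Split DE results into up- and down-regulated gene tables."""
    f = f or DEFilter()
    sig = (results["q"] < f.max_fdr) & (results["log2_mean"] > f.min_log2_mean)
    up = results[sig & (results["log2fc"] > f.min_abs_log2fc)]
    down = results[sig & (results["log2fc"] < -f.min_abs_log2fc)]
    return up.reset_index(drop=True), down.reset_index(drop=True)


def top_upregulated(results: pd.DataFrame, n: int = 200) -> list[str]:
    """The n most upregulated genes: ascending q, then descending log2fc."""
    pos = results[results["log2fc"] > 0]
    ranked = pos.sort_values(["q", "log2fc"], ascending=[True, False], kind="stable")
    if len(ranked) < n:
        warnings.warn(f"only {len(ranked)} upregulated genes available (requested {n})")
    return ranked["gene_id"].head(n).tolist()


def overlap_cluster(
    gene_lists: "dict[str, list[str]]",
    n_groups: int = 5,
):
    """Binary-overlap hierarchical clustering of upregulated gene lists.

    Each gene of the union becomes a 0/1 membership vector over the lists;
    Ward linkage on Euclidean distances groups both genes (rows) and lists
    (columns); the gene dendrogram is cut into ``n_groups`` flat groups.

    Returns ``(membership, gene_linkage, list_linkage, flat_groups)`` where
    ``membership`` is a genes x lists DataFrame and ``flat_groups`` maps group
    number to the genes it contains.
    """
    if len(gene_lists) < 2:
        raise ConfigError("need at least 2 gene lists")
    names = list(gene_lists)
    union: dict[str, None] = {}
    for lst in gene_lists.values():
        for g in lst:
            union.setdefault(g)
    genes = list(union)
    mat = np.zeros((len(genes), len(names)), dtype=float)
    for j, name in enumerate(names):
        members = set(gene_lists[name])
        for i, g in enumerate(genes):
            if g in members:
                mat[i, j] = 1.0
    membership = pd.DataFrame(mat, index=genes, columns=names)
    gene_linkage = linkage(mat, method="ward") if len(genes) > 1 else None
    list_linkage = linkage(mat.T, method="ward") if len(names) > 1 else None
    if gene_linkage is None:
        flat = {1: genes}
    else:
        labels = fcluster(gene_linkage, t=min(n_groups, len(genes)), criterion="maxclust")
        flat = {}
        for g, lab in zip(genes, labels):
            flat.setdefault(int(lab), []).append(g)
    return membership, gene_linkage, list_linkage, flat
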