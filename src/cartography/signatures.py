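"""Gene-signature scoring with binned control genes and exhaustion calling.

The score of a cell for a signature is the mean expression of the signature
genes minus the mean expression of a matched control set: all genes are
ranked by average expression across cells and split into ``n_bins``
equal-frequency bins, and for every signature gene ``ctrl_per_gene`` control
genes are sampled (seeded) from the same bin, excluding signature genes.
Cells with a score strictly above the threshold (default 0.6) are called as
having high exhaustion potential.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ConfigError, ExprMatrix, GeneSet

#: features never used as signature or control genes
from .preprocess import DEFAULT_EXCLUDE


@dataclass
class ScoreParams:
    """Binned-control scoring parameters."""

    n_bins: int = 25
    ctrl_per_gene: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.ctrl_per_gene < 1:
            raise ConfigError("n_bins and ctrl_per_gene must be >= 1")


@dataclass
class ExhaustionCall:
    """Per-cell exhaustion scores and boolean calls at a strict threshold."""

    scores: np.ndarray
    exhausted: np.ndarray
    signature_used: GeneSet
    threshold: float = 0.6

    def summary(self, meta: pd.DataFrame, by: list[str]) -> pd.DataFrame:
        """Counts and percentages of exhausted cells per metadata stratum."""
        df = meta.copy()
        df["exhausted"] = self.exhausted
        out = (
            df.groupby(by, observed=True)["exhausted"]
            .agg(n_cells="size", n_exhausted="sum")
            .reset_index()
        )
        out["pct_exhausted"] = 100.0 * out["n_exhausted"] / out["n_cells"].clip(lower=1)
        return out


def intersect_signature(sig: GeneSet, hvgs: "list[str]") -> GeneSet:
    """Restrict a signature to the genes present in the HVG list (order kept)."""
    hv = set(hvgs)
    genes = [g for g in sig.genes if g in hv]
    if not genes:
        raise ConfigError(
            f"signature {sig.name!r} has no overlap with the HVG list; "
            "review HVG thresholds or supply another signature"
        )
    return GeneSet(name=sig.name, genes=genes, description=sig.description)


def _mean_over_genes(values, rows: np.ndarray) -> np.ndarray:
    sub = values[rows, :]
    if sp.issparse(sub):
        return np.asarray(sub.mean(axis=0)).ravel()
    return np.asarray(sub).mean(axis=0)


def score_signature(
    e: ExprMatrix,
    sig: GeneSet,
    p: "ScoreParams | None" = None,
    exclude_features: tuple = DEFAULT_EXCLUDE,
) -> np.ndarray:
    """Binned-control signature score per cell (deterministic given seed)."""
    p = p or ScoreParams()
    usable = np.array([g not in set(exclude_features) for g in e.gene_ids])
    gene_pos = {g: i for i, g in enumerate(e.gene_ids)}
    sig_idx = np.array([gene_pos[g] for g in sig.genes if g in gene_pos], dtype=int)
    sig_idx = sig_idx[usable[sig_idx]]
    if sig_idx.size == 0:
        raise ConfigError(f"no gene of signature {sig.name!r} present in the matrix")

    pool = np.flatnonzero(usable)
    means = _gene_means(e.values)[pool]
    pool_names = e.gene_ids[pool].astype(str)
    # equal-frequency bins on the rank of the mean (ties broken by gene id):
    # invariant to adding a constant to every entry and to gene order
    order = np.lexsort((pool_names, means))
    bin_of_pool = np.empty(pool.size, dtype=int)
    bin_of_pool[order] = np.arange(pool.size) * p.n_bins // pool.size
    bin_of = dict(zip(pool, bin_of_pool))

    sig_set = set(sig_idx.tolist())
    ctrl: set[int] = set()
    by_bin: dict[int, np.ndarray] = {}
    for b in range(p.n_bins):
        members = [i for i in pool[bin_of_pool == b] if i not in sig_set]
        # canonical candidate order so sampling ignores matrix gene order
        members.sort(key=lambda i: str(e.gene_ids[i]))
        by_bin[b] = np.array(members, dtype=int)
    for gi in sig_idx:
        candidates = by_bin[bin_of[gi]]
        # per-gene generator keyed on (seed, gene id) so each signature
        # gene's controls are independent of signature and gene order
        rng = np.random.default_rng(
            [p.seed, zlib.crc32(str(e.gene_ids[gi]).encode())]
        )
        if candidates.size == 0:
            warnings.warn(f"bin of gene {e.gene_ids[gi]!r} has no control candidates")
            continue
        if candidates.size < p.ctrl_per_gene:
            warnings.warn(
                f"bin of gene {e.gene_ids[gi]!r} smaller than ctrl_per_gene; "
                "sampling with replacement"
            )
            picked = rng.choice(candidates, size=p.ctrl_per_gene, replace=True)
        else:
            picked = rng.choice(candidates, size=p.ctrl_per_gene, replace=False)
        ctrl.update(picked.tolist())
    if not ctrl:
        raise ConfigError("empty control set; matrix too small for these parameters")
    ctrl_idx = np.fromiter(sorted(ctrl), dtype=int)
    return _mean_over_genes(e.values, sig_idx) - _mean_over_genes(e.values, ctrl_idx)


def _gene_means(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.mean(axis=1)).ravel()
    return np.asarray(values).mean(axis=1)


def classify_exhausted(
    scores: np.ndarray,
    threshold: float = 0.6,
    signature_used: "GeneSet | None" = None,
) -> ExhaustionCall:
    """Call cells exhausted when score > threshold (strict inequality)."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ConfigError("scores must be finite")
    return ExhaustionCall(
        scores=scores,
        exhausted=scores > threshold,
        signature_used=signature_used or GeneSet("unspecified", ["NA"]),
        threshold=threshold,
    )


def select_extremes(
    scores: np.ndarray,
    cell_mask: np.ndarray,
    barcodes: np.ndarray,
    n: int = 153,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the top-n and bottom-n cells by score within a mask.

    Ties are broken by barcode lexicographic order, making the selection
    deterministic.  If the mask holds fewer than 2n cells, n is reduced to
    floor(mask size / 2) with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    barcodes = np.asarray(barcodes, dtype=object)
    cell_mask = np.asarray(cell_mask)
    idx = np.flatnonzero(cell_mask) if cell_mask.dtype == bool else cell_mask
    if idx.size == 0:
        raise ConfigError("empty cell mask")
    if idx.size < 2 * n:
        n = idx.size // 2
        warnings.warn(f"mask smaller than 2n; n reduced to {n}")
    bc = barcodes[idx].astype(str)
    asc = idx[np.lexsort((bc, scores[idx]))]       # score asc, barcode asc
    desc = idx[np.lexsort((bc, -scores[idx]))]     # score desc, barcode asc
    return desc[:n], asc[:n]
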