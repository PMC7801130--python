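"""Over-representation statistics and pre-ranked GSEA with the classic statistic.

Over-representation of a term is the hypergeometric upper tail

    P(X >= x) = sum_{i=x}^{min(k, m)} C(m, i) C(N-m, k-i) / C(N, k)

with N the universe of expressed genes, m the term size, k the number of up-
(or down-) regulated genes and x their overlap; computed with log-gamma
binomials for numerical stability and BH-adjusted across terms.  For
significant terms the up/down ratio log2(|up ∩ term| / |down ∩ term|) is
reported (infinite values carry a sign sentinel and a capped plotting value).

Pre-ranked GSEA uses the unweighted ("classic") running sum: +1/n_hits at set
members, -1/(n_total - n_hits) elsewhere; ES is the signed maximum deviation.
The null is gene-tag permutation (random same-size sets); NES divides ES by
the mean |null ES| of the same sign, and the collection-level FDR follows the
standard normalized-null procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core_io import ConfigError, GeneSet
from .diffexpr import bh_adjust

Q_FLOOR = 1e-300


@dataclass
class HypergeomInput:
    """Counts for the over-representation test; see module docstring."""

    N: int
    m: int
    k: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.m, self.k)):
            raise ConfigError(f"x={self.x} outside [0, min(m, k)]")
        if self.m > self.N or self.k > self.N:
            raise ConfigError("m and k cannot exceed N")
        if min(self.N, self.m, self.k) < 0:
            raise ConfigError("counts must be non-negative")


def _log_binom(n: int, r: int) -> float:
    return lgamma(n + 1) - lgamma(r + 1) - lgamma(n - r + 1)


def hypergeom_upper_pval(h: HypergeomInput) -> float:
    """Upper-tail P(X >= x) of the hypergeometric distribution (log-gamma)."""
    hi = min(h.k, h.m)
    lo = max(h.x, h.k - (h.N - h.m))
    if h.x <= max(0, h.k - (h.N - h.m)):
        return 1.0
    denom = _log_binom(h.N, h.k)
    terms = [
        _log_binom(h.m, i) + _log_binom(h.N - h.m, h.k - i) - denom
        for i in range(lo, hi + 1)
    ]
    if not terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(terms))))


def enrich_terms(
    up: "list[str]",
    down: "list[str]",
    terms: "list[GeneSet]",
    universe: "list[str]",
    fdr: float = 0.05,
    ratio_cap: float = 6.0,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the up list.

    Also reports the down-list overlap and, for significant terms
    (BH q < ``fdr``), the up/down log2 ratio with infinity sentinels when the
    denominator (or numerator) overlap is zero.
    """
    if not terms:
        raise ConfigError("no terms supplied")
    uni = set(universe)
    up_s = set(up) & uni
    down_s = set(down) & uni
    if len(up_s) != len(set(up)) or len(down_s) != len(set(down)):
        raise ConfigError("up/down gene lists must be subsets of the universe")
    N = len(uni)
    rows = []
    for term in terms:
        tg = set(term.genes) & uni
        restricted = len(term.genes) - len(tg)
        x_up = len(up_s & tg)
        x_down = len(down_s & tg)
        p = hypergeom_upper_pval(HypergeomInput(N=N, m=len(tg), k=len(up_s), x=x_up)) if tg else 1.0
        rows.append((term.name, N, len(tg), len(up_s), x_up, x_down, restricted, p))
    out = pd.DataFrame(
        rows, columns=["term", "N", "m", "k", "x", "x_down", "restricted_genes", "p_value"]
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < fdr
    ratio = np.full(len(out), np.nan)
    capped = np.full(len(out), np.nan)
    for i, (x_up, x_down) in enumerate(zip(out["x"], out["x_down"])):
        if x_up == 0 and x_down == 0:
            continue  # undefined; stays NaN (term annotated by the NaN)
        if x_down == 0:
            ratio[i], capped[i] = np.inf, ratio_cap
        elif x_up == 0:
            ratio[i], capped[i] = -np.inf, -ratio_cap
        else:
            r = np.log2(x_up / x_down)
            ratio[i] = r
            capped[i] = float(np.clip(r, -ratio_cap, ratio_cap))
    out["updown_log2_ratio"] = ratio
    out["updown_log2_ratio_capped"] = capped
    return out


def rank_genes_for_gsea(results: pd.DataFrame) -> pd.DataFrame:
    """Ranking score (1 / adjusted p) * sign(log2FC), descending.

    q-values are clipped below at 1e-300; genes with log2FC exactly 0 score 0
    and land mid-list.
    """
    q = np.clip(results["q"].to_numpy(dtype=float), Q_FLOOR, None)
    score = (1.0 / q) * np.sign(results["log2fc"].to_numpy(dtype=float))
    out = pd.DataFrame({"gene_id": results["gene_id"], "score": score})
    return out.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


@dataclass
class GseaResult:
    gene_set: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    n_perm: int
    seed: int
    size: int
    leading_edge: list = field(default_factory=list)
    skipped: "str | None" = None


def _running_es(n_total: int, hit_pos: np.ndarray) -> tuple[float, int]:
    """Signed maximum deviation of the classic running sum and its position."""
    n_hits = hit_pos.size
    n_miss = n_total - n_hits
    delta = np.full(n_total, -1.0 / n_miss)
    delta[hit_pos] = 1.0 / n_hits
    rs = np.cumsum(delta)
    i_max = int(np.argmax(rs))
    i_min = int(np.argmin(rs))
    if abs(rs[i_max]) >= abs(rs[i_min]):
        return float(rs[i_max]), i_max
    return float(rs[i_min]), i_min


def gsea_preranked(
    ranked: "list[str]",
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> GseaResult:
    """Classic pre-ranked GSEA of one gene set against an ordered gene list."""
    pos_of = {g: i for i, g in enumerate(ranked)}
    hit_pos = np.sort([pos_of[g] for g in gene_set.genes if g in pos_of])
    size = hit_pos.size
    base = GseaResult(
        gene_set=gene_set.name, es=np.nan, nes=np.nan, nominal_p=np.nan,
        fdr_q=np.nan, n_perm=n_perm, seed=seed, size=size,
    )
    if size < min_size or size > max_size:
        base.skipped = f"set size {size} outside [{min_size}, {max_size}]"
        return base
    n = len(ranked)
    if size >= n:
        base.skipped = "set covers the whole ranking"
        return base
    es, i_ext = _running_es(n, hit_pos)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = np.sort(rng.choice(n, size=size, replace=False))
        null[j], _ = _running_es(n, perm)
    same_sign = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, dtype=bool)
    n_same = max(int(same_sign.sum()), 1)
    nominal_p = float((np.abs(null[same_sign]) >= abs(es)).sum()) / n_same
    mean_same = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
    nes = float(es / mean_same) if mean_same and np.isfinite(mean_same) else np.nan
    if es >= 0:
        leading = [ranked[i] for i in hit_pos[hit_pos <= i_ext]]
    else:
        leading = [ranked[i] for i in hit_pos[hit_pos >= i_ext]]
    return GseaResult(
        gene_set=gene_set.name, es=es, nes=nes, nominal_p=nominal_p,
        fdr_q=np.nan, n_perm=n_perm, seed=seed, size=size,
        leading_edge=leading,
    )


def gsea_collection(
    ranked: "list[str]",
    gene_sets: "list[GeneSet]",
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """GSEA over a collection with the standard normalized-null FDR.

    For each set the null ES distribution is normalized the same way as the
    observed ES (divided by the mean |null ES| of the matching sign); FDR q of
    a set is the fraction of pooled normalized null NES at least as extreme
    (same sign) divided by the fraction of observed NES at least as extreme,
    capped at 1.
    """
    results: list[GseaResult] = []
    null_nes_pool: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    pos_of = {g: i for i, g in enumerate(ranked)}
    n = len(ranked)
    for gs in gene_sets:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = gsea_preranked(ranked, gs, n_perm=n_perm, seed=sub_seed,
                             min_size=min_size, max_size=max_size)
        results.append(res)
        if res.skipped:
            continue
        size = res.size
        sub_rng = np.random.default_rng(sub_seed)
        null = np.empty(n_perm)
        for j in range(n_perm):
            perm = np.sort(sub_rng.choice(n, size=size, replace=False))
            null[j], _ = _running_es(n, perm)
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        norm = np.where(null > 0, null / pos_mean, null / neg_mean)
        null_nes_pool.append(norm[np.isfinite(norm)])
    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.empty(0)
    obs = np.array([r.nes for r in results if not r.skipped and np.isfinite(r.nes)])
    for r in results:
        if r.skipped or not np.isfinite(r.nes) or pool.size == 0:
            continue
        if r.nes >= 0:
            num_pool = pool[pool >= 0]
            frac_null = (num_pool >= r.nes).mean() if num_pool.size else 1.0
            same_obs = obs[obs >= 0]
            frac_obs = (same_obs >= r.nes).mean() if same_obs.size else 1.0
        else:
            num_pool = pool[pool <= 0]
            frac_null = (num_pool <= r.nes).mean() if num_pool.size else 1.0
            same_obs = obs[obs <= 0]
            frac_obs = (same_obs <= r.nes).mean() if same_obs.size else 1.0
        r.fdr_q = float(min(1.0, frac_null / max(frac_obs, 1e-12)))
    return pd.DataFrame(
        [
            {
                "gene_set": r.gene_set, "es": r.es, "nes": r.nes,
                "nominal_p": r.nominal_p, "fdr_q": r.fdr_q, "size": r.size,
                "n_perm": r.n_perm, "skipped": r.skipped,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ]
    )
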