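"""Multi-donor, multi-condition synthetic CAR-T count matrices with planted truth.

The generator emulates the cellular structure of a CAR T-cell product study:

* 3 donors, each contributing an unstimulated and an antigen-stimulated
  product sample (plus separate leukapheresis samples);
* ~22.5% of product cells carry the CAR, detectable through a ``CAR-3LTR``
  pseudo-feature row holding vector-derived UMIs;
* upon stimulation ~50% of CAR-expressing cells switch on an activation
  program (the "responders"), and ~7% of responders additionally carry an
  exhaustion program with elevated CAR UMIs; ~7% of unstimulated
  CAR-expressing cells are activated prior to antigen encounter;
* baseline cluster structure is driven by CD4/CD8 identity and CCR7/SELL
  memory-marker programs, with S/G2M cell-cycle modules on a configurable
  fraction of cells.

Counts are negative binomial (gamma-Poisson) around per-cell means built from
log-normal baseline gene weights, per-donor multiplicative log-normal effects,
a log-normal library-size factor, and multiplicative program shifts.  All
planted fractions are allocated exactly (floor + largest remainder) and every
draw flows from a single seeded generator, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CAR_FEATURE_ID, ConfigError, CountMatrix

# -- gene programs ----------------------------------------------------------

#: activation program switched on in antigen-responding CAR+ cells
ACTIVATION_UP = [
    "IL2RA", "MYC", "GZMB", "IL2", "IL3", "IL4", "IL5", "IL8", "IL13",
    "CSF2", "CCR4", "BATF3", "IRF4",
]
ACTIVATION_DOWN = ["SELL", "CD3D", "CD3E", "CD3G", "B2M"]

#: exhaustion program on the small exhausted subpopulation of responders
EXHAUSTION_UP = [
    "LAG3", "HAVCR2", "CTLA4", "TIGIT", "TBX21", "IFNG", "CCL1", "CCL3",
    "CCL4", "CCL5", "ENTPD1", "PDCD1", "TOX", "EOMES", "CD244", "CD160",
    "BTLA", "CD38", "CD101", "CXCL13", "PRDM1", "NR4A2", "RGS16", "SH2D2A",
    "IKZF2", "ISG20",
]

S_PHASE_GENES = [
    "MCM2", "MCM3", "MCM4", "MCM5", "MCM6", "PCNA", "POLA1", "PRIM1",
    "RRM1", "RRM2", "TYMS", "FEN1", "GINS2", "CDC45", "UHRF1", "HELLS",
    "MSH2", "RFC4", "SLBP", "WDR76",
]
G2M_GENES = [
    "MKI67", "TOP2A", "CCNB1", "CCNB2", "CDK1", "BUB1", "BUB1B", "PLK1",
    "AURKA", "AURKB", "CDC20", "UBE2C", "BIRC5", "TPX2", "KIF11", "KIF23",
    "CENPA", "CENPE", "NUSAP1", "SMC4",
]

#: NK-like contaminant markers in leukapheresis (CD3E-negative population)
NK_GENES = ["GNLY", "NKG7", "NCAM1", "KLRD1", "KLRF1"]
CD3_GENES = ["CD3D", "CD3E", "CD3G"]

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP6", "MT-CO3", "MT-ND3",
    "MT-ND4", "MT-ND5", "MT-CYB",
]

#: baseline cluster programs: (name, program genes, natural-log fold shift)
DEFAULT_CLUSTER_PROGRAMS: list[tuple[str, tuple[str, ...], float]] = [
    ("cd4_cm_high", ("CD4", "CCR7", "SELL", "LEF1", "TCF7", "MAL", "NOSIP", "LDHB"), 2.0),
    ("cd4_cm_mid", ("CD4", "IL7R", "S100A4", "AQP3", "CD69", "GPR183", "ANXA1", "KLRB1"), 2.0),
    ("cd4_eff", ("CD4", "GZMA", "GZMH", "CST7", "ITGB1", "CD40LG", "ICOS", "S100A11"), 2.0),
    ("cd8_cm", ("CD8A", "CD8B", "CCR7", "SELL", "NELL2", "RGS10", "LDHB", "OXNAD1"), 2.0),
    ("cd8_eff", ("CD8A", "CD8B", "PRF1", "KLRG1", "FGFBP2", "GZMK", "TRGC2", "ZNF683"), 2.0),
]

ACTIVATED_CLUSTER = "activated"
NK_CLUSTER = "nk_like"


def allocate_counts(total: int, fractions: Sequence[float]) -> np.ndarray:
    """Partition ``total`` into integer counts by floor + largest remainder."""
    fractions = np.asarray(fractions, dtype=float)
    if total < 0 or fractions.min() < 0:
        raise ConfigError("allocate_counts requires non-negative inputs")
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = int(round(total - counts.sum())) if abs(fractions.sum() - 1) < 1e-9 else 0
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def exact_count(total: int, fraction: float) -> int:
    """Exact planted count for a single fraction (floor + largest remainder)."""
    return int(allocate_counts(total, [fraction, 1.0 - fraction])[0])


@dataclass
class SimConfig:
    """Parameters of the synthetic CAR-T product / leukapheresis generator.

    Fractions mirror the study conditions being emulated: 22.5% of product
    cells CAR-expressing, 50% of stimulated CAR+ cells responding, 7% of
    responders exhausted, and 7% of unstimulated CAR+ cells pre-activated.
    Effect sizes (program shifts, in natural-log units on the count means)
    are free parameters chosen so the planted populations are separable.
    """

    n_donors: int = 3
    cells_per_condition_per_donor: int = 6316
    n_genes: int = 2000
    cluster_programs: list = field(
        default_factory=lambda: list(DEFAULT_CLUSTER_PROGRAMS)
    )
    car_fraction: float = 0.225
    responder_fraction: float = 0.5
    exhausted_fraction: float = 0.07
    pre_activated_fraction: float = 0.07
    car_umi_mean: float = 5.0
    car_umi_dispersion: float = 0.1
    car_umi_mean_exhausted_multiplier: float = 2.0
    donor_effect_sd: float = 0.15
    nb_dispersion: float = 0.25
    mito_gene_count: int = 10
    mito_share: float = 0.05
    library_size_mean: float = 1500.0
    library_size_sd: float = 0.35
    baseline_log_sd: float = 2.0
    activation_up_shift: float = 1.5
    activation_down_shift: float = -1.2
    exhaustion_shift: float = 2.5
    cycling_fraction: float = 0.25
    contaminant_fraction: float = 0.02
    gene_universe: "list[str] | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "car_fraction", "responder_fraction", "exhausted_fraction",
            "pre_activated_fraction", "cycling_fraction", "contaminant_fraction",
            "mito_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 500:
            raise ConfigError("n_genes must be >= 500")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.car_umi_mean_exhausted_multiplier <= 1:
            raise ConfigError("car_umi_mean_exhausted_multiplier must be > 1")
        if self.mito_gene_count > len(MITO_GENES):
            raise ConfigError(f"mito_gene_count capped at {len(MITO_GENES)}")

    def program_genes(self) -> list[str]:
        genes: list[str] = []
        for _, prog, _ in self.cluster_programs:
            genes.extend(prog)
        genes.extend(ACTIVATION_UP + ACTIVATION_DOWN + EXHAUSTION_UP)
        genes.extend(S_PHASE_GENES + G2M_GENES + NK_GENES + CD3_GENES)
        out: dict[str, None] = {}
        for g in genes:
            out.setdefault(g)
        return list(out)

    def universe(self) -> list[str]:
        """Simulated gene universe: named program genes, mito genes, filler."""
        named = self.program_genes()
        mito = MITO_GENES[: self.mito_gene_count]
        if self.gene_universe is not None:
            missing = [g for g in named + mito if g not in set(self.gene_universe)]
            if missing:
                raise ConfigError(
                    f"program genes not in the supplied gene universe: {missing}"
                )
            if len(self.gene_universe) != self.n_genes:
                raise ConfigError("gene_universe length must equal n_genes")
            return list(self.gene_universe)
        n_fill = self.n_genes - len(named) - len(mito)
        if n_fill < 0:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {len(named) + len(mito)} "
                "named genes"
            )
        fillers = [f"GENE{i:05d}" for i in range(n_fill)]
        return named + mito + fillers


def _baseline_weights(cfg: SimConfig, rng: np.random.Generator, genes: list[str]):
    """Log-normal baseline gene weights; named program genes are forced to a
    moderate expression level (jittered around twice the median weight) so
    planted programs act on detectably expressed genes; mito genes receive a
    fixed ``mito_share`` of the expected library."""
    n = len(genes)
    w = rng.lognormal(mean=0.0, sigma=cfg.baseline_log_sd, size=n)
    named = set(cfg.program_genes())
    med = np.median(w)
    jitter = rng.lognormal(mean=0.0, sigma=0.3, size=n)
    for i, g in enumerate(genes):
        if g in named:
            w[i] = 2.0 * med * jitter[i]
    mito_idx = [i for i, g in enumerate(genes) if g.startswith("MT-")]
    non_mito = np.ones(n, dtype=bool)
    non_mito[mito_idx] = False
    w[~non_mito] = 0.0
    w[non_mito] = w[non_mito] / w[non_mito].sum() * (1.0 - cfg.mito_share)
    if mito_idx:
        w[mito_idx] = cfg.mito_share / len(mito_idx)
    return w


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    """Gamma-Poisson draws with mean ``mu`` and Var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=np.maximum(mu, 1e-12) * dispersion)
    return rng.poisson(lam)


def _pick(rng: np.random.Generator, pool: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(pool, size=n, replace=False) if n else np.empty(0, dtype=int)


def _simulate_block(
    cfg: SimConfig,
    rng: np.random.Generator,
    genes: list[str],
    gidx: dict[str, int],
    weights: np.ndarray,
    donor_factor: np.ndarray,
    donor: str,
    condition: str,
    n_cells: int,
    truth_rows: list,
    barcodes: list,
    product: bool,
) -> sp.csr_matrix:
    """Simulate one (donor, condition) sample; appends truth rows/barcodes."""
    cluster_names = [name for name, _, _ in cfg.cluster_programs]
    k = len(cluster_names)
    cl_counts = allocate_counts(n_cells, [1.0 / k] * k)
    cluster = np.repeat(np.arange(k), cl_counts)
    cluster = cluster[rng.permutation(n_cells)]

    car = np.zeros(n_cells, dtype=bool)
    responder = np.zeros(n_cells, dtype=bool)
    exhausted = np.zeros(n_cells, dtype=bool)
    contaminant = np.zeros(n_cells, dtype=bool)

    if product:
        n_car = exact_count(n_cells, cfg.car_fraction)
        car[_pick(rng, np.arange(n_cells), n_car)] = True
        car_cells = np.flatnonzero(car)
        if condition == "stimulated":
            n_resp = exact_count(len(car_cells), cfg.responder_fraction)
            resp_cells = _pick(rng, car_cells, n_resp)
            responder[resp_cells] = True
            n_exh = exact_count(n_resp, cfg.exhausted_fraction)
            exhausted[_pick(rng, resp_cells, n_exh)] = True
        else:
            n_pre = exact_count(len(car_cells), cfg.pre_activated_fraction)
            responder[_pick(rng, car_cells, n_pre)] = True
    else:
        n_cont = exact_count(n_cells, cfg.contaminant_fraction)
        contaminant[_pick(rng, np.arange(n_cells), n_cont)] = True

    # cell-cycle stages: cycling cells split evenly between S and G2M
    stage = np.full(n_cells, "G1", dtype=object)
    cycling_pool = np.flatnonzero(~contaminant)
    n_cyc = exact_count(len(cycling_pool), cfg.cycling_fraction)
    cyc = _pick(rng, cycling_pool, n_cyc)
    half = allocate_counts(n_cyc, [0.5, 0.5])
    stage[cyc[: half[0]]] = "S"
    stage[cyc[half[0]:]] = "G2M"

    # mean matrix in log space
    logmu = np.log(np.maximum(weights, 1e-300))[None, :] + np.log(donor_factor)[None, :]
    logmu = np.repeat(logmu, n_cells, axis=0)
    for ci, (_, prog, shift) in enumerate(cfg.cluster_programs):
        rows = np.flatnonzero((cluster == ci) & ~contaminant & ~responder)
        cols = [gidx[g] for g in prog]
        logmu[np.ix_(rows, cols)] += shift
    act_rows = np.flatnonzero(responder)
    if act_rows.size:
        logmu[np.ix_(act_rows, [gidx[g] for g in ACTIVATION_UP])] += cfg.activation_up_shift
        logmu[np.ix_(act_rows, [gidx[g] for g in ACTIVATION_DOWN])] += cfg.activation_down_shift
    exh_rows = np.flatnonzero(exhausted)
    if exh_rows.size:
        logmu[np.ix_(exh_rows, [gidx[g] for g in EXHAUSTION_UP])] += cfg.exhaustion_shift
    s_rows = np.flatnonzero(stage == "S")
    if s_rows.size:
        logmu[np.ix_(s_rows, [gidx[g] for g in S_PHASE_GENES])] += 1.5
    g2m_rows = np.flatnonzero(stage == "G2M")
    if g2m_rows.size:
        logmu[np.ix_(g2m_rows, [gidx[g] for g in G2M_GENES])] += 1.5
    cont_rows = np.flatnonzero(contaminant)
    if cont_rows.size:
        logmu[np.ix_(cont_rows, [gidx[g] for g in NK_GENES])] += 2.5
        logmu[np.ix_(cont_rows, [gidx[g] for g in CD3_GENES])] = -np.inf

    mu = np.exp(logmu)
    lib = rng.lognormal(
        mean=np.log(cfg.library_size_mean) - cfg.library_size_sd**2 / 2.0,
        sigma=cfg.library_size_sd,
        size=n_cells,
    )
    mu *= (lib / mu.sum(axis=1))[:, None]
    counts = _nb_counts(rng, mu, cfg.nb_dispersion).astype(np.int32)

    if product:
        car_umis = np.zeros(n_cells, dtype=np.int64)
        idx = np.flatnonzero(car)
        if idx.size:
            mean = np.full(idx.size, cfg.car_umi_mean)
            mean[exhausted[idx]] *= cfg.car_umi_mean_exhausted_multiplier
            car_umis[idx] = _nb_counts(rng, mean, cfg.car_umi_dispersion)
        counts = np.hstack([counts, car_umis[:, None].astype(np.int32)])

    true_cluster = np.array([cluster_names[c] for c in cluster], dtype=object)
    true_cluster[responder] = ACTIVATED_CLUSTER
    true_cluster[contaminant] = NK_CLUSTER
    sample_id = f"{donor}_{condition}"
    for i in range(n_cells):
        barcodes.append(f"{sample_id}_{i:06d}")
        truth_rows.append(
            (true_cluster[i], bool(car[i]), bool(responder[i]), bool(exhausted[i]),
             stage[i], donor, condition)
        )
    return sp.csr_matrix(counts.T)  # genes x cells


def _assemble(cfg: SimConfig, product: bool):
    rng = np.random.default_rng(cfg.seed if product else cfg.seed + 1)
    genes = cfg.universe()
    gidx = {g: i for i, g in enumerate(genes)}
    weights = _baseline_weights(cfg, rng, genes)
    donors = [f"donor{i + 1}" for i in range(cfg.n_donors)]
    donor_factors = {
        d: rng.lognormal(mean=0.0, sigma=cfg.donor_effect_sd, size=len(genes))
        for d in donors
    }
    conditions = ["unstimulated", "stimulated"] if product else ["leukapheresis"]
    blocks, truth_rows, barcodes = [], [], []
    for donor in donors:
        for condition in conditions:
            blocks.append(
                _simulate_block(
                    cfg, rng, genes, gidx, weights, donor_factors[donor],
                    donor, condition, cfg.cells_per_condition_per_donor,
                    truth_rows, barcodes, product,
                )
            )
    counts = sp.hstack(blocks, format="csr")
    gene_ids = list(genes) + ([CAR_FEATURE_ID] if product else [])
    truth = pd.DataFrame(
        truth_rows,
        columns=["true_cluster", "car_positive", "responder", "exhausted",
                 "cellcycle_stage", "donor", "condition"],
        index=pd.Index(barcodes, name="barcode"),
    )
    meta = truth[["donor", "condition"]].copy()
    meta["sample_id"] = meta["donor"].astype(str) + "_" + meta["condition"].astype(str)
    m = CountMatrix(
        counts=counts,
        gene_ids=np.array(gene_ids, dtype=object),
        gene_names=np.array(gene_ids, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )
    return m, truth


def simulate_product(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate CAR product samples (unstimulated + stimulated per donor).

    Returns the count matrix (with the ``CAR-3LTR`` pseudo-feature as the last
    gene row) and the per-cell ground-truth table.
    """
    return _assemble(cfg, product=True)


def simulate_leukapheresis(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate leukapheresis samples: no CAR feature, no activation program,
    plus a small CD3E-negative NK-like contaminant population."""
    return _assemble(cfg, product=False)


def scaled_config(**overrides) -> SimConfig:
    """A small-scale config for tests and examples (same structure, fewer cells)."""
    defaults = dict(cells_per_condition_per_donor=400, n_genes=600)
    defaults.update(overrides)
    return SimConfig(**defaults)


__all__ = [
    "SimConfig", "simulate_product", "simulate_leukapheresis",
    "allocate_counts", "exact_count", "scaled_config",
    "ACTIVATION_UP", "ACTIVATION_DOWN", "EXHAUSTION_UP",
    "S_PHASE_GENES", "G2M_GENES", "NK_GENES", "MITO_GENES",
    "DEFAULT_CLUSTER_PROGRAMS", "ACTIVATED_CLUSTER", "NK_CLUSTER",
]
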