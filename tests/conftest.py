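"""Shared fixtures: small simulated datasets reused across the suite."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cartography import preprocess as pp
from cartography.core_io import CountMatrix, read_gmt, packaged_gmt
from cartography.synthetic_data import SimConfig, simulate_leukapheresis, simulate_product


@pytest.fixture(scope="session")
def small_sim():
    """Small product simulation with ground truth (3 donors x 2 conditions)."""
    cfg = SimConfig(seed=7, cells_per_condition_per_donor=500, n_genes=800)
    m, truth = simulate_product(cfg)
    return {"cfg": cfg, "matrix": m, "truth": truth}


@pytest.fixture(scope="session")
def small_leuk():
    cfg = SimConfig(seed=7, cells_per_condition_per_donor=500, n_genes=800)
    m, truth = simulate_leukapheresis(cfg)
    return {"cfg": cfg, "matrix": m, "truth": truth}


@pytest.fixture(scope="session")
def small_expr(small_sim):
    """Normalized expression + HVGs for the small simulation.

    The HVG mean ceiling is widened to the reduced gene universe (the cp10k
    mean scale is inversely proportional to universe size).
    """
    expr = pp.normalize_log(small_sim["matrix"])
    hvgs = pp.select_hvgs(expr, pp.HVGParams(max_mean=30.0))
    truth = small_sim["truth"].loc[expr.barcodes]
    return {"expr": expr, "hvgs": hvgs, "truth": truth}


@pytest.fixture(scope="session")
def clustered_sim(small_sim, small_expr):
    """Cell-cycle-regressed PCA + kNN graph + Leiden labels for the small sim."""
    from cartography import cluster_integrate as ci

    expr, hvgs = small_expr["expr"], small_expr["hvgs"]
    s_set, g2m_set = read_gmt(packaged_gmt("cell_cycle_default.gmt"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cc = pp.cellcycle_score(expr, s_set, g2m_set)
    cov = pp.standard_covariates(small_sim["matrix"], expr)
    cov["s_score"] = cc["s_score"].to_numpy()
    cov["g2m_score"] = cc["g2m_score"].to_numpy()
    idx = np.array([expr.gene_index(g) for g in hvgs])
    resid = pp.regress_out(expr.subset_genes(idx), cov)
    emb = ci.pca(resid, n_components=30)
    graph = ci.knn_graph(emb, k=15)
    labels = ci.cluster_communities(graph, resolution=1.0, seed=0)
    return {
        "resid": resid, "embedding": emb, "graph": graph, "labels": labels,
        "cellcycle": cc, "truth": small_expr["truth"],
    }


@pytest.fixture(scope="session")
def midscale_sim():
    """12,000-cell product simulation at the default gene universe."""
    cfg = SimConfig(seed=11, cells_per_condition_per_donor=2000)
    m, truth = simulate_product(cfg)
    return {"cfg": cfg, "matrix": m, "truth": truth}


def toy_count_matrix(counts, gene_names=None, barcodes=None, meta=None):
    """CountMatrix from a dense genes x cells array with default labels."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_names = gene_names or [f"G{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"C{j}" for j in range(n_cells)]
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(gene_names, dtype=object),
        gene_names=np.array(gene_names, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )
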