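"""End-to-end orchestration and the composition report.

``run_pipeline`` executes simulate -> QC -> CAR calling -> normalize -> HVG ->
cluster -> integrate -> differential expression -> exhaustion scoring ->
enrichment on synthetic data, writing every artifact with a manifest of
config, seeds and content hashes so two runs with the same config are
hash-identical.  ``compose_report`` turns per-cell labels and flags into the
contingency counts and derived percentages (every percentage is recomputed
from counts, never stored independently; rounding is half-up at the printed
precision).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_integrate as ci
from . import diffexpr as de
from . import enrichment as enr
from . import preprocess as pp
from . import signatures as sig
from .core_io import CAR_FEATURE_ID, ConfigError, GeneSet, read_gmt, packaged_gmt
from .synthetic_data import (
    ACTIVATION_UP,
    EXHAUSTION_UP,
    SimConfig,
    simulate_leukapheresis,
    simulate_product,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of an end-to-end run on synthetic data."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc_product: pp.QCThresholds = field(default_factory=pp.QCThresholds.product)
    qc_leukapheresis: pp.QCThresholds = field(default_factory=pp.QCThresholds.leukapheresis)
    hvg: pp.HVGParams = field(default_factory=pp.HVGParams)
    n_pcs: int = 30
    knn_k: int = 15
    resolution: float = 1.0
    cluster_method: str = "leiden"
    de_filter: de.DEFilter = field(default_factory=de.DEFilter)
    score_params: sig.ScoreParams = field(default_factory=sig.ScoreParams)
    exhaustion_threshold: float = 0.6
    n_extremes: int = 153
    k_within: int = 7
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    gsea_n_perm: int = 200
    run_umap: bool = False
    seed: int = 0

    @classmethod
    def default_synthetic(cls, seed: int = 0, **sim_overrides) -> "RunConfig":
        """Defaults matched to the scaled-down synthetic data (QC floors are
        library-size dependent; the printed product/leukapheresis values
        assume full-depth libraries)."""
        sim = SimConfig(seed=seed, **sim_overrides)
        return cls(
            sim=sim,
            qc_product=pp.QCThresholds(min_genes_per_cell=200, min_total_umis=400),
            qc_leukapheresis=pp.QCThresholds(min_genes_per_cell=150, min_total_umis=300),
            # the HVG mean window lives on the cp10k scale, which scales
            # inversely with the gene-universe size; widen the ceiling for
            # the reduced synthetic universe
            hvg=pp.HVGParams(max_mean=30.0),
            seed=seed,
        )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _percent(count: int, total: int, decimals: int = 0) -> dict:
    """Half-up rounded percentage with the printed string representation."""
    if total == 0:
        value, printed = 0.0, "0%" if decimals == 0 else f"0.{'0' * decimals}%"
        return {"count": int(count), "total": int(total), "percent": value, "printed": printed}
    quant = Decimal(1).scaleb(-decimals)
    pct = (Decimal(count) * 100 / Decimal(total)).quantize(quant, rounding=ROUND_HALF_UP)
    return {
        "count": int(count),
        "total": int(total),
        "percent": float(pct),
        "printed": f"{pct}%",
    }


format_percent = _percent


@dataclass
class CompositionReport:
    """Contingency counts plus derived percentages of an analyzed product."""

    counts: pd.DataFrame
    percentages: dict
    cluster_condition_shares: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(orient="records"),
            "percentages": self.percentages,
            "cluster_condition_shares": self.cluster_condition_shares.to_dict(
                orient="records"
            ),
        }


def compose_report(
    cells: pd.DataFrame,
    activated_cluster=None,
) -> CompositionReport:
    """Build the composition report from per-cell labels and flags.

    ``cells`` needs columns ``donor, condition, car_positive, cluster,
    exhausted`` (one row per cell).  ``activated_cluster`` names the cluster
    holding antigen-responding cells; when None it is taken as the cluster
    with the highest share of stimulated CAR-expressing cells.
    """
    required = ["donor", "condition", "car_positive", "cluster", "exhausted"]
    for col in required:
        if col not in cells.columns:
            raise ConfigError(f"cells table lacks required column {col!r}")
        bad = cells.index[cells[col].isna()]
        if len(bad):
            raise ConfigError(f"cell {bad[0]!r} has a missing {col!r} flag")
    product = cells[cells["condition"].isin(["unstimulated", "stimulated"])]

    counts = (
        product.groupby(["donor", "condition", "car_positive", "cluster"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )

    if activated_cluster is None:
        stim_car_flags = (product["condition"] == "stimulated") & product["car_positive"]
        activated_cluster = _activated_clusters(
            product["cluster"].to_numpy(), stim_car_flags.to_numpy()
        )
    if np.isscalar(activated_cluster):
        activated_cluster = [activated_cluster]
    activated_cluster = list(activated_cluster)

    n_product = len(product)
    n_car = int(product["car_positive"].sum())
    unstim_car = product[(product["condition"] == "unstimulated") & product["car_positive"]]
    unstim_car_act = unstim_car[unstim_car["cluster"].isin(activated_cluster)]
    responders = product[
        (product["condition"] == "stimulated")
        & product["car_positive"]
        & product["cluster"].isin(activated_cluster)
    ]
    n_resp_exh = int(responders["exhausted"].sum())

    percentages = {
        "overall_car": _percent(n_car, n_product, decimals=1),
        "unstim_car_in_activated_cluster": _percent(
            len(unstim_car_act), len(unstim_car), decimals=0
        ),
        "exhausted_among_responders": _percent(n_resp_exh, len(responders), decimals=0),
    }

    shares = (
        product.groupby(["cluster", "condition"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    cl_tot = product.groupby("cluster", observed=True).size().rename("cluster_total")
    shares = shares.merge(cl_tot, on="cluster")
    shares["share"] = shares["n_cells"] / shares["cluster_total"]

    report = CompositionReport(
        counts=counts, percentages=percentages, cluster_condition_shares=shares
    )
    report.activated_cluster = activated_cluster
    return report


def _activated_clusters(clusters: np.ndarray, stim_car: np.ndarray) -> list:
    """Clusters holding the antigen-responding cells: every cluster where
    stimulated CAR+ cells form the majority (the responding compartment may
    split into a main activated cluster plus small subclusters such as the
    exhausted one); falls back to the highest stimulated-CAR+ share."""
    df = pd.DataFrame({"cluster": clusters, "stim_car": stim_car})
    per = df.groupby("cluster", observed=True)["stim_car"].agg(["sum", "size"])
    per["share"] = per["sum"] / per["size"]
    dominant = per[per["share"] > 0.5]
    if len(dominant):
        return list(dominant.index)
    return [per["share"].idxmax()]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: RunConfig, outdir) -> CompositionReport:
    """Execute all stages on simulated data; artifacts + manifest in outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    manifest = {"config": cfg.to_dict(), "complete": False, "artifacts": {}}

    def checkpoint(name: str, path: Path):
        artifacts[name] = path
        manifest["artifacts"][name] = _sha256(path)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    stage = "simulate"
    try:
        product, truth = simulate_product(cfg.sim)
        leuk, leuk_truth = simulate_leukapheresis(cfg.sim)

        stage = "qc"
        product_qc, prod_report = pp.apply_qc(product, cfg.qc_product)
        leuk_qc, leuk_report = pp.apply_qc(leuk, cfg.qc_leukapheresis)
        (outdir / "qc_report.json").write_text(
            json.dumps(
                {"product": prod_report.to_dict(), "leukapheresis": leuk_report.to_dict()},
                indent=2,
            )
        )
        checkpoint("qc_report", outdir / "qc_report.json")

        stage = "detect_car"
        car_mask, car_summary = pp.detect_car_cells(product_qc)
        _write_tsv(car_summary, outdir / "car_summary.tsv")
        checkpoint("car_summary", outdir / "car_summary.tsv")

        stage = "normalize"
        expr = pp.normalize_log(product_qc)
        leuk_expr = pp.normalize_log(leuk_qc)

        stage = "hvg"
        hvgs = pp.select_hvgs(expr, cfg.hvg)
        (outdir / "hvgs.txt").write_text("\n".join(map(str, hvgs)) + "\n")
        checkpoint("hvgs", outdir / "hvgs.txt")

        stage = "cellcycle"
        s_set, g2m_set = read_gmt(packaged_gmt("cell_cycle_default.gmt"))
        cc = pp.cellcycle_score(expr, s_set, g2m_set, cfg.score_params)
        cc.insert(0, "barcode", expr.barcodes)
        _write_tsv(cc, outdir / "cellcycle.tsv")
        checkpoint("cellcycle", outdir / "cellcycle.tsv")

        stage = "cluster"
        hv_idx = [expr.gene_index(g) for g in hvgs]
        covariates = pp.standard_covariates(product_qc, expr)
        covariates["s_score"] = cc["s_score"].to_numpy()
        covariates["g2m_score"] = cc["g2m_score"].to_numpy()
        resid = pp.regress_out(expr.subset_genes(np.array(hv_idx)), covariates)
        emb = ci.pca(resid, n_components=cfg.n_pcs)
        graph = ci.knn_graph(emb, k=cfg.knn_k)
        scan = ci.resolution_scan(graph, seed=cfg.seed, method=cfg.cluster_method)
        _write_tsv(scan, outdir / "resolution_scan.tsv")
        checkpoint("resolution_scan", outdir / "resolution_scan.tsv")
        labeling = ci.cluster_communities(
            graph, resolution=cfg.resolution, seed=cfg.seed, method=cfg.cluster_method
        )
        labels_df = pd.DataFrame(
            {"barcode": expr.barcodes, "cluster": labeling.labels, "car_positive": car_mask}
        )
        _write_tsv(labels_df, outdir / "cluster_labels.tsv")
        checkpoint("cluster_labels", outdir / "cluster_labels.tsv")

        if cfg.run_umap:
            um = ci.umap_embed(emb, seed=cfg.seed)
            _write_tsv(
                pd.DataFrame(um.coords, columns=["umap1", "umap2"]).assign(
                    barcode=expr.barcodes
                ),
                outdir / "umap.tsv",
            )
            checkpoint("umap", outdir / "umap.tsv")

        stage = "integrate"
        shared = [g for g in hvgs if g in set(leuk_expr.gene_ids)]
        prod_sub = resid.subset_genes(
            np.array([resid.gene_index(g) for g in shared])
        )
        leuk_cc = pp.cellcycle_score(leuk_expr, s_set, g2m_set, cfg.score_params)
        leuk_cov = pp.standard_covariates(leuk_qc, leuk_expr)
        leuk_cov["s_score"] = leuk_cc["s_score"].to_numpy()
        leuk_cov["g2m_score"] = leuk_cc["g2m_score"].to_numpy()
        leuk_sub = pp.regress_out(
            leuk_expr.subset_genes(
                np.array([leuk_expr.gene_index(g) for g in shared])
            ),
            leuk_cov,
        )
        joint = np.vstack([prod_sub.dense().T, leuk_sub.dense().T])
        n_prod = prod_sub.n_cells
        joint_emb = ci.pca(joint, n_components=min(cfg.n_pcs, joint.shape[1] - 1))
        ref = ci.Embedding(joint_emb.coords[:n_prod], "PCA", joint_emb.n_components,
                           barcodes=prod_sub.barcodes)
        query = ci.Embedding(joint_emb.coords[n_prod:], "PCA", joint_emb.n_components,
                             barcodes=leuk_sub.barcodes)
        neighbors = ci.batch_balanced_neighbors(ref, query, k_within=cfg.k_within)
        transferred = ci.transfer_labels(neighbors, labeling.labels)
        _write_tsv(
            pd.DataFrame({"barcode": leuk_sub.barcodes, "cluster": transferred}),
            outdir / "transfer_labels.tsv",
        )
        checkpoint("transfer_labels", outdir / "transfer_labels.tsv")

        stage = "de"
        stim = expr.cell_meta["condition"].to_numpy() == "stimulated"
        cluster_of = labeling.labels
        stim_car = stim & car_mask
        activated_clusters = _activated_clusters(cluster_of, stim_car)
        in_act = np.isin(cluster_of, activated_clusters)
        group_a = stim_car & in_act
        group_b = stim_car & ~in_act
        de_table = de.welch_ttest_by_gene(expr, group_a, group_b)
        de_table = de_table[de_table["gene_id"] != CAR_FEATURE_ID].reset_index(drop=True)
        _write_tsv(de_table, outdir / "de_activated_vs_rest.tsv")
        checkpoint("de_activated_vs_rest", outdir / "de_activated_vs_rest.tsv")
        up, down = de.apply_de_filter(de_table, cfg.de_filter)
        _write_tsv(up, outdir / "de_up.tsv")
        _write_tsv(down, outdir / "de_down.tsv")
        checkpoint("de_up", outdir / "de_up.tsv")
        checkpoint("de_down", outdir / "de_down.tsv")

        stage = "signatures"
        signature = read_gmt(packaged_gmt("exhaustion_signature_synthetic.gmt"))[0]
        sig_used = sig.intersect_signature(signature, hvgs)
        scores = sig.score_signature(expr, sig_used, cfg.score_params)
        call = sig.classify_exhausted(scores, cfg.exhaustion_threshold, sig_used)
        score_df = pd.DataFrame(
            {
                "barcode": expr.barcodes,
                "score": scores,
                "exhausted": call.exhausted,
                "cluster": cluster_of,
                "car_positive": car_mask,
                "condition": expr.cell_meta["condition"].to_numpy(),
            }
        )
        _write_tsv(score_df, outdir / "exhaustion_scores.tsv")
        checkpoint("exhaustion_scores", outdir / "exhaustion_scores.tsv")
        resp_mask = stim_car & in_act
        top, bottom = sig.select_extremes(
            scores, resp_mask, expr.barcodes, n=cfg.n_extremes
        )
        (outdir / "extreme_cells.json").write_text(
            json.dumps(
                {
                    "top": [str(expr.barcodes[i]) for i in top],
                    "bottom": [str(expr.barcodes[i]) for i in bottom],
                },
                indent=2,
            )
        )
        checkpoint("extreme_cells", outdir / "extreme_cells.json")

        stage = "enrichment"
        universe = [g for g in expr.gene_ids if g != CAR_FEATURE_ID]
        terms = [
            GeneSet("ACTIVATION_PROGRAM", list(ACTIVATION_UP)),
            GeneSet("EXHAUSTION_PROGRAM", list(EXHAUSTION_UP)),
        ]
        up_list = [g for g in up["gene_id"] if g in set(universe)]
        down_list = [g for g in down["gene_id"] if g in set(universe)]
        enr_table = enr.enrich_terms(up_list, down_list, terms, universe)
        _write_tsv(enr_table, outdir / "enrichment.tsv")
        checkpoint("enrichment", outdir / "enrichment.tsv")
        ranked = enr.rank_genes_for_gsea(de_table)["gene_id"].tolist()
        gsea_table = enr.gsea_collection(
            ranked, terms, n_perm=cfg.gsea_n_perm, seed=cfg.seed,
            min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size,
        )
        _write_tsv(gsea_table, outdir / "gsea.tsv")
        checkpoint("gsea", outdir / "gsea.tsv")

        stage = "report"
        cells = pd.DataFrame(
            {
                "donor": expr.cell_meta["donor"].to_numpy(),
                "condition": expr.cell_meta["condition"].to_numpy(),
                "car_positive": car_mask,
                "cluster": cluster_of,
                "exhausted": call.exhausted,
            },
            index=pd.Index(expr.barcodes, name="barcode"),
        )
        report = compose_report(cells, activated_cluster=activated_clusters)
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True, default=str)
        )
        checkpoint("report", outdir / "report.json")
        _write_tsv(report.counts, outdir / "report_counts.tsv")
        checkpoint("report_counts", outdir / "report_counts.tsv")
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.error("pipeline aborted at stage %s", stage)
        raise

    manifest["complete"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
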