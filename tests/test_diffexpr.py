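"""Welch t-test DE, BH adjustment, the three-criterion filter, overlap clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cartography import diffexpr as de
from cartography.core_io import ConfigError, ExprMatrix


def _expr(values, gene_names=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_names = gene_names or [f"G{i}" for i in range(n_genes)]
    barcodes = [f"C{j}" for j in range(n_cells)]
    return ExprMatrix(
        values=values,
        gene_ids=np.array(gene_names, dtype=object),
        gene_names=np.array(gene_names, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
    )


class TestWelch:
    def test_hand_computed_toy(self):
        e = _expr([[1, 2, 3, 4, 5, 6], [2, 2, 2, 2, 2, 2]])
        res = de.welch_ttest_by_gene(e, np.array([0, 1, 2]), np.array([3, 4, 5]))
        assert np.isclose(res.loc[0, "t"], -3.6742346, atol=1e-6)
        assert np.isclose(res.loc[0, "p"], 0.021312, atol=1e-5)

    def test_identical_groups_null(self):
        vals = np.array([[1.0, 5.0, 2.0, 1.0, 5.0, 2.0], [0, 3, 1, 0, 3, 1.0]])
        e = _expr(vals)
        res = de.welch_ttest_by_gene(e, np.array([0, 1, 2]), np.array([3, 4, 5]))
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_matches_scipy_reference(self):
        """t and p agree with the library Welch implementation to 1e-10/1e-8."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            vals = rng.normal(size=(30, 17))
            e = _expr(vals)
            a, b = np.arange(8), np.arange(8, 17)
            res = de.welch_ttest_by_gene(e, a, b)
            ref_t, ref_p = stats.ttest_ind(vals[:, a], vals[:, b], axis=1,
                                           equal_var=False)
            assert np.allclose(res["t"], ref_t, atol=1e-10)
            assert np.allclose(res["p"], ref_p, atol=1e-8)

    def test_null_type_one_error_rate(self):
        """Identically distributed NB groups: raw p < 0.05 within 3 binomial
        SDs of 5% over 2,000 genes."""
        rng = np.random.default_rng(9)
        lam = rng.gamma(2.0, 1.0, size=2000)
        counts = rng.poisson(rng.gamma(4.0, lam[:, None] / 4.0, size=(2000, 400)))
        e = _expr(np.log1p(counts))
        res = de.welch_ttest_by_gene(e, np.arange(200), np.arange(200, 400))
        frac = (res["p"] < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) <= 3 * sd

    def test_zero_variance_paths(self):
        e = _expr([[1, 1, 1, 1], [1, 1, 2, 2]])
        res = de.welch_ttest_by_gene(e, np.array([0, 1]), np.array([2, 3]))
        assert res.loc[0, "p"] == 1.0 and not res.loc[0, "degenerate"]
        assert res.loc[1, "p"] == 0.0 and res.loc[1, "degenerate"]

    def test_overlapping_groups_rejected(self):
        e = _expr(np.ones((2, 5)))
        with pytest.raises(ConfigError):
            de.welch_ttest_by_gene(e, np.array([0, 1, 2]), np.array([2, 3, 4]))


class TestBH:
    def test_hand_step_up(self):
        q = de.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert de.bh_adjust(np.array([0.3]))[0] == 0.3

    def test_all_ones(self):
        assert (de.bh_adjust(np.ones(5)) == 1.0).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
    def test_matches_brute_force_step_up(self, ps):
        p = np.array(ps)
        n = len(p)
        brute = np.empty(n)
        order = np.argsort(p, kind="stable")
        for rank_pos, idx in enumerate(order):
            candidates = [
                p[order[j]] * n / (j + 1) for j in range(rank_pos, n)
            ]
            brute[idx] = min(1.0, min(candidates))
        assert np.allclose(de.bh_adjust(p), brute, atol=0, rtol=0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        p = rng.uniform(size=500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(de.bh_adjust(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            de.bh_adjust(np.array([0.5, 1.5]))


class TestFilter:
    def _row(self, q, log2fc, mean):
        return pd.DataFrame(
            {"gene_id": ["g"], "log2fc": [log2fc], "log2_mean": [mean],
             "t": [0.0], "p": [q], "q": [q], "degenerate": [False]}
        )

    def test_passing_gene_is_upregulated(self):
        up, down = de.apply_de_filter(self._row(0.04, 1.2, -4.0))
        assert len(up) == 1 and len(down) == 0

    def test_fold_change_boundary_strict(self):
        up, down = de.apply_de_filter(self._row(0.04, 1.0, -4.0))
        assert len(up) == 0

    def test_fdr_boundary_strict(self):
        up, _ = de.apply_de_filter(self._row(0.05, 1.2, -4.0))
        assert len(up) == 0

    def test_mean_boundary_strict_and_downregulation_mirrored(self):
        up, down = de.apply_de_filter(self._row(0.01, -1.5, -5.0))
        assert len(up) == 0 and len(down) == 0  # mean exactly at the floor
        up, down = de.apply_de_filter(self._row(0.01, -1.5, -4.9))
        assert len(down) == 1

    def test_null_simulation_rarely_passes(self):
        """Under no signal the joint FDR + fold-change filter returns zero
        genes in >= 95% of runs."""
        rng = np.random.default_rng(11)
        empty = 0
        for _ in range(20):
            counts = rng.poisson(rng.gamma(3.0, 0.5, size=(300, 1)), size=(300, 120))
            e = _expr(np.log1p(counts))
            res = de.welch_ttest_by_gene(e, np.arange(60), np.arange(60, 120))
            up, down = de.apply_de_filter(res)
            empty += int(len(up) == 0 and len(down) == 0)
        # a >= 95% empty-run rate observed through 20 runs: allow binomial
        # noise around the nominal rate
        assert empty >= 18

    def test_planted_program_recovered(self, small_expr):
        """Activation-program genes recovered with recall and precision >= 0.8
        in the responder vs non-responder contrast."""
        from cartography.synthetic_data import ACTIVATION_UP

        e, truth = small_expr["expr"], small_expr["truth"]
        resp = (truth["responder"] & (truth["condition"] == "stimulated")).to_numpy()
        rest = ((~truth["responder"]) & (truth["condition"] == "stimulated")).to_numpy()
        res = de.welch_ttest_by_gene(e, resp, rest)
        up, _ = de.apply_de_filter(res)
        found = set(up["gene_id"])
        recall = len(found & set(ACTIVATION_UP)) / len(ACTIVATION_UP)
        precision = len(found & set(ACTIVATION_UP)) / max(len(found), 1)
        assert recall >= 0.8
        assert precision >= 0.8


class TestTopUpregulated:
    def _results(self, n_pos, n_neg=0):
        rng = np.random.default_rng(12)
        q = rng.uniform(size=n_pos + n_neg)
        fc = np.concatenate([rng.uniform(0.1, 3, n_pos), -rng.uniform(0.1, 3, n_neg)])
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n_pos + n_neg)],
             "log2fc": fc, "log2_mean": 0.0, "t": 0.0, "p": q, "q": q,
             "degenerate": False}
        )

    def test_exactly_n_returned(self):
        assert len(de.top_upregulated(self._results(300), n=200)) == 200

    def test_fewer_available_warns(self):
        with pytest.warns(UserWarning):
            out = de.top_upregulated(self._results(150, n_neg=50), n=200)
        assert len(out) == 150

    def test_q_tie_broken_by_fold_change(self):
        res = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "log2fc": [1.0, 2.0, 3.0],
             "log2_mean": 0.0, "t": 0.0, "p": [0.01, 0.01, 0.02],
             "q": [0.01, 0.01, 0.02], "degenerate": False}
        )
        assert de.top_upregulated(res, n=2) == ["b", "a"]


def _ward_distance(X, members_a, members_b):
    """Ward inter-cluster distance from first principles (ESS increase)."""
    ca, cb = X[members_a].mean(axis=0), X[members_b].mean(axis=0)
    na, nb = len(members_a), len(members_b)
    return np.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)


def _replay_ward(X, Z, atol=1e-9):
    """Brute-force oracle for a Ward linkage: every merge height must equal
    the centroid/ESS formula for the merged pair, and every merged pair must
    be a minimum-distance pair at its step (up to exact-tie ambiguity)."""
    clusters = {i: [i] for i in range(len(X))}
    for step, (a, b, height, _) in enumerate(Z):
        a, b = int(a), int(b)
        expected = _ward_distance(X, clusters[a], clusters[b])
        assert np.isclose(height, expected, atol=atol), (step, height, expected)
        best = min(
            _ward_distance(X, clusters[u], clusters[v])
            for u in clusters for v in clusters if u < v
        )
        assert height <= best + atol, (step, height, best)
        clusters[len(X) + step] = clusters.pop(a) + clusters.pop(b)


class TestOverlapCluster:
    def test_two_disjoint_lists_give_two_groups(self):
        membership, _, _, flat = de.overlap_cluster(
            {"c1": ["a", "b", "c"], "c2": ["d", "e"]}, n_groups=2
        )
        assert membership.shape == (5, 2)
        groups = {frozenset(v) for v in flat.values()}
        assert groups == {frozenset("abc"), frozenset("de")}

    def test_union_size_exact(self):
        lists = {"x": ["a", "b", "c"], "y": ["b", "c", "d"], "z": ["d", "e"]}
        membership, *_ = de.overlap_cluster(lists, n_groups=2)
        assert len(membership) == 5
        assert membership.to_numpy().sum() == sum(map(len, lists.values()))

    def test_matches_brute_force_ward_oracle(self):
        """The gene dendrogram is a valid Ward agglomeration: each merge
        height equals the ESS-increase formula recomputed from raw membership
        vectors, and each merge is greedily minimal at its step."""
        rng = np.random.default_rng(3)
        patterns = rng.choice(31, size=12, replace=False) + 1
        names = [f"g{i}" for i in range(12)]
        lists = {
            f"c{j}": [g for g, pat in zip(names, patterns) if (pat >> j) & 1]
            for j in range(5)
        }
        membership, gene_linkage, _, _ = de.overlap_cluster(lists)
        _replay_ward(membership.to_numpy(), gene_linkage)

    def test_single_list_rejected(self):
        with pytest.raises(ConfigError):
            de.overlap_cluster({"only": ["a"]})
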