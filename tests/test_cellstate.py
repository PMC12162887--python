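"""Cell-state analysis: HVGs, clustering, markers, signatures, scoring."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from irpdx import cellstate, synthio


def _adata(X, genes=None):
    X = np.asarray(X, dtype=float)
    ad = AnnData(X=sp.csr_matrix(X))
    ad.obs_names = [f"c{i:04d}" for i in range(X.shape[0])]
    ad.var_names = genes or [f"g{i:04d}" for i in range(X.shape[1])]
    return ad


class TestHVG:
    def test_planted_high_variance_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2, 0.1, size=(100, 50)).clip(min=0)
        X[:, 7] = rng.normal(2, 3.0, size=100).clip(min=0)  # 10x the spread
        ad = _adata(X)
        assert cellstate.hvg_select(ad, n=5)[0] == "g0007"

    def test_requesting_all_genes_is_identity_with_warning(self):
        ad = _adata(np.random.default_rng(1).poisson(3, (30, 20)))
        with pytest.warns(UserWarning):
            genes = cellstate.hvg_select(ad, n=50)
        assert genes == sorted(ad.var_names)


class TestEmbedCluster:
    def test_recovers_planted_states(self, state_adata):
        clusters, _ = cellstate.embed_cluster(
            state_adata, hvgs=cellstate.hvg_select(state_adata, n=400), seed=0
        )
        ari = adjusted_rand_score(state_adata.obs["state"], clusters)
        assert ari >= 0.9

    def test_deterministic_given_seed(self, state_adata):
        hv = cellstate.hvg_select(state_adata, n=300)
        a, _ = cellstate.embed_cluster(state_adata, hvgs=hv, seed=3)
        b, _ = cellstate.embed_cluster(state_adata, hvgs=hv, seed=3)
        assert (a == b).all()

    def test_npcs_bounds_checked(self, state_adata):
        with pytest.raises(ValueError):
            cellstate.embed_cluster(state_adata, hvgs=list(state_adata.var_names[:10]), n_pcs=10)


class TestMarkers:
    def test_planted_blocks_recovered_as_markers(self, state_adata):
        clusters = pd.Series(
            state_adata.obs["state"].to_numpy(), index=state_adata.obs_names
        )
        res = cellstate.cluster_markers(state_adata, clusters)
        sets = res.marker_sets()
        blocks = state_adata.uns["truth"]["marker_blocks"]
        for state, idx in blocks.items():
            if state not in sets:
                continue
            block_genes = {f"G{i:04d}" for i in idx}
            assert len(sets[state] & block_genes) / len(block_genes) >= 0.9

    def test_identical_expression_yields_no_markers(self):
        X = np.tile(np.arange(1, 41, dtype=float), (60, 1))
        ad = _adata(X)
        clusters = pd.Series(["a"] * 30 + ["b"] * 30, index=ad.obs_names)
        res = cellstate.cluster_markers(ad, clusters)
        assert res.marker_sets() == {}

    def test_singleton_cluster_skipped_with_warning(self, state_adata):
        clusters = pd.Series(
            state_adata.obs["state"].to_numpy(), index=state_adata.obs_names
        ).astype(str)
        clusters.iloc[0] = "lonely"
        with pytest.warns(UserWarning, match="lonely"):
            res = cellstate.cluster_markers(state_adata, clusters)
        assert "lonely" not in set(res.table["cluster"])


class TestJaccard:
    def test_identity_disjoint_and_arithmetic(self):
        a = {"x": set("abcdefghij"), "y": set("qrstu")}
        b = {"x": set("abcde" + "klmno"), "z": set("zw")}
        J = cellstate.marker_jaccard(a, b)
        assert J.loc["x", "x"] == pytest.approx(5 / 15)
        assert J.loc["y", "z"] == 0.0
        same = cellstate.marker_jaccard(a, a)
        assert same.loc["x", "x"] == 1.0 and same.loc["y", "y"] == 1.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        sets_a = {f"a{i}": set(rng.choice(50, rng.integers(1, 20), replace=False)) for i in range(4)}
        sets_b = {f"b{i}": set(rng.choice(50, rng.integers(1, 20), replace=False)) for i in range(3)}
        J = cellstate.marker_jaccard(sets_a, sets_b)
        Jt = cellstate.marker_jaccard(sets_b, sets_a)
        assert ((J >= 0) & (J <= 1)).all().all()
        np.testing.assert_allclose(J.to_numpy(), Jt.to_numpy().T)

    def test_empty_pair_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            J = cellstate.marker_jaccard({"a": set()}, {"b": set()})
        assert J.loc["a", "b"] == 0.0


class TestRacSignature:
    def test_min_rule_and_ranking(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(2, size=(40, 60)).astype(float)
        X[:, 3] += 50.0  # planted top gene
        ad = _adata(X)
        intersect = list(ad.var_names[:30])
        sig = cellstate.rac_signature(intersect, ad, n_top=50)
        assert len(sig) == 30  # min(n_top, |intersect|)
        assert sig[0] == "g0003"
        top5 = cellstate.rac_signature(intersect, ad, n_top=5)
        assert len(top5) == 5 and top5[0] == "g0003"

    def test_empty_intersect_rejected(self):
        ad = _adata(np.ones((5, 5)))
        with pytest.raises(ValueError):
            cellstate.rac_signature(["absent1", "absent2"], ad)


class TestModuleScore:
    def test_constant_matrix_scores_exactly_zero(self):
        ad = _adata(np.full((40, 120), 3.25))
        s = cellstate.module_score(ad, list(ad.var_names[:8]), n_bins=10, n_ctrl=20, seed=0)
        assert (s.scores == 0.0).all()

    def test_random_signature_on_shuffled_data_centres_at_zero(self):
        rng = np.random.default_rng(4)
        X = rng.permuted(rng.lognormal(0, 1, size=(150, 400)), axis=0)
        ad = _adata(X)
        means = []
        for draw in range(50):
            genes = list(rng.choice(ad.var_names, 15, replace=False))
            s = cellstate.module_score(ad, genes, seed=draw)
            means.append(s.scores.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-12

    def test_planted_module_separates_states(self, state_adata):
        blocks = state_adata.uns["truth"]["marker_blocks"]
        genes = [f"G{i:04d}" for i in blocks["MES-like"]]
        s = cellstate.module_score(state_adata, genes, seed=0)
        is_state = (state_adata.obs["state"] == "MES-like").to_numpy()
        assert roc_auc_score(is_state, s.scores) > 0.95

    def test_invariant_to_gene_order(self):
        # permuting the columns (genes travel with their values) must not
        # change scores: binning and control draws are order-independent
        rng = np.random.default_rng(5)
        X = rng.lognormal(0, 1, size=(60, 200))
        ad = _adata(X)
        sig = list(ad.var_names[:10])
        s1 = cellstate.module_score(ad, sig, seed=9)
        perm = rng.permutation(ad.n_vars)
        ad2 = _adata(X[:, perm], genes=list(np.array(ad.var_names)[perm]))
        s2 = cellstate.module_score(ad2, sig, seed=9)
        np.testing.assert_allclose(s1.scores.to_numpy(), s2.scores.to_numpy())
        assert s1.control_genes == s2.control_genes

    def test_missing_genes_dropped_with_warning(self):
        ad = _adata(np.random.default_rng(0).lognormal(0, 1, (20, 100)))
        with pytest.warns(UserWarning, match="absent"):
            s = cellstate.module_score(ad, ["g0001", "nope"], n_ctrl=10)
        assert s.genes == ["g0001"]
        with pytest.raises(ValueError):
            cellstate.module_score(ad, ["nope"])


class TestCellCycle:
    def test_planted_cycle_phases_classified(self):
        cfg = synthio.SynthConfig(
            seed=13, cells_per_condition=80, n_genes=600, cycle_effect=2.0
        )
        adata = synthio.gen_state_mixture_counts(cfg)
        from irpdx import xenodeconv

        adata, _ = xenodeconv.qc_filter(adata)
        adata = xenodeconv.normalize_log(adata)
        blocks = adata.uns["truth"]["marker_blocks"]
        s_genes = [f"G{i:04d}" for i in blocks["S"]]
        g2m_genes = [f"G{i:04d}" for i in blocks["G2M"]]
        res = cellstate.cell_cycle_assign(adata, s_genes, g2m_genes, seed=0)
        acc = (res["phase"] == adata.obs["phase"]).mean()
        assert acc >= 0.95


class TestCohortCompare:
    def test_degenerate_equal_scores(self):
        n = 40
        scores = pd.Series(np.ones(n))
        tumour = pd.Series([f"t{i % 4}" for i in range(n)])
        cond = pd.Series(["primary"] * 20 + ["recurrent"] * 20)
        out = cellstate.cohort_compare(scores, tumour, cond)
        assert all(v == 0 for v in out["high_fraction"].values())
        assert all(np.isnan(p) for p in out["ranksum_p"].values())

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        rows = []
        for cond, delta, tumours in (("primary", 0.0, 6), ("recurrent", 1.0, 6)):
            for t in range(tumours):
                for _ in range(50):
                    rows.append((rng.normal(delta, 1.0), f"{cond}_t{t}", cond))
        df = pd.DataFrame(rows, columns=["score", "tumour", "condition"])
        out = cellstate.cohort_compare(df["score"], df["tumour"], df["condition"])
        means = out["tumour_means"].groupby("condition")["score"].mean()
        assert means["recurrent"] > means["primary"]
        assert out["ranksum_p"][("primary", "recurrent")] < 0.05
        assert out["high_fraction"]["recurrent"] > out["high_fraction"]["primary"]
        # pooled threshold is mean + 2 sd of all scores
        assert out["threshold"] == pytest.approx(
            df["score"].mean() + 2 * df["score"].std(ddof=1)
        )

    def test_single_tumour_condition_reports_undefined_p(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "score": rng.normal(size=30),
                "tumour": ["a"] * 15 + ["b"] * 5 + ["c"] * 10,
                "condition": ["primary"] * 15 + ["recurrent"] * 15,
            }
        )
        out = cellstate.cohort_compare(df["score"], df["tumour"], df["condition"])
        assert np.isnan(out["ranksum_p"][("primary", "recurrent")])
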