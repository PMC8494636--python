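import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from epiretro.differential_stats import (
    call_dmgs,
    ch_dmg_lmm,
    enrichment_test,
    naive_ttest,
    overlap_score,
)
from epiretro.synthetic_data import simulate_lmm_dataset


class TestChDmgLmm:
    def test_planted_effect_recovered_with_correct_sign(self):
        resp, design, _ = simulate_lmm_dataset(n_genes=8, n_per_group=120, delta=0.2, seed=1)
        res = ch_dmg_lmm(resp, design, covariates=("sex", "global_mch"))
        assert res["converged"].all()
        assert (res["coef"] > 0.1).all()
        assert (res["fdr"] < 0.01).all()

    def test_requires_binary_group(self):
        resp, design, _ = simulate_lmm_dataset(n_genes=2, n_per_group=20, seed=2)
        design.loc[0, "group"] = "C"
        with pytest.raises(ValueError, match="binary"):
            ch_dmg_lmm(resp, design)

    def test_requires_multiple_mice(self):
        resp, design, _ = simulate_lmm_dataset(n_genes=2, n_per_group=20, seed=3)
        design["mouse"] = "m0"
        with pytest.raises(ValueError, match="mice"):
            ch_dmg_lmm(resp, design)

    def test_cluster_covariate_absorbs_composition_difference(self):
        # group B over-represents a high-mCH cluster; with the cluster as a
        # covariate the target coefficient stays near zero
        rng = np.random.default_rng(4)
        n = 300
        group = np.repeat(["A", "B"], n // 2)
        cluster = np.where(
            rng.random(n) < np.where(group == "A", 0.2, 0.8), "c_hi", "c_lo"
        )
        resp = (0.5 + 0.3 * (cluster == "c_hi") + rng.normal(0, 0.05, n))[:, None]
        design = pd.DataFrame(
            {
                "group": group,
                "cluster": cluster,
                "mouse": rng.choice(["m0", "m1", "m2", "m3"], n),
                "sex": rng.choice(["M", "F"], n),
                "global_mch": np.ones(n),
            }
        )
        with_cov = ch_dmg_lmm(resp, design, covariates=("cluster", "sex"))
        without = ch_dmg_lmm(resp, design, covariates=("sex",))
        assert abs(with_cov["coef"][0]) < 0.02
        assert without["coef"][0] > 0.1


class TestCallDmgs:
    def _results(self, fc, fdr):
        return pd.DataFrame(
            {
                "gene": ["g"],
                "coef": [0.1],
                "se": [0.01],
                "z": [10.0],
                "p_value": [1e-10],
                "fold_change": [fc],
                "converged": [True],
                "fdr": [fdr],
            }
        )

    def test_cluster_context_needs_fold_one_point_five(self):
        assert len(call_dmgs(self._results(1.6, 0.001), "l5et_clusters")) == 1
        assert len(call_dmgs(self._results(1.3, 0.001), "l5et_clusters")) == 0

    def test_target_context_needs_fold_one_point_two_five(self):
        assert len(call_dmgs(self._results(1.3, 0.001), "targets")) == 1
        assert len(call_dmgs(self._results(1.2, 0.001), "targets")) == 0

    def test_equal_means_never_called(self):
        assert len(call_dmgs(self._results(1.0, 1e-9), "targets")) == 0

    def test_fdr_gate(self):
        assert len(call_dmgs(self._results(2.0, 0.02), "targets")) == 0


class TestEnrichment:
    def _table(self, counts):
        rows = []
        rng = np.random.default_rng(0)
        for ci, row in enumerate(counts):
            for ti, n in enumerate(row):
                for _ in range(n):
                    rows.append(
                        {
                            "cluster": f"c{ci}",
                            "target": f"t{ti}",
                            "mouse": f"m{rng.integers(4)}",
                        }
                    )
        return pd.DataFrame(rows)

    def test_uniform_table_has_zero_enrichment(self):
        res = enrichment_test(self._table([[20, 20], [20, 20]]))
        assert np.allclose(res["rel_enrichment"], 0.0)

    def test_hand_computed_expected_counts(self):
        res = enrichment_test(self._table([[30, 10], [10, 30]]))
        res = res.set_index(["cluster", "target"])
        assert res.loc[("c0", "t0"), "expected"] == pytest.approx(20.0)
        assert res.loc[("c0", "t0"), "rel_enrichment"] == pytest.approx(0.5)
        assert res.loc[("c0", "t1"), "rel_enrichment"] == pytest.approx(-0.5)

    def test_observed_minus_expected_sums_to_zero(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(5, 40, size=(3, 2)).tolist()
        res = enrichment_test(self._table(counts))
        assert (res["observed"] - res["expected"]).sum() == pytest.approx(0.0)

    def test_planted_enrichment_flagged(self):
        rng = np.random.default_rng(6)
        n = 400
        target = rng.choice(["A", "B"], size=n)
        probs = {"A": [0.5, 0.25, 0.25], "B": [0.17, 0.415, 0.415]}
        cluster = np.array([f"c{rng.choice(3, p=probs[t])}" for t in target])
        tbl = pd.DataFrame(
            {"cluster": cluster, "target": target,
             "mouse": rng.choice(["m0", "m1", "m2", "m3"], n)}
        )
        res = enrichment_test(tbl).set_index(["cluster", "target"])
        assert res.loc[("c0", "A"), "fdr"] < 0.05
        assert res.loc[("c0", "A"), "rel_enrichment"] > 0


class TestOverlapScore:
    def test_identical_distributions_score_one(self):
        groups = ["g1"] * 10 + ["g2"] * 10
        clusters = ([0] * 5 + [1] * 5) * 2
        om = overlap_score(groups, clusters)
        assert om.scores.loc["g1", "g2"] == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self):
        groups = ["g1"] * 5 + ["g2"] * 5
        clusters = [0] * 5 + [1] * 5
        om = overlap_score(groups, clusters)
        assert om.scores.loc["g1", "g2"] == 0.0

    def test_hand_computed_half(self):
        groups = ["g1"] * 4 + ["g2"] * 4
        clusters = [0, 0, 1, 1, 0, 1, 2, 2]
        om = overlap_score(groups, clusters)
        # D1 = (.5, .5, 0), D2 = (.25, .25, .5) -> sum of minima = 0.5
        assert om.scores.loc["g1", "g2"] == pytest.approx(0.5)

    def test_diagonal_is_one_and_symmetric(self):
        rng = np.random.default_rng(7)
        groups = rng.choice(["a", "b", "c"], 60)
        clusters = rng.integers(4, size=60)
        om = overlap_score(groups, clusters)
        assert np.allclose(np.diag(om.scores), 1.0)
        assert np.allclose(om.scores, om.scores.T)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 3)), min_size=4, max_size=60))
    def test_equals_one_minus_total_variation(self, pairs):
        groups = [g for g, _ in pairs]
        clusters = [c for _, c in pairs]
        if len(set(groups)) < 2:
            groups[0], groups[1] = 0, 1
        om = overlap_score(groups, clusters)
        D = om.distributions
        tv = 0.5 * np.abs(D.loc[0] - D.loc[1]).sum()
        assert om.scores.loc[0, 1] == pytest.approx(1.0 - tv)


class TestBenjaminiHochberg:
    def test_matches_direct_step_up_implementation(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            p = rng.uniform(size=40)
            _, q, _, _ = multipletests(p, method="fdr_bh")
            # independent direct step-up: q_i = min over j>=rank(i) of p_j*n/j
            order = np.argsort(p)
            n = len(p)
            adj = p[order] * n / np.arange(1, n + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            direct = np.empty(n)
            direct[order] = np.minimum(adj, 1.0)
            assert np.allclose(q, direct)


class TestNaiveComparison:
    def test_naive_test_ignores_mouse_structure(self):
        resp, design, _ = simulate_lmm_dataset(
            n_genes=20, n_per_group=150, confound_by_mouse=True,
            sigma_mouse=0.05, n_mice=20, seed=9,
        )
        naive_p = naive_ttest(resp, design)
        lmm = ch_dmg_lmm(resp, design, covariates=("sex", "global_mch"))
        # the naive test finds many "significant" genes; the mixed model's
        # p-values are systematically larger on the same data
        assert (naive_p < 0.01).sum() >= 5
        assert (lmm["p_value"].to_numpy() > naive_p).mean() > 0.8
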