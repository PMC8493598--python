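import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import braingraph as bg
from braingraph.errors import InputError
from braingraph.stats import GroupComparison, encode_gender, metric_families
from oracles import bh_stepup, oneway_anova_f, pooled_t


class TestAncova:
    def test_no_covariates_equals_oneway_anova(self):
        groups = [np.array([1.0, 2.0, 3.0]),
                  np.array([2.0, 4.0, 6.0]),
                  np.array([5.0, 6.0, 10.0])]
        y = np.concatenate(groups)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f, p = bg.ancova_group_test(y, labels)
        assert f == pytest.approx(oneway_anova_f(groups), abs=1e-10)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        n = 60
        labels = np.repeat(["a", "b", "c"], n // 3)
        rejections = 0
        reps = 100
        for _ in range(reps):
            cov = pd.DataFrame({"age": rng.normal(50, 5, n),
                                "mean_fd": rng.uniform(0.02, 0.1, n)})
            y = rng.standard_normal(n)
            _, p = bg.ancova_group_test(y, labels, cov)
            rejections += p < 0.05
        from scipy.stats import binom
        lo, hi = binom.ppf([0.0025, 0.9975], reps, 0.05)
        assert lo <= rejections <= hi

    def test_confounded_effect_absorbed_by_covariate(self):
        # metric is a pure function of age; ages differ by group
        rng = np.random.default_rng(1)
        n = 60
        labels = np.repeat(["a", "b", "c"], n // 3)
        n_unadj = n_adj = n_unadj_sig = 0
        for _ in range(50):
            age = np.concatenate([rng.normal(45, 2, 20), rng.normal(55, 2, 20),
                                  rng.normal(65, 2, 20)])
            y = 0.5 * age + rng.normal(0, 0.5, n)
            _, p_un = bg.ancova_group_test(y, labels)
            _, p_ad = bg.ancova_group_test(y, labels, pd.DataFrame({"age": age}))
            if p_un < 0.05:
                n_unadj_sig += 1
                if p_ad >= 0.05:
                    n_adj += 1
        assert n_unadj_sig > 0
        assert n_adj >= 0.9 * n_unadj_sig

    def test_reference_level_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(30)
        g1 = np.repeat(["a", "b", "c"], 10)
        g2 = np.repeat(["z", "b", "c"], 10)  # different sorted order, same partition
        f1, p1 = bg.ancova_group_test(y, g1)
        f2, p2 = bg.ancova_group_test(y, g2)
        assert f1 == pytest.approx(f2) and p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            bg.ancova_group_test(np.arange(6.0), ["a"] * 6)


class TestPosthoc:
    def test_closed_form_pooled_t(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = ["A", "A", "A", "B", "B", "B"]
        t, p = bg.posthoc_pairwise(y, g, ("A", "B"))
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert t == pytest.approx(pooled_t(y[:3], y[3:]), abs=1e-10)

    def test_swapping_pair_flips_sign(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(20)
        g = ["A"] * 10 + ["B"] * 10
        t1, p1 = bg.posthoc_pairwise(y, g, ("A", "B"))
        t2, p2 = bg.posthoc_pairwise(y, g, ("B", "A"))
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_identical_groups_t_zero(self):
        y = np.tile([1.0, 2.0, 3.0], 2)
        g = ["A"] * 3 + ["B"] * 3
        t, _ = bg.posthoc_pairwise(y, g, ("A", "B"))
        assert t == pytest.approx(0, abs=1e-12)


class TestBhFdr:
    def test_stepup_hand_case(self):
        flags, adj = bg.bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05)
        assert flags.all()
        np.testing.assert_allclose(adj, 0.04)

    def test_all_ones_none_flagged(self):
        flags, _ = bg.bh_fdr(np.ones(5))
        assert not flags.any()

    def test_single_p_reduces_to_threshold(self):
        assert bg.bh_fdr([0.04], 0.05)[0][0]
        assert not bg.bh_fdr([0.06], 0.05)[0][0]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 500), m=st.integers(1, 40))
    def test_matches_hand_stepup_and_contains_bonferroni(self, seed, m):
        p = np.random.default_rng(seed).uniform(0, 1, m)
        flags, adj = bg.bh_fdr(p, 0.05)
        oflags, oadj = bh_stepup(p, 0.05)
        np.testing.assert_array_equal(flags, oflags)
        np.testing.assert_allclose(adj, oadj, atol=1e-12)
        bonf = p <= 0.05 / m
        assert np.all(flags[bonf])  # BH flags are a superset of Bonferroni


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 50))
        res = bg.partial_correlation(x, y)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_perfect_correlation(self):
        x = np.arange(20.0)
        res = bg.partial_correlation(x, x)
        assert res.r == pytest.approx(1.0)

    def test_generative_recovery_and_pingouin_crosscheck(self):
        rng = np.random.default_rng(5)
        n = 500
        z = rng.standard_normal(n)
        w = rng.standard_normal((n, 2))
        w[:, 1] = 0.5 * w[:, 0] + np.sqrt(1 - 0.25) * w[:, 1]  # corr(w1,w2)=0.5
        x = 2.0 * z + w[:, 0]
        y = -1.5 * z + w[:, 1]
        res = bg.partial_correlation(x, y, z[:, None])
        assert abs(res.r - 0.5) < 0.1
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_affine_covariate_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 60))
        c = rng.standard_normal((60, 2))
        r1 = bg.partial_correlation(x, y, c).r
        r2 = bg.partial_correlation(x, y, 3.0 * c + 11.0).r
        assert r1 == pytest.approx(r2, abs=1e-10)


def make_table(rng, n_per_group=12, effect=0.0):
    groups = np.repeat(["C", "NC", "HC"], n_per_group)
    n = groups.size
    shift = np.where(groups == "C", effect, 0.0)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": groups,
        "age": rng.normal(54, 6, n),
        "gender": rng.choice(["M", "F"], n),
        "mean_fd": rng.uniform(0.03, 0.12, n),
        "Eloc_auc": rng.standard_normal(n) + shift,
        "Cp_auc": rng.standard_normal(n),
        "BC_auc_node0": rng.standard_normal(n),
        "BC_auc_node1": rng.standard_normal(n),
    })


class TestGroupComparisonModel:
    def test_families_default_split(self):
        fams = metric_families(["Cp_auc", "Eloc_auc", "BC_auc_node0", "BC_auc_node1"])
        assert fams["global"] == ["Cp_auc", "Eloc_auc"]
        assert fams["BC_nodal"] == ["BC_auc_node0", "BC_auc_node1"]

    def test_gate_no_posthoc_for_nonsignificant(self, rng):
        res = GroupComparison(make_table(rng, effect=3.0)).fit()
        tested = set(res.posthoc["metric"])
        assert tested <= set(res.significant_metrics)

    def test_strong_effect_detected_with_direction(self, rng):
        res = GroupComparison(make_table(rng, effect=3.0)).fit()
        assert "Eloc_auc" in res.significant_metrics
        ph = res.posthoc
        row = ph[(ph.metric == "Eloc_auc") & (ph.group_a == "C") & (ph.group_b == "HC")]
        assert row.iloc[0]["t"] > 0

    def test_single_group_refused(self, rng):
        tab = make_table(rng)
        tab["group"] = "only"
        with pytest.raises(InputError):
            GroupComparison(tab)

    def test_missing_covariate_refused(self, rng):
        tab = make_table(rng).drop(columns=["mean_fd"])
        with pytest.raises(InputError):
            GroupComparison(tab)

    def test_gender_encoding_deterministic(self):
        np.testing.assert_array_equal(encode_gender(["M", "F", "M"]), [1.0, 0.0, 1.0])
        np.testing.assert_array_equal(encode_gender([0, 1, 0]), [0.0, 1.0, 0.0])

    def test_partial_correlations_table(self, rng):
        tab = make_table(rng, effect=3.0)
        metric_cols = [c for c in tab.columns if "_auc" in c]
        tab["HbA1c"] = tab["Eloc_auc"] * 0.5 + rng.standard_normal(len(tab))
        res = GroupComparison(tab, metric_cols=metric_cols).fit()
        corr = res.partial_correlations(["HbA1c"], groups=["C", "NC"])
        assert set(corr["group"]) == {"C", "NC", "C+NC"}
        assert ((corr["r"] <= 1) & (corr["r"] >= -1)).all()

    def test_summary_mentions_metrics(self, rng):
        res = GroupComparison(make_table(rng, effect=3.0)).fit()
        text = res.summary()
        assert "Eloc_auc" in text and "FDR" in text

    def test_full_inference_runs(self, rng):
        tab = make_table(rng, effect=3.0)
        metric_cols = [c for c in tab.columns if "_auc" in c]
        tab["HbA1c"] = rng.standard_normal(len(tab)) + 8
        results, corr = bg.full_inference(tab, clinical_cols=["HbA1c"],
                                          patient_groups=["C", "NC"],
                                          metric_cols=metric_cols)
        assert {"metric", "F", "p", "p_fdr", "significant"} <= set(results.omnibus.columns)
        if results.significant_metrics:
            assert set(corr["variable"]) == {"HbA1c"}
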