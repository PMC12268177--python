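"""Normalization, time-course DEG test, clustering, fold-change rules."""

import numpy as np
import pandas as pd
import pytest

from dhsdyn.expression import (
    CountMatrix,
    bh_adjust,
    cluster_profiles,
    expression_values,
    fold_change_deg,
    log_display,
    timecourse_deg,
    tmm_factors,
    two_group_test,
)

TIMES_8 = np.repeat([12.0, 13.0, 14.0, 16.0], 2)


def make_counts(X, lengths=None):
    X = np.asarray(X)
    samples = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(X.shape[1])],
            "stage": [f"t{i // 2}" for i in range(X.shape[1])],
            "replicate": [i % 2 + 1 for i in range(X.shape[1])],
            "time": list(TIMES_8[: X.shape[1]]),
        }
    )
    idx = pd.Index([f"g{i}" for i in range(X.shape[0])], name="gene_id")
    counts = pd.DataFrame(X, index=idx, columns=samples["sample"])
    lengths = pd.Series(lengths if lengths is not None else 1000, index=idx)
    return CountMatrix(counts, lengths, samples)


class TestTmm:
    def test_identical_samples_all_factors_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=200)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), 1.0, rtol=1e-12)

    def test_doubled_sample_closed_form(self):
        """B = 2 x A at equal library sizes: all M-values are 1, so the
        factors are (1/sqrt(2), sqrt(2)) after geometric-mean scaling."""
        rng = np.random.default_rng(1)
        a = rng.integers(1, 400, size=300)
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = tmm_factors(counts, library_sizes=np.array([1.0, 1.0]))
        np.testing.assert_allclose(
            f.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-9
        )

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 800, size=(500, 6)),
                              columns=[f"s{i}" for i in range(6)])
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 800, size=(300, 4)),
                              columns=list("abcd"))
        f1 = tmm_factors(counts)
        f2 = tmm_factors(counts.sample(frac=1, random_state=0))
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-12)

    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero"):
            tmm_factors(counts)


class TestExpressionValues:
    def test_stated_formula(self):
        cm = make_counts(np.array([[100, 100]] * 2), lengths=[2000, 2000])
        # force library size 1e6 and factor 1 by construction
        cm.counts.iloc[:, :] = 0
        cm.counts.iloc[0] = [100, 100]
        cm.counts.loc["g1"] = [10**6 - 100] * 2
        factors = pd.Series([1.0, 1.0], index=cm.counts.columns)
        values = expression_values(cm, factors)
        assert values.loc["g0", "s0"] == pytest.approx(100 / 1e6 * 1e6 / 2.0)

    def test_zero_count_zero_value(self):
        cm = make_counts([[0, 5], [10, 10]])
        values = expression_values(cm, pd.Series(1.0, index=cm.counts.columns))
        assert values.iloc[0, 0] == 0.0

    def test_depth_invariance_under_library_scaling(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 500, size=(300, 4))
        cm = make_counts(X)
        scaled = X.copy()
        scaled[:, 2] *= 7  # deeper sequencing of one library
        cm2 = make_counts(scaled)
        v1 = expression_values(cm, tmm_factors(cm.counts))
        v2 = expression_values(cm2, tmm_factors(cm2.counts))
        np.testing.assert_allclose(v1.to_numpy(), v2.to_numpy(), rtol=1e-9)

    def test_log_display_convention(self):
        s = pd.Series([0.0, 3.0, 10.0])
        assert log_display(s).tolist() == [1.0, 4.0, 11.0]
        assert log_display(s, offset=0).tolist() == s.tolist()
        assert (log_display(s).diff().dropna() > 0).all()  # order preserved


class TestTimecourse:
    def test_flat_noiseless_gene_not_deg(self):
        expr = pd.DataFrame([[5.0] * 8], index=["flat"])
        res = timecourse_deg(expr, TIMES_8)
        assert res.table.loc["flat", "pvalue"] == 1.0
        assert not res.table.loc["flat", "is_deg"]

    def test_exact_cubic_saturates(self):
        t = TIMES_8
        y = np.exp(0.5 * (t - 13.0) ** 3 / 10 + 1.0) - 1.0  # exact cubic in log space
        expr = pd.DataFrame([y, [2.0] * 8], index=["cubic", "flat"])
        res = timecourse_deg(expr, t)
        assert res.table.loc["cubic", "pvalue"] < 1e-12
        assert res.table.loc["cubic", "is_deg"]

    def test_qvalues_bound_pvalues(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(np.exp(rng.standard_normal((50, 8))) - 1 + 1.0)
        res = timecourse_deg(expr, TIMES_8)
        assert (res.table["qvalue"] >= res.table["pvalue"] - 1e-15).all()

    def test_type_one_error_calibrated(self):
        """2000 null genes with iid Gaussian log-signal: raw rejections ~ alpha."""
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(np.exp(rng.standard_normal((2000, 8))) - 1.0)
        res = timecourse_deg(expr, TIMES_8)
        assert (res.table["pvalue"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)
        assert res.table["is_deg"].sum() <= 5


class TestClustering:
    def test_planted_orthogonal_profiles_recovered(self):
        base = np.eye(4)  # four orthogonal stage profiles
        expr = pd.DataFrame(
            np.repeat(np.repeat(base, 5, axis=0), 2, axis=1),
            index=[f"g{i}" for i in range(20)],
        )
        expr.columns = [f"s{i}" for i in range(8)]
        labels = cluster_profiles(expr, [f"t{i // 2}" for i in range(8)], k=4, seed=0)
        for i in range(4):
            block = labels.iloc[5 * i: 5 * (i + 1)]
            assert block.nunique() == 1
        assert labels.nunique() == 4

    def test_duplicated_gene_same_cluster(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.random((30, 8)), index=[f"g{i}" for i in range(30)])
        expr.loc["g1"] = expr.loc["g0"]
        labels = cluster_profiles(expr, [f"t{i // 2}" for i in range(8)], k=3, seed=1)
        assert labels["g0"] == labels["g1"]

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.random((40, 8)))
        stages = [f"t{i // 2}" for i in range(8)]
        l1 = cluster_profiles(expr, stages, k=5, seed=42)
        l2 = cluster_profiles(expr, stages, k=5, seed=42)
        assert l1.equals(l2)

    def test_too_few_genes_errors(self):
        expr = pd.DataFrame(np.random.default_rng(9).random((4, 8)))
        with pytest.raises(ValueError, match="smaller k"):
            cluster_profiles(expr, [f"t{i // 2}" for i in range(8)], k=9, seed=0)


class TestTwoSampleRules:
    def test_fold_change_with_pseudocount(self):
        a = pd.Series({"g1": 0.0, "g2": 5.0, "g3": 9.0})
        b = pd.Series({"g1": 3.0, "g2": 5.0, "g3": 1.0})
        up, down = fold_change_deg(a, b)
        assert up == {"g1"}  # (3+1)/(0+1) = 4 > 2
        assert down == {"g3"}  # (9+1)/(1+1) = 5 > 2

    def test_equal_values_neither(self):
        a = pd.Series({"g": 4.0})
        up, down = fold_change_deg(a, a)
        assert up == down == set()

    def test_threshold_near_one_splits_any_unequal_pair(self):
        a = pd.Series({"g": 2.0})
        b = pd.Series({"g": 2.5})
        up, down = fold_change_deg(a, b, threshold=1 + 1e-9)
        assert up == {"g"} and down == set()

    def test_t_statistic_matches_hand_computation(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        b = pd.DataFrame([[4.0, 6.0, 8.0]], index=["g"])
        res = two_group_test(a, b)
        # pooled variance: s2 = (SSa + SSb)/(3+3-2) = (2 + 8)/4 = 2.5
        t_hand = (2.0 - 6.0) / np.sqrt(2.5 * (2 / 3))
        assert res.loc["g", "t"] == pytest.approx(t_hand, rel=1e-12)

    def test_identical_groups_no_degs(self):
        rng = np.random.default_rng(10)
        a = pd.DataFrame(rng.random((20, 3)))
        res = two_group_test(a, a.copy())
        assert not res["is_deg"].any()
        assert res.loc[res["pvalue"].notna(), "pvalue"].min() == pytest.approx(1.0)

    def test_planted_large_shift_detected(self):
        rng = np.random.default_rng(11)
        a = pd.DataFrame(rng.standard_normal((50, 3)))
        b = pd.DataFrame(rng.standard_normal((50, 3)))
        b.iloc[0] += 10.0  # 10 group SDs
        res = two_group_test(a, b)
        assert res.iloc[0]["is_deg"]


class TestBh:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), 0.2)

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)
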