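import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evcargo.core_io import ExpressionMatrix, ValidationError
from evcargo.synthetic import SimulationConfig, simulate_cohort
from evcargo.core_io import filter_expressed, normalize_rpm
from evcargo.trajectory import (
    age_correlation,
    baseline_relative_expression,
    classify_nonlinear,
    distance_correlation,
    mean_shift_permutation_test,
    quadrant_concordance,
    trajectory_stats,
)

AGES = np.array([2.0, 6.0, 8.0, 12.0, 18.0])


def brute_force_dcor(x, y):
    """Independent O(n^2) double-centring oracle (explicit loops)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    a = np.empty((n, n))
    b = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = abs(x[i] - x[j])
            b[i, j] = abs(y[i] - y[j])
    A = np.empty((n, n))
    B = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a[i, j] - a[i, :].mean() - a[:, j].mean() + a.mean()
            B[i, j] = b[i, j] - b[i, :].mean() - b[:, j].mean() + b.mean()
    dcov2 = (A * B).mean()
    dvx = (A * A).mean()
    dvy = (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy))


class TestAgeCorrelation:
    def test_perfect_linear(self):
        assert age_correlation(AGES, AGES) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert age_correlation(-AGES, AGES) == pytest.approx(-1.0)

    def test_textbook_oracle(self):
        values = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        num = ((values - values.mean()) * (AGES - AGES.mean())).sum()
        den = np.sqrt(((values - values.mean()) ** 2).sum() * ((AGES - AGES.mean()) ** 2).sum())
        assert age_correlation(values, AGES) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(age_correlation(np.ones(5), AGES))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            age_correlation(np.ones(4), AGES)


class TestDistanceCorrelation:
    def test_identical_vectors(self):
        assert distance_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_constant_convention(self):
        assert distance_correlation([1, 2, 3], [5, 5, 5]) == 0.0

    def test_brute_force_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 4.0, 9.0, 16.0])
        assert distance_correlation(x, y) == pytest.approx(brute_force_dcor(x, y), abs=1e-12)

    def test_agrees_with_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            assert distance_correlation(x, y) == pytest.approx(
                brute_force_dcor(x, y), abs=1e-10
            )

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            d0 = distance_correlation(x, y)
            assert distance_correlation(3.5 * x + 7, y) == pytest.approx(d0, abs=1e-10)
            assert distance_correlation(x, 0.2 * y - 4) == pytest.approx(d0, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            distance_correlation([1, 2], [1, 2, 3])


class TestClassifyNonlinear:
    def test_points_on_smooth_curve_unflagged(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-1, 1, 60)
        d = 0.3 + 0.2 * r**2  # cubic spline reproduces a quadratic exactly
        stats_df = pd.DataFrame({"pearson_r": r, "dcor": d})
        out = classify_nonlinear(stats_df)
        assert (out["category"] == "linear").all()
        np.testing.assert_allclose(out["residual"], 0.0, atol=1e-8)

    def test_outlier_flagged_with_sign_convention(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(-1, 1, 80)
        d = 0.3 + 0.2 * r**2
        stats_df = pd.DataFrame({"pearson_r": r, "dcor": d})
        # residual +0.20 at pearson_r = -0.3 -> nonlinear_negative
        stats_df.loc[len(stats_df)] = {"pearson_r": -0.3, "dcor": 0.3 + 0.2 * 0.09 + 0.20}
        out = classify_nonlinear(stats_df)
        assert out.iloc[-1]["category"] == "nonlinear_negative"
        # mirrored outlier at +0.3 -> nonlinear_positive
        stats_df.loc[len(stats_df)] = {"pearson_r": 0.3, "dcor": 0.3 + 0.2 * 0.09 + 0.20}
        out = classify_nonlinear(stats_df)
        assert out.iloc[-1]["category"] == "nonlinear_positive"

    def test_flagged_set_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        stats_df = pd.DataFrame(
            {"pearson_r": rng.uniform(-1, 1, 200), "dcor": rng.uniform(0, 1, 200)}
        )
        flagged_prev = None
        for thr in (0.05, 0.1, 0.2, 0.4):
            out = classify_nonlinear(stats_df, threshold=thr)
            flagged = set(out.index[out["category"] != "linear"])
            if flagged_prev is not None:
                assert flagged <= flagged_prev
            flagged_prev = flagged

    def test_too_few_features(self):
        stats_df = pd.DataFrame({"pearson_r": [0.1, 0.2], "dcor": [0.3, 0.4]})
        with pytest.raises(ValidationError):
            classify_nonlinear(stats_df)

    def test_planted_truth_recovery(self):
        cfg = SimulationConfig(seed=7)  # 500 features at defaults
        matrix, samples, _, truth = simulate_cohort(cfg)
        rpm = filter_expressed(normalize_rpm(matrix))
        meta = samples.set_index("sample_id")
        cols = [c for c in rpm.sample_ids if meta.loc[c, "fraction"] == "EV"]
        ages = meta.loc[cols, "age_months"].to_numpy(float)
        out = classify_nonlinear(trajectory_stats(rpm.subset_samples(cols), ages))
        planted = truth.features.loc[out.index, "planted_shape"]
        flagged = out["category"].str.startswith("nonlinear")
        nl = planted == "nonlinear"
        lin = planted.isin(["linear_up", "linear_down"])
        assert flagged[nl].mean() >= 0.90
        assert flagged[lin].mean() <= 0.05


class TestQuadrantConcordance:
    def test_direct_count_example(self):
        r_ev = pd.Series([0.5, -0.5], index=["a", "b"])
        r_fc = pd.Series([0.5, 0.5], index=["a", "b"])
        q = quadrant_concordance(r_ev, r_fc)
        assert q.fractions[("+", "+")] == 0.5
        assert q.fractions[("-", "+")] == 0.5
        assert q.fractions[("+", "-")] == 0.0
        assert sum(q.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_correlations_excluded(self):
        r_ev = pd.Series([0.5, 0.0, -0.2], index=list("abc"))
        r_fc = pd.Series([0.5, 0.3, np.nan], index=list("abc"))
        q = quadrant_concordance(r_ev, r_fc)
        assert q.n_excluded == 2
        assert sum(q.counts.values()) == 1

    def test_chi2_matches_textbook_oracle(self):
        # counts (30, 10, 30, 30): independent goodness-of-fit arithmetic
        r_ev = pd.Series(
            [0.5] * 30 + [0.5] * 10 + [-0.5] * 30 + [-0.5] * 30,
            index=[f"f{i}" for i in range(100)],
        )
        r_fc = pd.Series(
            [0.5] * 30 + [-0.5] * 10 + [0.5] * 30 + [-0.5] * 30,
            index=[f"f{i}" for i in range(100)],
        )
        q = quadrant_concordance(r_ev, r_fc)
        counts = np.array([30, 10, 30, 30])
        expected = 25.0
        chi2 = (((counts - expected) ** 2) / expected).sum()
        p = sps.chi2.sf(chi2, df=3)
        assert q.chi2_stat == pytest.approx(chi2, abs=1e-12)
        assert q.p_value == pytest.approx(p, abs=1e-12)

    def test_exact_multinomial_fallback_small_n(self):
        r_ev = pd.Series([0.5, 0.5, -0.5], index=list("abc"))
        r_fc = pd.Series([0.5, -0.5, 0.5], index=list("abc"))
        q = quadrant_concordance(r_ev, r_fc)
        assert q.method == "exact_multinomial"
        assert 0 < q.p_value <= 1

    def test_all_undefined_error(self):
        with pytest.raises(ValidationError):
            quadrant_concordance(
                pd.Series([0.0], index=["a"]), pd.Series([0.1], index=["a"])
            )


class TestMeanShiftPermutationTest:
    def _matrix(self, values, prefix):
        return ExpressionMatrix(
            pd.DataFrame(
                values,
                index=[f"f{i}" for i in range(values.shape[0])],
                columns=[f"{prefix}{j}" for j in range(values.shape[1])],
            ),
            unit="rpm",
        )

    def test_identical_matrices_zero_difference(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 100, size=(20, 10))
        ages = np.repeat(AGES, 2)
        m1 = self._matrix(v, "a")
        m2 = self._matrix(v, "b")
        res = mean_shift_permutation_test(m1, m2, ages, ages, n_permutations=50, seed=1)
        assert res.observed_difference == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_null(self):
        rng = np.random.default_rng(3)
        v1 = rng.uniform(1, 100, size=(15, 10))
        v2 = rng.uniform(1, 100, size=(15, 10))
        ages = np.repeat(AGES, 2)
        r1 = mean_shift_permutation_test(
            self._matrix(v1, "a"), self._matrix(v2, "b"), ages, ages, 100, seed=9
        )
        r2 = mean_shift_permutation_test(
            self._matrix(v1, "a"), self._matrix(v2, "b"), ages, ages, 100, seed=9
        )
        np.testing.assert_array_equal(r1.null_means, r2.null_means)

    def test_p_value_floor(self):
        rng = np.random.default_rng(4)
        v1 = rng.uniform(1, 100, size=(10, 10))
        ages = np.repeat(AGES, 2)
        res = mean_shift_permutation_test(
            self._matrix(v1, "a"), self._matrix(v1 * 2, "b"), ages, ages, 99, seed=0
        )
        assert res.p_value >= 1 / 100

    def test_invalid_permutation_count(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(1, 10, (5, 10))
        ages = np.repeat(AGES, 2)
        with pytest.raises(ValueError):
            mean_shift_permutation_test(
                self._matrix(v, "a"), self._matrix(v, "b"), ages, ages, 0, seed=0
            )


class TestBaselineRelativeExpression:
    def test_constant_expression_all_zero(self, small_rpm):
        rpm, samples, features, _ = small_rpm
        const = ExpressionMatrix(
            pd.DataFrame(
                100.0, index=rpm.feature_ids, columns=rpm.sample_ids
            ),
            unit="rpm",
        )
        out = baseline_relative_expression(const, samples, features)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_doubling_gives_plus_one(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "mouse_id": ["m1", "m1"],
                "age_months": [2, 18],
                "fraction": ["EV", "EV"],
            }
        )
        features = pd.DataFrame({"feature_id": ["f1"], "rna_class": ["miRNA"]})
        x = ExpressionMatrix(
            pd.DataFrame({"a": [10.0], "b": [20.0]}, index=["f1"]), unit="rpm"
        )
        out = baseline_relative_expression(x, samples, features)
        assert out.loc[("miRNA", "EV"), 18] == pytest.approx(1.0)
        assert out.loc[("miRNA", "EV"), 2] == 0.0

    def test_planted_linear_up_monotone(self):
        cfg = SimulationConfig(
            n_features_per_class=40, class_labels=("miRNA",), linear_fraction=1.0,
            nonlinear_fraction=0.0, discordant_fraction=0.0, effect_size=3.0, seed=13,
        )
        matrix, samples, features, truth = simulate_cohort(cfg)
        rpm = normalize_rpm(matrix)
        up = truth.features.index[truth.features["planted_shape"] == "linear_up"]
        sub = ExpressionMatrix(rpm.data.loc[up], unit="rpm")
        feats = features[features["feature_id"].isin(up)]
        out = baseline_relative_expression(sub, samples, feats)
        row = out.loc[("miRNA", "EV")].to_numpy(dtype=float)
        # oracle: recompute class-total means directly
        meta = samples.set_index("sample_id")
        manual = []
        for age in (2, 6, 8, 12, 18):
            cols = meta.index[(meta["fraction"] == "EV") & (meta["age_months"] == age)]
            manual.append(rpm.data.loc[up, cols].sum(axis=0).mean())
        np.testing.assert_allclose(row, np.log2(np.array(manual) / manual[0]), atol=1e-10)
        assert (np.diff(row) > 0).all()

    def test_missing_baseline_age_error(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["a"],
                "mouse_id": ["m1"],
                "age_months": [18],
                "fraction": ["EV"],
            }
        )
        features = pd.DataFrame({"feature_id": ["f1"], "rna_class": ["miRNA"]})
        x = ExpressionMatrix(pd.DataFrame({"a": [1.0]}, index=["f1"]), unit="rpm")
        with pytest.raises(ValidationError):
            baseline_relative_expression(x, samples, features)
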