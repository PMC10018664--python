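"""Metric suite: hand-computed oracles, invariances, F-test behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respforecast import (
    box_stats,
    compute_report,
    evaluate_split,
    f_test,
    fit_normalizer,
    improvement_pct,
    mae,
    make_supervised,
    nrmse,
    rmse,
    WindowSpec,
)
from respforecast.evaluation import MetricsReport, aggregate_reports


finite_pairs = st.integers(min_value=2, max_value=60).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(-100, 100), min_size=n, max_size=n),
        st.lists(st.floats(-100, 100), min_size=n, max_size=n),
    )
)


class TestPointMetrics:
    def test_rmse_hand_example(self):
        assert rmse([1, 2, 3], [2, 4, 6]) == pytest.approx(np.sqrt(14 / 3))

    def test_rmse_identity_and_constant_offset(self):
        assert rmse([1, 2], [1, 2]) == 0.0
        assert rmse([0, 0, 0], [1, 1, 1]) == 1.0

    def test_mae_hand_example(self):
        assert mae([1, 2, 3], [2, 4, 6]) == pytest.approx(2.0)
        assert mae([0, 0], [1, -1]) == 1.0

    def test_nrmse_is_rmse_over_range(self):
        Y = [0.0, 10.0]
        Yhat = [1.0, 9.0]
        assert nrmse(Y, Yhat) == pytest.approx(rmse(Y, Yhat) / 10.0)

    def test_nrmse_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            nrmse([4.0, 4.0], [1.0, 2.0])

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])
        with pytest.raises(ValueError):
            mae([], [])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(finite_pairs)
    def test_rmse_dominates_mae(self, pair):
        Y, Yhat = pair
        assert rmse(Y, Yhat) >= mae(Y, Yhat) - 1e-12

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        finite_pairs.filter(lambda p: max(p[0]) > min(p[0])),
        st.floats(min_value=0.1, max_value=50).flatmap(
            lambda a: st.tuples(st.sampled_from([a, -a]),
                                st.floats(-100, 100))
        ),
    )
    def test_nrmse_affine_invariance(self, pair, ab):
        Y, Yhat = np.asarray(pair[0]), np.asarray(pair[1])
        a, b = ab
        assert nrmse(a * Y + b, a * Yhat + b) == pytest.approx(
            nrmse(Y, Yhat), rel=1e-9, abs=1e-12
        )

    def test_agreement_with_brute_force_loops(self, rng):
        """Vectorized metrics vs elementwise Python loops, random instances."""
        for _ in range(100):
            n = int(rng.integers(2, 40))
            Y = rng.normal(size=n) * 10
            Yhat = Y + rng.normal(size=n)
            sq = sum((y - p) ** 2 for y, p in zip(Y, Yhat))
            ab = sum(abs(y - p) for y, p in zip(Y, Yhat))
            assert rmse(Y, Yhat) == pytest.approx((sq / n) ** 0.5, rel=1e-12)
            assert mae(Y, Yhat) == pytest.approx(ab / n, rel=1e-12)
            assert nrmse(Y, Yhat) == pytest.approx(
                (sq / n) ** 0.5 / (max(Y) - min(Y)), rel=1e-12
            )


class TestFTest:
    def test_identical_series_give_f_one_p_one(self):
        Y = [1.0, 2.0, 3.0, 4.0]
        F, p = f_test(Y, Y)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_constructed_variance_ratio_four(self):
        Y = [0.0, 2.0, 4.0, 6.0]        # var = 4 x var of Yhat
        Yhat = [0.0, 1.0, 2.0, 3.0]
        F, _ = f_test(Y, Yhat)
        assert F == pytest.approx(4.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            f_test([1.0, 1.0], [1.0, 2.0])

    def test_type_one_error_near_alpha(self, rng):
        """Quick null calibration; the full 2000-replicate run is elsewhere."""
        rejections = 0
        reps = 400
        for _ in range(reps):
            _, p = f_test(rng.normal(size=50), rng.normal(size=50))
            rejections += p < 0.05
        assert 0.02 < rejections / reps < 0.09


class TestBoxStats:
    def test_quartiles_inclusive_linear_interpolation(self):
        b = box_stats([1, 2, 3, 4])
        assert b.median == 2.5
        assert b.q25 == 1.75
        assert b.q75 == 3.25

    def test_all_equal_degenerate_box(self):
        b = box_stats([2.0, 2.0, 2.0, 2.0])
        assert b.median == b.q25 == b.q75 == 2.0
        assert b.whisker_low == b.whisker_high == 2.0
        assert b.outliers.size == 0

    def test_extreme_point_beyond_2p7_sd_flagged(self):
        x = [0] * 9 + [100]             # mean 10, SD ~29.7, 2.7 SD ~80.2
        b = box_stats(x)
        np.testing.assert_array_equal(b.outliers, [100])
        assert b.whisker_high == 0.0    # whiskers exclude the outlier

    def test_whiskers_at_most_extreme_non_outliers(self, rng):
        x = np.concatenate([rng.normal(size=200), [50.0]])
        b = box_stats(x)
        assert 50.0 in b.outliers
        kept = x[np.abs(x - x.mean()) <= 2.7 * x.std()]
        assert b.whisker_high == kept.max()
        assert b.whisker_low == kept.min()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            box_stats([1.0, 2.0, 3.0])


class TestImprovement:
    def test_reference_predictor_worked_example(self):
        """0.14 mm reference vs 0.108 mm achieved: almost 23% improvement."""
        pct = improvement_pct(0.14, 0.108)
        assert pct == pytest.approx(100 * (0.14 - 0.108) / 0.14)
        assert round(pct) == 23

    def test_identity_and_quarter_reduction(self):
        assert improvement_pct(0.5, 0.5) == 0.0
        assert improvement_pct(1.0, 0.75) == 25.0

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            improvement_pct(0.0, 0.1)


class _EchoPredictor:
    """Stands in for a trained model; returns canned predictions."""

    def __init__(self, outputs):
        self.outputs = np.asarray(outputs, dtype=float)

    def predict(self, X):
        return self.outputs


class TestEvaluateSplit:
    @pytest.fixture()
    def toy(self):
        samples_mm = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 8.0, 4.0])
        norm = fit_normalizer(samples_mm)
        test_set = make_supervised(norm.transform(samples_mm),
                                   WindowSpec(2, 1, 1))
        return norm, test_set

    def test_perfect_predictor_scores_zero(self, toy):
        norm, test_set = toy
        rep = evaluate_split(_EchoPredictor(test_set.targets[:, 0]),
                             test_set, norm)
        assert rep.rmse_mm == rep.mae_mm == rep.nrmse == 0.0
        assert rep.f_stat == pytest.approx(1.0)

    def test_constant_predictor_matches_hand_computation(self, toy):
        norm, test_set = toy
        const = np.full(len(test_set), 0.5)
        rep = evaluate_split(_EchoPredictor(const), test_set, norm)
        truth_mm = norm.inverse_transform(test_set.targets).ravel()
        pred_mm = norm.inverse_transform(const)
        assert rep.rmse_mm == pytest.approx(rmse(truth_mm, pred_mm))
        assert rep.mae_mm == pytest.approx(mae(truth_mm, pred_mm))
        assert rep.n == len(test_set)
        assert rep.y_min_mm == truth_mm.min()
        assert rep.y_max_mm == truth_mm.max()

    def test_metrics_are_in_millimetres_not_normalized(self, toy):
        norm, test_set = toy
        off = test_set.targets[:, 0] + 0.1   # 0.1 normalized = 1 mm here
        rep = evaluate_split(_EchoPredictor(off), test_set, norm)
        assert rep.rmse_mm == pytest.approx(1.0)

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError):
            MetricsReport(n=1, rmse_mm=-1, mae_mm=0, nrmse=0, f_stat=1,
                          p_value=0.5, y_min_mm=0, y_max_mm=1)
        with pytest.raises(ValueError):
            MetricsReport(n=1, rmse_mm=0, mae_mm=0, nrmse=0, f_stat=1,
                          p_value=1.5, y_min_mm=0, y_max_mm=1)


class TestAggregation:
    def test_identical_reports_mean_equals_value_sd_zero(self):
        rep = compute_report([1.0, 2.0, 3.0], [1.1, 2.1, 3.1])
        agg = aggregate_reports([rep] * 4)
        assert agg["rmse_mm_mean"] == pytest.approx(rep.rmse_mm)
        assert agg["rmse_mm_sd"] == 0.0
        assert agg["n_signals"] == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_reports([])
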