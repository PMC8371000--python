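"""LAPE threshold classifiers: linear rounding and forest probability curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aoqc import (
    classify_by_thresholds,
    estimate_thresholds,
    fit_linear_model,
    fit_random_forest,
    predict_linear,
    probability_curves,
)
from aoqc.lape_classifiers import (
    SCORE_GRID,
    LapeThresholds,
    LinearModel,
    ProbabilityCurves,
)


def synthetic_curves(t12: float, t23: float) -> ProbabilityCurves:
    """Hand-built smooth curves with crossings planted exactly at t12/t23:
    logistic ramps make class 2 overtake class 1 at t12 and class 3
    overtake class 2 at t23."""
    g = SCORE_GRID
    p1 = 1.0 / (1.0 + np.exp((g - t12) / 1.5))
    p3 = 1.0 / (1.0 + np.exp(-(g - t23) / 1.5))
    p2 = 1.0 - p1 - p3
    probs = np.column_stack([p1, p2, p3])
    return ProbabilityCurves(grid=g, raw=probs, smoothed=probs)


class TestLinearModel:
    def test_two_point_interpolation(self):
        # degenerate two-class data keeps the closed form obvious, so build
        # the OLS line directly instead of via the three-class fitter
        slope, intercept = np.polyfit([0.0, 75.0], [1.0, 3.0], 1)
        model = LinearModel(slope=slope, intercept=intercept)
        assert model.intercept == pytest.approx(1.0)
        assert model.slope == pytest.approx(2.0 / 75.0)

    def test_recovers_generating_line(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 75, 300)
        labels_cont = 1.0 + scores * (2.0 / 75.0)  # exact line through (0,1),(75,3)
        labels = np.clip(np.round(labels_cont), 1, 3).astype(int)
        # refit on exactly-linear noise-free subset: use scores where the
        # rounded label equals the line (i.e. at the label centers)
        centers = np.array([0.0, 37.5, 75.0])
        s = np.repeat(centers, 50)
        y = np.repeat([1, 2, 3], 50)
        model = fit_linear_model(s, y)
        assert model.slope == pytest.approx(2.0 / 75.0, abs=1e-9)
        assert model.intercept == pytest.approx(1.0, abs=1e-9)
        del labels  # rounding sanity only

    def test_separable_clusters_classified_perfectly(self):
        rng = np.random.default_rng(1)
        s = np.concatenate(
            [rng.normal(4, 0.5, 100), rng.normal(37, 0.5, 100), rng.normal(70, 0.5, 100)]
        )
        y = np.repeat([1, 2, 3], 100)
        model = fit_linear_model(s, y)
        assert (predict_linear(model, s) == y).all()

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear_model([5.0] * 9, [1, 2, 3] * 3)

    @pytest.mark.parametrize(
        "value, expected",
        [(2.4, 2), (0.2, 1), (3.9, 3), (1.5, 2), (2.5, 3)],  # half-up ties
    )
    def test_rounding_and_clamping(self, value, expected):
        model = LinearModel(slope=1.0, intercept=0.0)
        assert predict_linear(model, value) == expected

    def test_band_8_35_classifies_20_as_2(self):
        # a line whose implied boundaries are exactly (8, 35)
        slope = 1.0 / 27.0
        intercept = 1.5 - 8.0 * slope
        model = LinearModel(slope=slope, intercept=intercept)
        assert model.implied_boundaries == pytest.approx((8.0, 35.0))
        assert predict_linear(model, 20.0) == 2


class TestForest:
    def test_separable_training_is_learned(self):
        rng = np.random.default_rng(2)
        s = np.concatenate(
            [rng.uniform(0, 7, 200), rng.uniform(10, 33, 200), rng.uniform(37, 75, 200)]
        )
        y = np.repeat([1, 2, 3], 200)
        model = fit_random_forest(s, y, seed=0)
        pred = model.forest.predict(s.reshape(-1, 1))
        assert (pred == y).mean() >= 0.99

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 75, 300)
        y = np.clip(np.round(1 + s / 37.0), 1, 3).astype(int)
        a = fit_random_forest(s, y, seed=5)
        b = fit_random_forest(s, y, seed=5)
        grid = SCORE_GRID.reshape(-1, 1)
        np.testing.assert_array_equal(
            a.forest.predict_proba(grid), b.forest.predict_proba(grid)
        )


@pytest.fixture(scope="module")
def separable_curves():
    rng = np.random.default_rng(4)
    s = np.concatenate(
        [rng.uniform(0, 7, 300), rng.uniform(9, 33, 300), rng.uniform(37, 75, 300)]
    )
    y = np.repeat([1, 2, 3], 300)
    model = fit_random_forest(s, y, n_trees=300, seed=0)
    return probability_curves(model)


class TestProbabilityCurves:
    def test_grid_has_751_points(self, separable_curves):
        assert len(separable_curves.grid) == 751
        assert separable_curves.grid[0] == 0.0
        assert separable_curves.grid[-1] == 75.0

    def test_raw_probabilities_sum_to_one(self, separable_curves):
        np.testing.assert_allclose(separable_curves.raw.sum(axis=1), 1.0, atol=1e-6)

    def test_each_class_dominates_its_own_band(self, separable_curves):
        g = separable_curves.grid
        p = separable_curves.smoothed
        for j, (lo, hi) in enumerate([(1, 6), (11, 31), (39, 73)]):
            inside = (g > lo) & (g < hi)
            outside_far = (g < lo - 6) | (g > hi + 6)
            assert (p[inside, j] > 0.5).mean() > 0.95
            assert (p[outside_far, j] < 0.5).all()


class TestEstimateThresholds:
    @pytest.mark.parametrize("t12, t23", [(8.0, 35.0), (7.0, 38.0)])
    def test_planted_crossings_recovered(self, t12, t23):
        th = estimate_thresholds(synthetic_curves(t12, t23))
        assert th.t12 == pytest.approx(t12, abs=0.05)
        assert th.t23 == pytest.approx(t23, abs=0.05)

    def test_no_intersection_is_an_error(self):
        g = SCORE_GRID
        p1 = np.full_like(g, 0.8)
        p2 = np.full_like(g, 0.15)
        p3 = np.full_like(g, 0.05)
        curves = ProbabilityCurves(
            grid=g, raw=np.column_stack([p1, p2, p3]), smoothed=np.column_stack([p1, p2, p3])
        )
        with pytest.raises(ValueError, match="intersect"):
            estimate_thresholds(curves)


class TestClassifyByThresholds:
    @pytest.mark.parametrize(
        "score, th, expected",
        [
            (5.0, (8.0, 35.0), 1),
            (20.0, (8.0, 35.0), 2),
            (40.0, (7.0, 38.0), 3),
            (8.0, (8.0, 35.0), 2),  # boundary goes inward
            (35.0, (8.0, 35.0), 2),
        ],
    )
    def test_banding(self, score, th, expected):
        assert classify_by_thresholds(score, LapeThresholds(*th)) == expected

    @given(st.floats(min_value=0, max_value=74), st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nondecreasing_in_score(self, score, delta):
        th = LapeThresholds(8.0, 35.0)
        assert classify_by_thresholds(score + delta, th) >= classify_by_thresholds(score, th)

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            LapeThresholds(40.0, 35.0)


class TestRecoveryStudy:
    """Planted-band recovery at n=3000 (shared session experiment)."""

    def test_forest_thresholds_near_planted_bands(self, threshold_recovery):
        th = threshold_recovery["thresholds"]
        assert th.t12 == pytest.approx(8.0, abs=2.0)
        assert th.t23 == pytest.approx(35.0, abs=2.0)

    def test_linear_boundaries_near_planted_bands(self, threshold_recovery):
        b12, b23 = threshold_recovery["linear"].implied_boundaries
        assert b12 == pytest.approx(8.0, abs=2.0)
        assert b23 == pytest.approx(35.0, abs=2.0)

    def test_held_out_accuracy_near_bayes_rate(self, threshold_recovery):
        assert threshold_recovery["forest_acc"] >= threshold_recovery["bayes_acc"] - 0.03
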