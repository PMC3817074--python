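"""Base learners: design construction, penalties, df calibration and
penalized least-squares fitting, cross-checked against dense oracles."""

import numpy as np
import pandas as pd
import pytest

import stuntquant as sq
from oracles import dense_hat_trace, penalized_lstsq
from stuntquant.learners import (CovariateSpec, bspline_design, calibrate_df,
                                 difference_penalty, hat_trace)


def cat_spec(name, levels, ref=None):
    return CovariateSpec(name, "categorical", levels=tuple(levels),
                         reference_level=ref)


class TestCategorical:
    def test_five_level_wealth_with_df4_is_unpenalized(self):
        learner = sq.build_categorical_learner(
            cat_spec("wealth", ["poorest", "poorer", "middle", "richer", "richest"]),
            df=4)
        table = pd.DataFrame({"wealth": ["poorest", "middle", "richest"]})
        pl = learner.prepare(table)
        assert pl.p == 4
        assert pl.lam == 0.0

    def test_binary_sex_codes_female_against_male_baseline(self):
        learner = sq.build_categorical_learner(cat_spec("sex", ["male", "female"]), df=4)
        table = pd.DataFrame({"sex": ["male", "female", "female"]})
        X, _ = learner.build_design(table)
        np.testing.assert_array_equal(X, [[0.0], [1.0], [1.0]])

    def test_ten_level_covariate_ridge_calibrated_to_df4(self, rng):
        levels = [f"l{i}" for i in range(10)]
        learner = sq.build_categorical_learner(cat_spec("c", levels), df=4)
        table = pd.DataFrame({"c": rng.choice(levels, size=600)})
        pl = learner.prepare(table)
        assert pl.hat_trace == pytest.approx(4.0, abs=0.01)
        assert dense_hat_trace(pl.X, pl.penalty, pl.lam) == pytest.approx(4.0, abs=0.01)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            sq.build_categorical_learner(cat_spec("c", ["only"]), df=4).prepare(
                pd.DataFrame({"c": ["only"]}))


class TestPSpline:
    spec = CovariateSpec("z", "continuous", range=(0.0, 1.0), center=0.5)

    def test_smooth_deviation_fits_are_orthogonal_to_linear_span(self, rng):
        _, smooth = sq.build_pspline_learner(self.spec, df=4)
        table = pd.DataFrame({"z": rng.uniform(0, 1, 400)})
        pl = smooth.prepare(table)
        u = rng.normal(size=400)
        _, fitted, _ = pl.fit_to_gradient(u)
        z = table["z"].to_numpy()
        scale = np.linalg.norm(fitted) + 1e-12
        assert abs(fitted.sum()) / scale < 1e-8
        assert abs(fitted @ (z - z.mean())) / scale < 1e-8

    def test_linear_signal_is_captured_by_linear_part_not_smooth(self, rng):
        linear, smooth = sq.build_pspline_learner(self.spec, df=4)
        table = pd.DataFrame({"z": rng.uniform(0, 1, 400)})
        signal = 2.0 * (table["z"].to_numpy() - 0.5)
        _, lin_fit, lin_sse = linear.prepare(table).fit_to_gradient(signal)
        _, _, smooth_sse = smooth.prepare(table).fit_to_gradient(signal)
        assert lin_sse < 1e-18
        # orthogonalized smooth term leaves the linear signal untouched
        assert smooth_sse == pytest.approx(signal @ signal, rel=1e-6)

    def test_difference_penalty_null_space_leaves_two_df_at_large_lambda(self, rng):
        x = rng.uniform(0, 1, 300)
        B = bspline_design(x, 0.0, 1.0, 20)
        K = difference_penalty(B.shape[1])
        assert hat_trace(B, K, 1e12) == pytest.approx(2.0, abs=1e-3)

    def test_df4_calibration_matches_eigenvalue_oracle(self, rng):
        x = rng.uniform(0, 1, 500)
        B = bspline_design(x, 0.0, 1.0, 20)
        assert B.shape[1] == 24
        K = difference_penalty(24)
        lam = calibrate_df(B, K, 4.0)
        assert dense_hat_trace(B, K, lam) == pytest.approx(4.0, abs=0.01)


class TestVarying:
    modifier = CovariateSpec("age", "continuous", range=(0.0, 24.0), center=12.0)
    group = CovariateSpec("feed", "varying", levels=("none", "bf", "excl"),
                          reference_level="none")

    def _table(self, rng, n=900):
        return pd.DataFrame({
            "age": rng.uniform(0, 24, n),
            "feed": rng.choice(["none", "bf", "excl"], size=n, p=[0.2, 0.5, 0.3]),
        })

    def test_reference_and_other_levels_contribute_exactly_zero(self, rng):
        learner = sq.build_varying_learner(self.modifier, self.group, "bf", df=4)
        table = self._table(rng)
        pl = learner.prepare(table)
        coef, fitted, _ = pl.fit_to_gradient(rng.normal(size=len(table)))
        mask = (table["feed"] != "bf").to_numpy()
        np.testing.assert_array_equal(fitted[mask], 0.0)

    def test_constant_group_offset_recovered(self, rng):
        learner = sq.build_varying_learner(self.modifier, self.group, "bf", df=4)
        table = self._table(rng, n=2000)
        u = np.where(table["feed"] == "bf", 0.7, 0.0)
        pl = learner.prepare(table)
        _, fitted, _ = pl.fit_to_gradient(u)
        in_group = (table["feed"] == "bf").to_numpy()
        assert np.allclose(fitted[in_group], 0.7, atol=0.02)

    def test_sign_switching_age_curve_recovered(self, rng):
        # positive before month 9, negative after month 12
        learner = sq.build_varying_learner(self.modifier, self.group, "excl", df=6)
        table = self._table(rng, n=4000)
        age = table["age"].to_numpy()
        truth = np.where(table["feed"] == "excl", 0.5 * (1 - age / 10.5), 0.0)
        u = truth + 0.1 * rng.normal(size=len(table))
        pl = learner.prepare(table)
        _, fitted, _ = pl.fit_to_gradient(u)
        sel = ((table["feed"] == "excl") & (age < 9)).to_numpy()
        assert fitted[sel].min() > 0
        sel = ((table["feed"] == "excl") & (age > 12)).to_numpy()
        assert fitted[sel].max() < 0

    def test_reference_level_term_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            sq.build_varying_learner(self.modifier, self.group, "none", df=4)


class TestSpatial:
    def test_unpenalized_two_region_fit_equals_group_means(self):
        graph = sq.make_region_graph("path", 2)
        learner = sq.build_spatial_learner(graph, df=4)
        learner = sq.BaseLearner(learner.id, learner.design_fn, learner.penalty,
                                 None, learner.meta)  # lambda = 0
        table = pd.DataFrame({"region": ["R00"] * 3 + ["R01"] * 2})
        u = np.array([1.0, 2.0, 3.0, 10.0, 20.0])
        pl = learner.prepare(table)
        coef, _, _ = pl.fit_to_gradient(u)
        np.testing.assert_allclose(coef, [2.0, 15.0])

    def test_infinite_lambda_shrinks_to_constant(self, rng):
        graph = sq.make_region_graph("grid", 9)
        learner = sq.build_spatial_learner(graph, df=4)
        table = pd.DataFrame({"region": rng.choice(graph.region_ids, 200)})
        X, _ = learner.build_design(table)
        u = rng.normal(size=200)
        coef = penalized_lstsq(X, graph.laplacian, 1e10, u)
        assert np.ptp(coef) < 1e-5

    def test_laplacian_roughness_decreases_with_lambda(self, rng):
        graph = sq.make_region_graph("grid", 16)
        learner = sq.build_spatial_learner(graph, df=4)
        table = pd.DataFrame({"region": rng.choice(graph.region_ids, 400)})
        X, _ = learner.build_design(table)
        u = rng.normal(size=400)
        lap = graph.laplacian
        rough = [penalized_lstsq(X, lap, lam, u) @ lap @ penalized_lstsq(X, lap, lam, u)
                 for lam in (0.1, 1.0, 10.0, 100.0)]
        assert all(a >= b - 1e-12 for a, b in zip(rough, rough[1:]))

    def test_unknown_region_rejected(self):
        graph = sq.make_region_graph("grid", 4)
        learner = sq.build_spatial_learner(graph, df=2)
        with pytest.raises(ValueError, match="unknown region"):
            learner.build_design(pd.DataFrame({"region": ["nowhere"]}))


class TestCalibrateDf:
    def test_zero_lambda_trace_is_rank(self, rng):
        X = rng.normal(size=(100, 6))
        K = np.eye(6)
        assert hat_trace(X, K, 0.0) == pytest.approx(6.0)

    def test_trace_is_monotone_decreasing_in_lambda(self, rng):
        X = bspline_design(rng.uniform(0, 1, 200), 0, 1, 10)
        K = difference_penalty(X.shape[1])
        traces = [hat_trace(X, K, lam) for lam in (0, 0.1, 1, 10, 100, 1e4)]
        assert all(a >= b - 1e-10 for a, b in zip(traces, traces[1:]))

    def test_unattainable_df_reports_interval(self, rng):
        X = bspline_design(rng.uniform(0, 1, 200), 0, 1, 10)
        K = difference_penalty(X.shape[1])
        with pytest.raises(ValueError, match="interval"):
            calibrate_df(X, K, 1.5)  # below the 2-dim penalty null space

    def test_calibrated_lambda_reproduced_by_dense_oracle(self, rng):
        X = bspline_design(rng.uniform(0, 1, 400), 0, 1, 20)
        K = difference_penalty(24)
        lam = calibrate_df(X, K, 4.0)
        # independent check: dense trace at lam is 4, and perturbing lambda
        # by 1% moves the trace off target
        assert dense_hat_trace(X, K, lam) == pytest.approx(4.0, abs=1e-3)
        assert abs(dense_hat_trace(X, K, lam * 1.25) - 4.0) > 1e-3


class TestFitToGradient:
    def test_zero_gradient_gives_zero_fit(self, recovery_cohort):
        *_, table, config, learners = recovery_cohort
        pl = learners[0].prepare(table)
        coef, fitted, sse = pl.fit_to_gradient(np.zeros(len(table)))
        assert not np.any(coef) and not np.any(fitted) and sse == 0.0

    def test_column_space_gradient_interpolated_when_unpenalized(self, rng):
        learner = sq.build_categorical_learner(cat_spec("c", ["a", "b", "d"]), df=4)
        table = pd.DataFrame({"c": rng.choice(["a", "b", "d"], 300)})
        pl = learner.prepare(table)
        u = pl.X @ np.array([0.5, -1.0])
        _, fitted, sse = pl.fit_to_gradient(u)
        assert sse < 1e-18

    def test_matches_dense_normal_equations_oracle(self, rng):
        spec = CovariateSpec("z", "continuous", range=(0.0, 1.0), center=0.5)
        _, smooth = sq.build_pspline_learner(spec, df=4)
        table = pd.DataFrame({"z": rng.uniform(0, 1, 100)})
        pl = smooth.prepare(table)
        u = rng.normal(size=100)
        _, fitted, _ = pl.fit_to_gradient(u)
        expected = pl.X @ penalized_lstsq(pl.X, pl.penalty, pl.lam, u)
        np.testing.assert_allclose(fitted, expected, atol=1e-8)

    def test_penalized_fit_never_beats_zero_vector(self, recovery_cohort, rng):
        *_, table, config, learners = recovery_cohort
        u = rng.normal(size=len(table))
        for learner in learners:
            _, _, sse = learner.prepare(table).fit_to_gradient(u)
            assert sse <= u @ u + 1e-9, learner.id


def test_all_penalizable_learners_hit_common_df_target(recovery_cohort):
    """Every df-calibrated learner reports a hat trace within 0.01 of the
    shared budget; unpenalizable learners report their column count."""
    *_, table, config, learners = recovery_cohort
    for learner in learners:
        pl = learner.prepare(table)
        if learner.df_target is not None and pl.p > learner.df_target:
            assert pl.hat_trace == pytest.approx(config.df, abs=0.01), learner.id
        else:
            assert pl.hat_trace == pytest.approx(pl.p, abs=0.01), learner.id
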