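"""Boosting engine: gradients, risk, offset, the component-wise loop,
cross-validated stopping and prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import stuntquant as sq
from oracles import check_risk, lp_quantile_regression
from stuntquant.boosting import LossSpec, default_cv_grid
from stuntquant.learners import BaseLearner, build_intercept_learner


def linear_learner(col):
    def design(table, transform=None):
        return table[col].to_numpy(dtype=float)[:, None], None
    return BaseLearner(f"lin({col})", design, None, None,
                       {"kind": "linear", "covariate": col})


def joint_linear_learner(cols):
    def design(table, transform=None):
        X = table[list(cols)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(X)), X]), None
    return BaseLearner("joint", design, None, None, {"kind": "linear"})


class TestNegativeGradient:
    def test_check_loss_branches(self):
        loss = LossSpec("quantile", 0.35)
        u = sq.negative_gradient(loss, np.array([1.0, -1.0]), np.zeros(2))
        np.testing.assert_allclose(u, [0.35, -0.65])

    def test_tie_takes_lower_branch(self):
        loss = LossSpec("quantile", 0.5)
        u = sq.negative_gradient(loss, np.array([2.0]), np.array([2.0]))
        assert u[0] == -0.5

    def test_binomial_at_zero_eta(self):
        loss = LossSpec("binomial")
        y = np.array([0.0, 1.0, 1.0])
        np.testing.assert_allclose(sq.negative_gradient(loss, y, np.zeros(3)),
                                   y - 0.5)

    def test_binomial_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            sq.negative_gradient(LossSpec("binomial"), np.array([0.5]), np.zeros(1))


class TestEmpiricalRisk:
    def test_perfect_fit_has_zero_check_risk(self, rng):
        y = rng.normal(size=30)
        assert sq.empirical_risk(LossSpec("quantile", 0.35), y, y) == 0.0

    def test_median_check_loss_is_half_mean_absolute_error(self, rng):
        y, eta = rng.normal(size=50), rng.normal(size=50)
        assert sq.empirical_risk(LossSpec("quantile", 0.5), y, eta) == pytest.approx(
            np.mean(np.abs(y - eta)) / 2)

    @pytest.mark.parametrize("tau", [0.05, 0.35, 0.9])
    def test_matches_term_by_term_oracle(self, rng, tau):
        y, eta = rng.normal(size=50), rng.normal(size=50)
        assert sq.empirical_risk(LossSpec("quantile", tau), y, eta) == pytest.approx(
            check_risk(y, eta, tau), abs=1e-12)


class TestOffsetInit:
    def test_binomial_logit_of_mean(self):
        assert sq.offset_init(LossSpec("binomial"), np.array([0, 0, 0, 1.0])) == \
            pytest.approx(np.log(1 / 3))

    def test_symmetric_outcome_has_zero_median_offset(self):
        y = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert sq.offset_init(LossSpec("quantile", 0.5), y) == 0.0

    def test_interpolation_rule_matches_sorted_oracle(self):
        y = np.arange(1.0, 101.0)
        got = sq.offset_init(LossSpec("quantile", 0.35), y)
        # linear interpolation of order statistics at position 1 + 0.35*(n-1)
        pos = 0.35 * 99
        k = int(pos)
        expected = np.sort(y)[k] + (pos - k) * (np.sort(y)[k + 1] - np.sort(y)[k])
        assert got == pytest.approx(expected)

    def test_degenerate_binomial_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sq.offset_init(LossSpec("binomial"), np.ones(5))


class TestBoostLoop:
    def test_mstop_zero_is_offset_only(self, rng):
        table = pd.DataFrame({"x": rng.normal(size=50)})
        y = rng.normal(size=50)
        model = sq.boost(table, y, [linear_learner("x")], LossSpec("quantile", 0.5),
                         mstop=0)
        assert model.mstop == 0
        np.testing.assert_allclose(model.predict(table), model.offset)

    def test_informative_learner_selected_first(self, rng):
        n = 1000
        cols = {f"x{j}": rng.normal(size=n) for j in range(10)}
        table = pd.DataFrame(cols)
        y = 2.0 * table["x7"].to_numpy() + 0.3 * rng.normal(size=n)
        learners = [linear_learner(f"x{j}") for j in range(10)]
        model = sq.boost(table, y, learners, LossSpec("quantile", 0.5), mstop=1)
        assert model.selection_path[0] == "lin(x7)"

    def test_training_risk_non_increasing(self, recovery_cohort):
        *_, table, config, learners = recovery_cohort
        y = table["haz"].to_numpy()
        model = sq.boost(table, y, learners, LossSpec("quantile", 0.35),
                         mstop=120, track_risk=True)
        path = np.array(model.train_risk_path)
        assert np.all(np.diff(path) <= 1e-12)

    def test_unselected_learners_have_zero_contributions(self, fitted_q35):
        model, _ = fitted_q35
        counts = model.selection_counts()
        for lid, coef in model.contributions.items():
            if counts[lid] == 0:
                assert not np.any(coef)

    def test_selection_path_length_is_mstop(self, fitted_q35):
        model, _ = fitted_q35
        assert len(model.selection_path) == model.mstop


class TestPredict:
    def test_predictor_additivity(self, fitted_q35, recovery_cohort):
        *_, table, config, learners = recovery_cohort
        model, _ = fitted_q35
        total = np.full(len(table), model.offset)
        for pl in model.prepared:
            total += model.predict_term(pl.id, table)
        np.testing.assert_allclose(total, model.predict(table), atol=1e-10)

    def test_reference_category_record_gets_zero_term(self, fitted_q35):
        model, _ = fitted_q35
        frame = pd.DataFrame({"sex": ["male"]})
        assert model.predict_term("cat(sex)", frame)[0] == 0.0

    def test_in_sample_quantile_coverage(self, fitted_q35, recovery_cohort):
        *_, table, config, learners = recovery_cohort
        model, _ = fitted_q35
        frac = np.mean(table["haz"].to_numpy() <= model.predict(table))
        assert frac == pytest.approx(0.35, abs=0.02)

    def test_serialization_roundtrip_predicts_identically(self, fitted_q35,
                                                          recovery_cohort):
        *_, table, config, learners = recovery_cohort
        model, _ = fitted_q35
        clone = sq.BoostedModel.from_json(model.to_json(), learners, table)
        np.testing.assert_allclose(clone.predict(table), model.predict(table),
                                   atol=1e-12)


class TestCrossValidation:
    def _noise_problem(self, seed, n=300):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({f"x{j}": rng.normal(size=n) for j in range(3)})
        y = rng.normal(size=n)
        learners = [linear_learner(f"x{j}") for j in range(3)]
        return table, y, learners

    def test_pure_noise_selects_smallest_checkpoint(self):
        grid = (0, 25, 50, 100)
        hits = 0
        for seed in range(20):
            table, y, learners = self._noise_problem(seed)
            cv = sq.cross_validate_mstop(table, y, learners,
                                         LossSpec("quantile", 0.5),
                                         folds=5, grid=grid, seed=seed)
            hits += cv.mstop == 0
        assert hits >= 16  # >= 80% of replicates

    def test_planted_signal_moves_mstop_off_zero(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"x": rng.normal(size=300)})
        y = 1.5 * table["x"].to_numpy() + rng.normal(size=300)
        cv = sq.cross_validate_mstop(table, y, [linear_learner("x")],
                                     LossSpec("quantile", 0.5),
                                     folds=5, grid=(0, 25, 50, 100), seed=0)
        assert cv.mstop > 0

    def test_survey_sized_cohort_completes_and_returns_grid_member(self):
        spec, graph = sq.nfhs_like_scenario(n=12176, seed=21)
        table = sq.simulate_cohort(spec, graph)
        learners = [linear_learner("child_age"), linear_learner("mother_bmi")]
        grid = (0, 25, 50)
        cv = sq.cross_validate_mstop(table, table["haz"].to_numpy(), learners,
                                     LossSpec("quantile", 0.35),
                                     folds=5, grid=grid, seed=1)
        assert cv.mstop in grid

    def test_default_grid_shape(self):
        grid = default_cv_grid()
        assert grid[0] == 0 and grid[-1] == 2500 and grid[1] - grid[0] == 25


class TestOracleAgreement:
    def test_componentwise_quantile_boosting_reaches_near_optimal_risk(self):
        """Greedy per-covariate selection on the non-smooth check loss can
        stop at coordinate-wise stationary points, so the guarantee it
        carries is risk-level: within 1e-3 of the exact LP optimum."""
        rng = np.random.default_rng(1)
        n = 200
        X = rng.normal(size=(n, 3))
        y = 0.3 + X @ np.array([1.0, -0.5, 0.25]) + rng.normal(size=n)
        table = pd.DataFrame(X, columns=["x1", "x2", "x3"])
        Xd = np.hstack([np.ones((n, 1)), X])
        bhat = lp_quantile_regression(Xd, y, 0.35)
        learners = [build_intercept_learner()] + [linear_learner(c)
                                                  for c in ("x1", "x2", "x3")]
        model = sq.boost(table, y, learners, LossSpec("quantile", 0.35),
                         mstop=20_000, nu=0.2)
        loss = LossSpec("quantile", 0.35)
        risk_boost = sq.empirical_risk(loss, y, model.predict(table))
        risk_lp = sq.empirical_risk(loss, y, Xd @ bhat)
        assert risk_boost <= risk_lp + 1e-3


@settings(deadline=None, max_examples=30, derandomize=True)
@given(y=hnp.arrays(np.float64, 20, elements=st.floats(-5, 5)),
       eta=hnp.arrays(np.float64, 20, elements=st.floats(-5, 5)),
       tau=st.floats(0.05, 0.95))
def test_check_risk_nonnegative_and_zero_only_at_fit(y, eta, tau):
    risk = sq.empirical_risk(LossSpec("quantile", tau), y, eta)
    assert risk >= 0.0
    if np.array_equal(y, eta):
        assert risk == 0.0
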