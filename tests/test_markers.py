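import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_logistic_pair
from omifuse import (
    fit_lasso_logistic,
    lambda_max,
    magnitude_penalty,
    select_tuning_markers,
    sign_penalty,
    simulate_marker_scenario,
    solve_penalized_logistic,
)
from omifuse.markers import _prep
from omifuse.simulate import MarkerScenarioSpec
from oracle_utils import cd_logistic_objective, orthant_oracle_logistic


class TestPenaltyValues:
    # hand-evaluated ordered-pair sums of the two fusion penalties
    @pytest.mark.parametrize(
        "b1, b2, expected",
        [
            ([1.0, -2.0], [1.0, -2.0], 0.0),
            ([1.0], [-1.0], 2.0),
            ([2.0, 1.0], [1.0, 1.0], 2.0),
            ([0.0], [0.0], 0.0),
            ([1.0], [0.0], 1.0),  # discordant: 1^2 + 0^2
        ],
    )
    def test_magnitude(self, b1, b2, expected):
        assert magnitude_penalty(b1, b2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "b1, b2, expected",
        [
            ([3.0, 0.1], [0.2, 5.0], 0.0),
            ([1.0], [-1.0], 8.0),
            ([1.0], [0.0], 2.0),
        ],
    )
    def test_sign(self, b1, b2, expected):
        assert sign_penalty(b1, b2) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            magnitude_penalty([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            sign_penalty([1.0], [1.0, 2.0])

    def test_penalties_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 6))
        assert magnitude_penalty(a, b) == pytest.approx(magnitude_penalty(b, a))
        assert sign_penalty(a, b) == pytest.approx(sign_penalty(b, a))


class TestSolverIdentities:
    @pytest.mark.parametrize("penalty", ["magnitude", "sign"])
    def test_zero_fusion_equals_independent_lassos(self, penalty, compiled_solvers):
        d1, d2 = make_logistic_pair(3, n=30, p=8)
        joint = solve_penalized_logistic(
            d1, d2, 0.05, 0.0, penalty=penalty, tol=1e-8
        )
        f1 = fit_lasso_logistic(d1, 0.05, tol=1e-8)
        f2 = fit_lasso_logistic(d2, 0.05, tol=1e-8)
        assert np.abs(joint.beta[0] - f1.beta[0]).max() <= 1e-6
        assert np.abs(joint.beta[1] - f2.beta[0]).max() <= 1e-6

    def test_full_shrinkage_at_lambda_max(self, compiled_solvers):
        d1, d2 = make_logistic_pair(4, n=30, p=10)
        lmax = lambda_max(d1, d2)
        fit = solve_penalized_logistic(d1, d2, lmax * (1 + 1e-10), 1.0, "magnitude")
        assert not fit.beta[0].any() and not fit.beta[1].any()
        for k, d in ((0, d1), (1, d2)):
            pbar = d.y.mean()
            assert fit.intercepts[k] == pytest.approx(
                np.log(pbar / (1 - pbar)), abs=1e-6
            )
        # just below lambda_max something enters
        fit2 = solve_penalized_logistic(d1, d2, lmax * 0.95, 0.0, "none")
        assert fit2.beta[0].any() or fit2.beta[1].any()

    def test_unpenalized_limit_matches_ml(self, compiled_solvers):
        d1, _ = make_logistic_pair(5, n=60, p=3)
        fit = fit_lasso_logistic(d1, 0.0, tol=1e-9)
        Xs, y, _, _ = _prep(d1, "expression")
        res = sm.GLM(y, sm.add_constant(Xs), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta[0], res.params[1:], atol=1e-4)
        assert fit.intercepts[0] == pytest.approx(res.params[0], abs=1e-4)

    def test_huge_penalty_gives_zero(self, compiled_solvers):
        d1, _ = make_logistic_pair(6)
        fit = fit_lasso_logistic(d1, 50.0)
        assert not fit.beta[0].any()

    def test_swapping_datasets_swaps_solutions(self, compiled_solvers):
        d1, d2 = make_logistic_pair(7, n=25, p=6)
        a = solve_penalized_logistic(d1, d2, 0.05, 1.0, "magnitude")
        b = solve_penalized_logistic(d2, d1, 0.05, 1.0, "magnitude")
        np.testing.assert_array_equal(a.beta[0], b.beta[1])
        np.testing.assert_array_equal(a.beta[1], b.beta[0])
        assert a.intercepts == b.intercepts[::-1]

    def test_negative_tuning_rejected(self):
        d1, d2 = make_logistic_pair(8)
        with pytest.raises(ValueError):
            solve_penalized_logistic(d1, d2, -0.1, 0.0)


class TestOracleAgreement:
    @pytest.mark.parametrize("lam1, lam2", [(0.05, 0.5), (0.1, 2.0)])
    def test_fused_magnitude_matches_orthant_optimizer(
        self, lam1, lam2, compiled_solvers
    ):
        d1, d2 = make_logistic_pair(9, n=20, p=4)
        fit = solve_penalized_logistic(
            d1, d2, lam1, lam2, "magnitude", tol=1e-8, max_sweeps=5000
        )
        f_cd = cd_logistic_objective(d1, d2, fit, lam1, lam2, "magnitude")
        f_or = orthant_oracle_logistic(d1, d2, lam1, lam2, "magnitude", fit)
        assert abs(f_cd - f_or) <= 1e-4

    def test_lasso_matches_orthant_optimizer(self, compiled_solvers):
        d1, d2 = make_logistic_pair(10, n=20, p=4)
        fit = solve_penalized_logistic(d1, d2, 0.08, 0.0, "none", tol=1e-8)
        f_cd = cd_logistic_objective(d1, d2, fit, 0.08, 0.0, "none")
        f_or = orthant_oracle_logistic(d1, d2, 0.08, 0.0, "none", fit)
        assert abs(f_cd - f_or) <= 1e-5


class TestMonotonicity:
    @pytest.mark.parametrize("penalty", ["magnitude", "sign", "none"])
    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_never_increases(self, penalty, seed, compiled_solvers):
        d1, d2 = make_logistic_pair(100 + seed, n=25, p=12)
        fit = solve_penalized_logistic(d1, d2, 0.03, 1.0, penalty)
        assert np.all(np.diff(fit.objective_trace) <= 1e-10)

    def test_fusion_equalizes_same_sign_coefficients(self, compiled_solvers):
        """On same-sign truth the coefficient gap shrinks monotonically in lam2."""
        d1, d2, _ = simulate_marker_scenario(
            MarkerScenarioSpec("I", n_per_group=40, p=20), seed=21
        )
        gaps = []
        for lam2 in (0.0, 0.5, 2.0, 8.0, 32.0):
            fit = solve_penalized_logistic(d1, d2, 0.05, lam2, "magnitude")
            gaps.append(np.abs(fit.beta[0] - fit.beta[1]).max())
        assert all(g2 <= g1 + 1e-8 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.05 * gaps[0] + 1e-8


class TestTuningSelection:
    def test_single_point_grid_returns_that_fit(self, compiled_solvers):
        d1, d2 = make_logistic_pair(11, n=30, p=6)
        fit = select_tuning_markers(
            d1, d2, penalty="magnitude", lambda1_grid=[0.07], lambda2_grid=[2.0]
        )
        assert fit.lambda1 == 0.07 and fit.lambda2 == 2.0

    def test_empty_grid_rejected(self):
        d1, d2 = make_logistic_pair(12)
        with pytest.raises(ValueError):
            select_tuning_markers(d1, d2, lambda1_grid=[])

    def test_pure_noise_selects_null_model(self, compiled_solvers):
        # sized so BIC is selection-consistent: the best spurious deviance
        # over p candidates stays below the log(n) price of one coefficient
        nulls = 0
        n_sims = 25
        for s in range(n_sims):
            d1, d2 = make_logistic_pair(200 + s, n=200, p=4, beta_scale=0.0)
            fit = select_tuning_markers(d1, d2, penalty="none")
            if not fit.beta[0].any() and not fit.beta[1].any():
                nulls += 1
        assert nulls >= 0.8 * n_sims

    def test_matched_diseases_prefer_positive_fusion(self, compiled_solvers):
        """When the two diseases share identical effects, out-of-fold
        deviance should select a positive cross-disease coupling in most
        replicates (cross-validation sees the estimation gain of fusion,
        which support-based scores cannot)."""
        from omifuse.markers import default_lambda1_grid

        wins = 0
        n_sims = 25
        for s in range(n_sims):
            d1, d2, _ = simulate_marker_scenario(MarkerScenarioSpec("I"), 300 + s)
            grid = default_lambda1_grid(d1, d2, n=6)
            fit = select_tuning_markers(
                d1, d2, penalty="magnitude", criterion="cv", seed=s,
                lambda1_grid=grid, lambda2_grid=[0.0, 8.0, 32.0],
            )
            if fit.lambda2 > 0:
                wins += 1
        assert wins > n_sims / 2

    def test_cv_criterion_runs_and_returns_fit(self, compiled_solvers):
        d1, d2 = make_logistic_pair(13, n=40, p=6)
        fit = select_tuning_markers(
            d1, d2, penalty="none", criterion="cv",
            lambda1_grid=[0.2, 0.05], seed=1,
        )
        assert fit.path and fit.lambda1 in (0.2, 0.05)

    def test_degenerate_folds_rejected(self):
        d1, d2 = make_logistic_pair(14, n=8, p=3)
        with pytest.raises(ValueError, match="folds"):
            select_tuning_markers(
                d1, d2, penalty="none", criterion="cv",
                lambda1_grid=[0.1], cv_folds=6,
            )


def test_original_scale_coefficients_reproduce_linear_predictor(compiled_solvers):
    d1, d2 = make_logistic_pair(15, n=30, p=5)
    fit = solve_penalized_logistic(d1, d2, 0.05, 0.0, "none")
    Xs, _, _, _ = _prep(d1, "expression")
    lp_std = Xs @ fit.beta[0] + fit.intercepts[0]
    lp_orig = d1.X @ fit.beta_original(0) + fit.intercept_original(0)
    np.testing.assert_allclose(lp_std, lp_orig, atol=1e-10)
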