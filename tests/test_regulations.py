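import numpy as np
import pytest

from conftest import make_regulation_pair
from omifuse import (
    OmicsDataset,
    dist_matrices,
    fit_lasso_regulation,
    lambda3_max,
    select_tuning_regulations,
    signdist_matrices,
    simulate_cnv_matrix,
    solve_penalized_regulation,
)
from omifuse.regulations import _prep_xz
from oracle_utils import cd_regulation_objective, orthant_oracle_regulation


class TestDistances:
    def test_identical_matrices_have_zero_distance(self):
        e = np.random.default_rng(0).standard_normal((4, 4))
        assert dist_matrices(e, e) == 0.0
        assert signdist_matrices(e, e) == 0.0

    def test_single_entry_difference(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        b[1, 2] = 2.0
        assert dist_matrices(a, b) == 4.0

    def test_opposite_signs_single_entry(self):
        a = np.zeros((2, 2))
        b = np.zeros((2, 2))
        a[0, 0], b[0, 0] = 1.0, -1.0
        assert signdist_matrices(a, b) == 4.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((4, 4)) * (rng.uniform(size=(4, 4)) < 0.5)
        b = rng.standard_normal((4, 4)) * (rng.uniform(size=(4, 4)) < 0.5)
        d = sum((a[j, l] - b[j, l]) ** 2 for j in range(4) for l in range(4))
        sd = sum(
            (np.sign(a[j, l]) - np.sign(b[j, l])) ** 2
            for j in range(4)
            for l in range(4)
        )
        assert dist_matrices(a, b) == pytest.approx(d)
        assert signdist_matrices(a, b) == pytest.approx(sd)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dist_matrices(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            signdist_matrices(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSolverIdentities:
    @pytest.mark.parametrize("penalty", ["magnitude", "sign"])
    def test_zero_fusion_equals_separate_lassos(self, penalty, compiled_solvers):
        d1, d2, _ = make_regulation_pair(30, n=25, p=6)
        joint = solve_penalized_regulation(d1, d2, 0.2, 0.0, penalty, tol=1e-8)
        f1 = fit_lasso_regulation(d1, 0.2, tol=1e-8)
        f2 = fit_lasso_regulation(d2, 0.2, tol=1e-8)
        assert np.abs(joint.eta[0] - f1.eta[0]).max() <= 1e-6
        assert np.abs(joint.eta[1] - f2.eta[0]).max() <= 1e-6

    def test_full_shrinkage_at_lambda3_max(self, compiled_solvers):
        d1, d2, _ = make_regulation_pair(31, n=20, p=8)
        lmax = lambda3_max(d1, d2)
        fit = solve_penalized_regulation(d1, d2, lmax * (1 + 1e-10), 1.0)
        assert not fit.eta[0].any() and not fit.eta[1].any()

    def test_huge_penalty_gives_zero(self, compiled_solvers):
        d1, _, _ = make_regulation_pair(32)
        fit = fit_lasso_regulation(d1, 100.0)
        assert not fit.eta[0].any()

    def test_unpenalized_limit_matches_per_gene_ols(self, compiled_solvers):
        d1, _, _ = make_regulation_pair(33, n=40, p=5)
        fit = fit_lasso_regulation(d1, 0.0, tol=1e-9, max_sweeps=20000)
        Z, X, *_ = _prep_xz(d1)
        for j in range(X.shape[1]):
            ols = np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            np.testing.assert_allclose(fit.eta[0][j], ols, atol=1e-6)

    def test_noiseless_sparse_truth_support_recovered(self, compiled_solvers):
        from omifuse.simulate import RegulationSimSpec, simulate_regulation_data

        Z = simulate_cnv_matrix(50, 10, seed=34)
        spec = RegulationSimSpec(
            regulated_fraction=0.3, n_shared=2, noise_sd=0.0
        )
        d1, d2, (eta1, _) = simulate_regulation_data(spec, Z, Z.copy(), 35)
        fit = fit_lasso_regulation(d1, 0.01, tol=1e-8)
        # noiseless, n >> support: exact support recovery at small lam3
        np.testing.assert_array_equal(fit.support(0), eta1 != 0)

    def test_gene_problems_decouple_exactly(self, compiled_solvers):
        # updates never couple genes, so with a fixed sweep count the joint
        # solve and per-gene solves agree bitwise
        from omifuse.simulate import _RectangularOmics

        d1, d2, _ = make_regulation_pair(36, n=20, p=6)
        kwargs = dict(penalty="none", tol=0.0, max_sweeps=60)
        joint = solve_penalized_regulation(d1, d2, 0.15, 0.0, **kwargs)
        for j in range(3):
            s1 = _RectangularOmics(
                d1.sample_ids, [d1.gene_ids[j]], d1.gene_ids,
                d1.X[:, [j]], d1.Z,
            )
            s2 = _RectangularOmics(
                d2.sample_ids, [d2.gene_ids[j]], d2.gene_ids,
                d2.X[:, [j]], d2.Z,
            )
            single = solve_penalized_regulation(s1, s2, 0.15, 0.0, **kwargs)
            # agreement to summation-order precision (response centering is
            # the only arithmetic that differs between the two layouts)
            np.testing.assert_allclose(
                single.eta[0][0], joint.eta[0][j], rtol=0, atol=1e-12
            )
            np.testing.assert_allclose(
                single.eta[1][0], joint.eta[1][j], rtol=0, atol=1e-12
            )

    def test_constant_cnv_column_fixed_at_zero(self, compiled_solvers, caplog):
        d1, d2, _ = make_regulation_pair(37, n=15, p=5)
        Z = d1.Z.copy()
        Z[:, 2] = 7.0
        d1c = OmicsDataset(
            d1.sample_ids, d1.gene_ids, X=d1.X, Z=Z, group_label=d1.group_label
        )
        fit = solve_penalized_regulation(d1c, d2, 0.05, 0.0, "none")
        assert not fit.eta[0][:, 2].any()
        assert any("constant" in r.message for r in caplog.records)


class TestOracleAgreement:
    def test_fused_magnitude_matches_orthant_optimizer(self, compiled_solvers):
        d1, d2, _ = make_regulation_pair(38, n=20, p=4)
        fit = solve_penalized_regulation(
            d1, d2, 0.1, 0.5, "magnitude", tol=1e-9, max_sweeps=10000
        )
        f_cd = cd_regulation_objective(d1, d2, fit, 0.1, 0.5, "magnitude")
        f_or = orthant_oracle_regulation(d1, d2, 0.1, 0.5, "magnitude", fit)
        assert abs(f_cd - f_or) <= 1e-4

    def test_lasso_matches_orthant_optimizer(self, compiled_solvers):
        d1, d2, _ = make_regulation_pair(39, n=20, p=4)
        fit = solve_penalized_regulation(d1, d2, 0.15, 0.0, "none", tol=1e-9)
        f_cd = cd_regulation_objective(d1, d2, fit, 0.15, 0.0, "none")
        f_or = orthant_oracle_regulation(d1, d2, 0.15, 0.0, "none", fit)
        assert abs(f_cd - f_or) <= 1e-5


class TestMonotonicityAndSymmetry:
    @pytest.mark.parametrize("penalty", ["magnitude", "sign", "none"])
    @pytest.mark.parametrize("seed", range(3))
    def test_objective_trace_never_increases(self, penalty, seed, compiled_solvers):
        d1, d2, _ = make_regulation_pair(400 + seed, n=15, p=8)
        fit = solve_penalized_regulation(d1, d2, 0.1, 0.5, penalty)
        assert np.all(np.diff(fit.objective_trace) <= 1e-10)

    def test_swapping_groups_swaps_solutions(self, compiled_solvers):
        d1, d2, _ = make_regulation_pair(41, n=15, p=6)
        a = solve_penalized_regulation(d1, d2, 0.1, 0.5, "magnitude")
        b = solve_penalized_regulation(d2, d1, 0.1, 0.5, "magnitude")
        np.testing.assert_array_equal(a.eta[0], b.eta[1])
        np.testing.assert_array_equal(a.eta[1], b.eta[0])


class TestTuningSelection:
    def test_single_point_grid_returns_that_fit(self, compiled_solvers):
        d1, d2, _ = make_regulation_pair(42, n=20, p=6)
        fit = select_tuning_regulations(
            d1, d2, penalty="magnitude", lambda3_grid=[0.3], lambda4_grid=[0.5]
        )
        assert fit.lambda3 == 0.3 and fit.lambda4 == 0.5

    def test_pure_noise_selects_null_model(self, compiled_solvers):
        nulls = 0
        n_sims = 20
        # dimensions where BIC is selection-consistent: the best spurious
        # correlation over p*q candidate pairs must fall below the log(n)
        # price of one coefficient
        for s in range(n_sims):
            rng = np.random.default_rng(9000 + s)
            n, p = 500, 3
            Z = simulate_cnv_matrix(n, p, 500 + s)
            X = rng.standard_normal((n, p))  # expression unrelated to CNV
            d = OmicsDataset(
                [f"s{i}" for i in range(n)], [f"g{j}" for j in range(p)],
                X=X, Z=Z,
            )
            fit = select_tuning_regulations(d, d, penalty="none")
            if not fit.eta[0].any():
                nulls += 1
        assert nulls >= 0.8 * n_sims

    def test_shared_structure_prefers_positive_fusion(self, compiled_solvers):
        """Out-of-fold error selects a positive coupling when the per-gene
        support (10% of 60 CNVs) coincides with the six shared same-sign
        CNVs — cross-validation sees the estimation gain of fusion that
        support-counting scores cannot."""
        from omifuse.simulate import RegulationSimSpec, simulate_regulation_data

        wins = 0
        n_sims = 10
        for s in range(n_sims):
            Z1 = simulate_cnv_matrix(30, 60, 700 + s)
            Z2 = simulate_cnv_matrix(30, 60, 800 + s)
            d1, d2, _ = simulate_regulation_data(
                RegulationSimSpec(n_genes=10), Z1, Z2, 900 + s
            )
            fit = select_tuning_regulations(
                d1, d2, penalty="magnitude", criterion="cv", seed=s,
                lambda4_grid=[0.0, 0.5, 2.0],
            )
            if fit.lambda4 > 0:
                wins += 1
        assert wins > n_sims / 2
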