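"""LPV-AR core: regressor construction, ridge fitting, selection, CFC index."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lpvcfc import lpvar
from lpvcfc.core import BandSpec
from lpvcfc.lpvar import (
    LPVARStructure,
    SchedulingSignal,
    basis_row,
    build_regressor_matrix,
    build_scheduling,
    cfc_index,
    fit_rls,
    lpvar_cfc,
    permuted_regressors,
    predict_residuals,
    select_lambda_ucurve,
    select_order_step1,
)


def _random_scheduling(rng, n):
    phase = rng.uniform(-np.pi, np.pi, n)
    return SchedulingSignal(np.cos(phase), np.sin(phase))


def naive_regressor_matrix(y, s, p, q):
    """Triple-loop reference construction (independent of the vectorized path)."""
    rows = []
    for n in range(p, len(y)):
        row = []
        for k in range(1, p + 1):
            for b in basis_row(s.s1[n], s.s2[n], q):
                row.append(y[n - k] * b)
        rows.append(row)
    return np.array(rows)


class TestScheduling:
    def test_zero_phase(self):
        s = build_scheduling(np.array([0.0]))
        assert (s.s1[0], s.s2[0]) == (1.0, 0.0)

    def test_quarter_cycle(self):
        s = build_scheduling(np.array([np.pi / 2]))
        assert abs(s.s1[0]) < 1e-15 and s.s2[0] == 1.0

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=200))
    def test_unit_circle_identity(self, phases):
        s = build_scheduling(np.asarray(phases))
        assert np.max(np.abs(s.s1**2 + s.s2**2 - 1.0)) < 1e-12


class TestBasis:
    def test_second_order_monomials(self):
        s1, s2 = 0.3, -0.7
        assert np.allclose(basis_row(s1, s2, 2), [1.0, s2**2, s1 * s2, s1**2])

    def test_order_zero_is_plain_ar(self):
        assert np.array_equal(basis_row(0.5, 0.5, 0), [1.0])

    def test_first_order(self):
        assert np.allclose(basis_row(0.6, 0.8, 1), [1.0, 0.8, 0.6])

    @given(
        st.floats(-1, 1), st.floats(-1, 1), st.integers(min_value=0, max_value=4)
    )
    def test_length_matches_structure(self, s1, s2, q):
        expected = 1 if q == 0 else q + 2
        assert basis_row(s1, s2, q).size == expected


class TestRegressorMatrix:
    def test_shape_counts_columns_per_lag(self, rng):
        y = rng.standard_normal(100)
        s = _random_scheduling(rng, 100)
        Phi = build_regressor_matrix(y, s, LPVARStructure(2, 2))
        assert Phi.X.shape == (98, 8)
        assert Phi.target.shape == (98,)

    def test_order_zero_equals_plain_ar_matrix(self, rng):
        y = rng.standard_normal(50)
        s = _random_scheduling(rng, 50)
        Phi = build_regressor_matrix(y, s, LPVARStructure(3, 0))
        expected = np.column_stack([y[3 - k : 50 - k] for k in range(1, 4)])
        assert np.allclose(Phi.X, expected)

    def test_hand_evaluated_rows(self):
        y = np.array([1.0, 2.0, 3.0])
        s = SchedulingSignal(np.ones(3), np.zeros(3))
        Phi = build_regressor_matrix(y, s, LPVARStructure(1, 2))
        assert np.allclose(Phi.X, [[1, 0, 0, 1], [2, 0, 0, 2]])
        assert np.allclose(Phi.target, [2.0, 3.0])

    @pytest.mark.parametrize("p,q,n", [(1, 0, 10), (2, 1, 20), (3, 2, 50), (2, 3, 30)])
    def test_matches_naive_triple_loop(self, p, q, n, rng):
        y = rng.standard_normal(n)
        s = _random_scheduling(rng, n)
        Phi = build_regressor_matrix(y, s, LPVARStructure(p, q))
        assert np.allclose(Phi.X, naive_regressor_matrix(y, s, p, q))

    def test_short_signal_rejected(self, rng):
        with pytest.raises(ValueError, match="too short"):
            build_regressor_matrix(np.ones(3), _random_scheduling(rng, 3), LPVARStructure(5, 1))


class TestRidgeFit:
    def test_unregularized_matches_dense_solver(self, rng):
        # full-rank case: q=1 basis has independent columns
        y = rng.standard_normal(200)
        s = _random_scheduling(rng, 200)
        Phi = build_regressor_matrix(y, s, LPVARStructure(2, 1))
        model = fit_rls(Phi, lam=0.0)
        expected, *_ = np.linalg.lstsq(Phi.X, Phi.target, rcond=None)
        assert np.allclose(model.w, expected, atol=1e-10)

    def test_extreme_shrinkage_kills_coefficients(self, rng):
        y = rng.standard_normal(200)
        s = _random_scheduling(rng, 200)
        Phi = build_regressor_matrix(y, s, LPVARStructure(2, 1))
        model = fit_rls(Phi, lam=1e9)
        assert np.linalg.norm(model.w) < 1e-6 * np.linalg.norm(Phi.X.T @ Phi.target)

    def test_exact_recovery_of_identifiable_coefficients(self, rng):
        """Noise-free targets built from a known coefficient vector are
        recovered exactly.  For even q the retained monomials are collinear
        with the constant (s1^2 + s2^2 = 1), so the recoverable truth is the
        projection onto the regressor row space."""
        y_driver = rng.standard_normal(300)
        s = _random_scheduling(rng, 300)
        structure = LPVARStructure(2, 2)
        Phi = build_regressor_matrix(y_driver, s, structure)
        w_raw = rng.standard_normal(Phi.X.shape[1])
        w_true = np.linalg.pinv(Phi.X) @ (Phi.X @ w_raw)  # identifiable representative
        clean = lpvar.RegressorMatrix(Phi.X, Phi.X @ w_true, structure)
        model = fit_rls(clean, lam=1e-8)
        assert np.max(np.abs(model.w - w_true)) < 1e-6

    def test_large_sample_recovery_relative_error(self, rng):
        y_driver = rng.standard_normal(2000)
        s = _random_scheduling(rng, 2000)
        structure = LPVARStructure(3, 1)
        Phi = build_regressor_matrix(y_driver, s, structure)
        w_true = rng.standard_normal(Phi.X.shape[1])
        clean = lpvar.RegressorMatrix(Phi.X, Phi.X @ w_true, structure)
        model = fit_rls(clean, lam=1e-8)
        assert np.linalg.norm(model.w - w_true) / np.linalg.norm(w_true) < 1e-3

    def test_negative_lambda_rejected(self, rng):
        y = rng.standard_normal(50)
        Phi = build_regressor_matrix(y, _random_scheduling(rng, 50), LPVARStructure(1, 1))
        with pytest.raises(ValueError):
            fit_rls(Phi, lam=-1.0)


class TestResiduals:
    def test_zero_coefficients_return_target(self, rng):
        y = rng.standard_normal(80)
        s = _random_scheduling(rng, 80)
        Phi = build_regressor_matrix(y, s, LPVARStructure(2, 1))
        model = lpvar.LPVARModel(np.zeros(Phi.X.shape[1]), Phi.structure)
        _, e = predict_residuals(model, Phi)
        assert np.array_equal(e, Phi.target)

    def test_noise_free_residuals_vanish(self, rng):
        y = rng.standard_normal(80)
        s = _random_scheduling(rng, 80)
        structure = LPVARStructure(2, 1)
        Phi = build_regressor_matrix(y, s, structure)
        w = rng.standard_normal(Phi.X.shape[1])
        clean = lpvar.RegressorMatrix(Phi.X, Phi.X @ w, structure)
        _, e = predict_residuals(lpvar.LPVARModel(w, structure), clean)
        assert np.max(np.abs(e)) < 1e-8

    def test_normal_equation_stationarity_at_optimum(self, rng):
        y = rng.standard_normal(300)
        s = _random_scheduling(rng, 300)
        Phi = build_regressor_matrix(y, s, LPVARStructure(3, 2))
        lam = 0.5
        model = fit_rls(Phi, lam=lam)
        _, e = predict_residuals(model, Phi)
        gap = np.linalg.norm(Phi.X.T @ e - lam * model.w)
        assert gap < 1e-8 * np.linalg.norm(Phi.X.T @ Phi.target)

    def test_dimension_mismatch_rejected(self, rng):
        y = rng.standard_normal(50)
        Phi = build_regressor_matrix(y, _random_scheduling(rng, 50), LPVARStructure(2, 1))
        with pytest.raises(ValueError):
            predict_residuals(lpvar.LPVARModel(np.zeros(3), Phi.structure), Phi)


class TestPermutation:
    def test_identity_permutation_reproduces_matrix_and_zero_index(self, rng):
        y = rng.standard_normal(120)
        s = _random_scheduling(rng, 120)
        structure = LPVARStructure(2, 2)
        Phi = build_regressor_matrix(y, s, structure)
        Phi0 = permuted_regressors(y, s, structure, permutation=np.arange(120))
        assert np.array_equal(Phi.X, Phi0.X)
        model = fit_rls(Phi, lam=0.1)
        _, e = predict_residuals(model, Phi)
        _, e0 = predict_residuals(model, Phi0)
        assert cfc_index(e, e0) == 0.0

    def test_constant_scheduling_immune_to_permutation(self, rng):
        y = rng.standard_normal(60)
        s = SchedulingSignal(np.full(60, 0.6), np.full(60, 0.8))
        structure = LPVARStructure(2, 1)
        Phi = build_regressor_matrix(y, s, structure)
        Phi0 = permuted_regressors(y, s, structure, rng=rng)
        assert np.allclose(Phi.X, Phi0.X)

    def test_scheduling_pairs_preserved_as_multiset(self, rng):
        s = _random_scheduling(rng, 40)
        perm = rng.permutation(40)
        sp = s.take(perm)
        original = sorted(zip(s.s1, s.s2))
        permuted = sorted(zip(sp.s1, sp.s2))
        assert np.allclose(original, permuted)


class TestCFCIndex:
    def test_equal_residuals_give_zero(self, rng):
        e = rng.standard_normal(100)
        assert cfc_index(e, e.copy()) == 0.0

    def test_log_ratio_algebra(self):
        e = np.ones(10)
        e0 = np.ones(10) * np.exp(0.5)  # energy ratio exp(-1)
        assert cfc_index(e, e0) == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative_for_arbitrary_pairs(self, rng):
        for _ in range(20):
            e = rng.standard_normal(50)
            e0 = rng.standard_normal(50)
            assert cfc_index(e, e0) >= 0.0

    def test_zero_permuted_energy_rejected(self):
        with pytest.raises(ValueError):
            cfc_index(np.ones(5), np.zeros(5))


class TestOrderSelection:
    def test_returned_pair_attains_grid_minimum(self, rng):
        y = rng.standard_normal(300)
        s = _random_scheduling(rng, 300)
        p, q, grid = select_order_step1(y, s, p_grid=(1, 2, 3), q_grid=(0, 1, 2))
        assert grid[(p, q)] == min(grid.values())

    def test_recovers_generating_polynomial_order(self, rng):
        """Data simulated from a strongly phase-modulated AR(2) with first-
        order coefficient dependence is assigned q = 1 by the MSE grid."""
        hits = 0
        for seed in range(10):
            gen = np.random.default_rng(seed)
            n = 1500
            phase = np.cumsum(gen.uniform(0.05, 0.3, n))
            s = SchedulingSignal(np.cos(phase), np.sin(phase))
            y = np.zeros(n)
            eps = 0.05 * gen.standard_normal(n)
            for t in range(2, n):
                a1 = 0.5 + 0.45 * s.s1[t]
                a2 = -0.4 + 0.3 * s.s2[t]
                y[t] = a1 * y[t - 1] + a2 * y[t - 2] + eps[t]
            _, q_star, _ = select_order_step1(
                y, s, p_grid=(1, 2, 3), q_grid=(0, 1, 2), lam_init=0.1
            )
            hits += q_star == 1
        assert hits >= 8

    def test_lambda_star_in_grid_and_two_path_consistency(self, rng):
        y = rng.standard_normal(400)
        s = _random_scheduling(rng, 400)
        Phi = build_regressor_matrix(y, s, LPVARStructure(3, 2))
        lam_star, ucurve = select_lambda_ucurve(Phi)
        assert lam_star in lpvar.DEFAULT_LAMBDA_GRID
        for lam, u in ucurve.items():
            model = fit_rls(Phi, lam=lam)
            _, e = predict_residuals(model, Phi)
            u_check = 1.0 / np.linalg.norm(model.w) + 1.0 / np.linalg.norm(e)
            assert abs(u - u_check) < 1e-10

    def test_ridge_norm_monotone_in_lambda(self, rng):
        y = rng.standard_normal(400)
        s = _random_scheduling(rng, 400)
        Phi = build_regressor_matrix(y, s, LPVARStructure(4, 2))
        norms = [
            np.linalg.norm(fit_rls(Phi, lam=lam).w) for lam in lpvar.DEFAULT_LAMBDA_GRID
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestEstimateCFC:
    OPTIONS = dict(p_grid=(2, 4, 6, 8, 10), q_grid=(0, 1, 2, 3))

    def test_deterministic_under_fixed_seed(self, set1_signal, coupled_bands):
        from lpvcfc.cfc import CFCOptions, estimate_cfc

        opts = CFCOptions(seed=0, **self.OPTIONS)
        a = estimate_cfc(set1_signal, *coupled_bands, options=opts)
        b = estimate_cfc(set1_signal, *coupled_bands, options=opts)
        assert a == b

    def test_coupled_pair_dominates_uncoupled_pair(self, coupled_bands):
        from lpvcfc.cfc import CFCOptions, estimate_cfc
        from lpvcfc.simulate import SimulationSpec, generate_signal

        wins = 0
        for seed in range(10):
            x = generate_signal(SimulationSpec(seed=100 + seed))
            opts = CFCOptions(seed=seed, **self.OPTIONS)
            coupled = estimate_cfc(x, *coupled_bands, options=opts)
            uncoupled = estimate_cfc(
                x, BandSpec(7.5, 8.5), BandSpec(29.0, 31.0), options=opts
            )
            wins += coupled > uncoupled
        assert wins >= 9

    def test_white_noise_well_separated_from_coupled_signal(self, coupled_bands):
        from lpvcfc.cfc import CFCOptions, estimate_cfc
        from lpvcfc.core import TimeSeries
        from lpvcfc.simulate import SimulationSpec, generate_signal

        coupled_vals, noise_vals = [], []
        for seed in range(10):
            opts = CFCOptions(seed=seed, **self.OPTIONS)
            x = generate_signal(SimulationSpec(seed=200 + seed))
            coupled_vals.append(estimate_cfc(x, *coupled_bands, options=opts))
            gen = np.random.default_rng(300 + seed)
            w = TimeSeries(gen.standard_normal(1440), 240.0)
            noise_vals.append(estimate_cfc(w, *coupled_bands, options=opts))
        assert np.median(coupled_vals) > 3.0 * np.median(noise_vals)

    def test_multiple_permutations_reduce_index_variance(self, set1_signal, coupled_bands):
        from lpvcfc.cfc import CFCOptions, estimate_cfc

        single = [
            estimate_cfc(
                set1_signal, *coupled_bands,
                options=CFCOptions(seed=s, n_permutations=1, **self.OPTIONS),
            )
            for s in range(8)
        ]
        averaged = [
            estimate_cfc(
                set1_signal, *coupled_bands,
                options=CFCOptions(seed=s, n_permutations=5, **self.OPTIONS),
            )
            for s in range(8)
        ]
        assert np.var(averaged) <= np.var(single)
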