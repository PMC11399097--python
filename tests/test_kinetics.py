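import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from trwaxs.kinetics import (
    KineticsDecomposition,
    SequentialModel,
    compare_models,
    concentration_profiles,
    fit_global,
    solve_basis_spectra,
)
from trwaxs.reduction import compute_difference, filter_trains
from trwaxs.synthetic import GeneratorConfig, simulate_train_series


class TestConcentrationProfiles:
    def test_initial_condition(self):
        c = concentration_profiles(SequentialModel(3, (0.3, 0.02)), np.array([0.0]))
        assert np.allclose(c, [[1.0, 0.0, 0.0]])

    def test_intermediate_peaks_at_closed_form_argmax(self):
        """C_B is maximal at ln(kA/kB)/(kA-kB) (about 9.24 us for 0.2, 0.05)."""
        k_a, k_b = 0.2, 0.05
        t = np.linspace(0.0, 60.0, 60001)
        c = concentration_profiles(SequentialModel(3, (k_a, k_b)), t)
        t_star = np.log(k_a / k_b) / (k_a - k_b)
        assert t_star == pytest.approx(9.24, abs=0.005)
        assert t[np.argmax(c[:, 1])] == pytest.approx(t_star, abs=2e-3)

    def test_degenerate_rate_limit(self):
        """As k_B -> k_A the generic formula approaches k_A t exp(-k_A t)."""
        k_a = 0.3
        t = np.linspace(0.1, 6.0, 200)  # k_a t <= 2, where the gap error is below tolerance
        generic = concentration_profiles(
            SequentialModel(3, (k_a, k_a * (1 + 1e-6)), degenerate_tol=1e-9), t
        )
        limit = k_a * t * np.exp(-k_a * t)
        assert np.allclose(generic[:, 1], limit, rtol=1e-6)

    @settings(derandomize=True, max_examples=40)
    @given(
        k_a=st.floats(1e-3, 5.0),
        ratio=st.floats(1e-3, 0.999),
        n_states=st.sampled_from([2, 3]),
    )
    def test_mass_conservation(self, k_a, ratio, n_states):
        rates = (k_a,) if n_states == 2 else (k_a, k_a * ratio)
        t = np.linspace(0.0, 300.0, 73)
        c = concentration_profiles(SequentialModel(n_states, rates), t)
        assert np.allclose(c.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((c > -1e-12) & (c < 1 + 1e-12))

    def test_monotonicity(self):
        t = np.linspace(0.0, 200.0, 100)
        c = concentration_profiles(SequentialModel(3, (0.1, 0.01)), t)
        assert np.all(np.diff(c[:, 0]) < 0)
        assert np.all(np.diff(c[:, 2]) > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            concentration_profiles(SequentialModel(2, (0.1,)), np.array([-1.0]))


class TestSolveBasisSpectra:
    def test_exact_recovery_of_consistent_system(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 100, 40)
        c = concentration_profiles(SequentialModel(3, (0.1, 0.01)), t)
        bs_true = rng.standard_normal((3, 25))
        ds = (c @ bs_true).T
        bs = solve_basis_spectra(ds, c)
        assert np.allclose(bs, bs_true, atol=1e-9)

    def test_single_state_is_time_mean(self):
        rng = np.random.default_rng(1)
        ds = rng.standard_normal((7, 9))
        bs = solve_basis_spectra(ds, np.ones((9, 1)))
        assert np.allclose(bs[0], ds.mean(axis=1))

    def test_matches_normal_equations_oracle(self):
        """Small random instance against an independent normal-equations solve."""
        rng = np.random.default_rng(2)
        c = rng.random((8, 3)) + 0.1
        ds = rng.standard_normal((5, 8))
        bs = solve_basis_spectra(ds, c)
        oracle = np.linalg.solve(c.T @ c, c.T @ ds.T)
        assert np.allclose(bs, oracle, atol=1e-10)

    def test_rank_deficiency_names_collinear_states(self):
        t = np.linspace(0, 10, 12)
        c = np.column_stack([np.exp(-0.1 * t), 2.0 * np.exp(-0.1 * t), t])
        with pytest.raises(ValueError, match="states 0 and 1"):
            solve_basis_spectra(np.ones((4, 12)), c)


class TestGlobalFit:
    def test_noiseless_three_state_recovery(self, noiseless_series):
        """Variable projection recovers both rates to 1e-4 relative on a
        noiseless 170 q x 175 t synthetic."""
        cfg, series = noiseless_series
        ds = compute_difference(series)
        fit = fit_global(ds.delta_S, series.time_us, n_states=3)
        assert fit.converged
        assert np.allclose(fit.model.rates, cfg.rates, rtol=1e-4)

    def test_three_state_residual_below_two_state(self, noiseless_series):
        cfg, series = noiseless_series
        ds = compute_difference(series)
        fit3 = fit_global(ds.delta_S, series.time_us, n_states=3)
        fit2 = fit_global(ds.delta_S, series.time_us, n_states=2)
        assert fit3.residual_r < fit2.residual_r

    def test_noisy_rate_recovery_at_generator_defaults(self):
        """Median relative rate error under Poisson noise stays below 10%."""
        errs = []
        for seed in range(20):
            cfg = GeneratorConfig(seed=1000 + seed)
            series = simulate_train_series(cfg)
            kept, _ = filter_trains(series)
            ds = compute_difference(kept, pairing="adjacent")
            fit = fit_global(ds.delta_S, series.time_us, n_states=3)
            errs.extend(np.abs(np.array(fit.model.rates) / np.array(cfg.rates) - 1.0))
        assert np.median(errs) < 0.10

    def test_variable_projection_matches_joint_optimization(self):
        """On a tiny instance the nested solve agrees with brute-force joint
        optimization over rates and spectra."""
        rng = np.random.default_rng(5)
        t = np.array([0.0, 2.0, 5.0, 10.0, 30.0, 80.0])
        bs_true = rng.standard_normal((2, 2))
        c_true = concentration_profiles(SequentialModel(2, (0.08,)), t)
        ds = (c_true @ bs_true).T + 0.01 * rng.standard_normal((2, 6))

        fit = fit_global(ds, t, n_states=2)

        def joint(params):
            model = SequentialModel(2, (np.exp(params[0]),))
            c = concentration_profiles(model, t)
            bs = params[1:].reshape(2, 2)
            return np.sum((ds - (c @ bs).T) ** 2)

        x0 = np.concatenate([[np.log(0.08)], bs_true.ravel()])
        res = minimize(joint, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000})
        assert fit.residual_r == pytest.approx(res.fun, rel=1e-5, abs=1e-10)

    def test_residual_invariant_under_q_permutation(self, noiseless_series):
        cfg, series = noiseless_series
        ds = compute_difference(series)
        rng = np.random.default_rng(9)
        perm = rng.permutation(ds.delta_S.shape[0])
        fit_a = fit_global(ds.delta_S, series.time_us, n_states=3)
        fit_b = fit_global(ds.delta_S[perm], series.time_us, n_states=3)
        assert fit_b.residual_r == pytest.approx(fit_a.residual_r, rel=1e-6, abs=1e-12)

    def test_estimator_interface(self, noiseless_series):
        cfg, series = noiseless_series
        ds = compute_difference(series)
        est = KineticsDecomposition(n_states=3)
        assert "n_states" in est.get_params()
        est.fit(ds.delta_S, t_us=series.time_us)
        assert est.rates_.shape == (2,)
        recon = est.predict(series.time_us)
        assert recon.shape == ds.delta_S.shape


class TestCompareModels:
    def test_threshold_rule(self, noiseless_series):
        cfg, series = noiseless_series
        ds = compute_difference(series)
        fit3 = fit_global(ds.delta_S, series.time_us, n_states=3)
        fit2 = fit_global(ds.delta_S, series.time_us, n_states=2)
        report = compare_models(fit2, fit3, improvement_threshold=0.05)
        assert report["selected_n_states"] == 3  # noiseless 3-state truth: huge improvement
        forced = compare_models(fit2, fit3, improvement_threshold=1.0)
        assert forced["selected_n_states"] == 2

    def test_two_state_truth_rarely_promotes_three_state(self):
        """On 2-state truth the nested 3-state gain stays below 5% in >= 18/20 seeds."""
        promoted = 0
        for seed in range(20):
            cfg = GeneratorConfig(
                seed=2000 + seed, n_train_pairs=10, n_states=2, rates=(0.05,),
            )
            series = simulate_train_series(cfg)
            kept, _ = filter_trains(series)
            ds = compute_difference(kept, pairing="adjacent")
            fit2 = fit_global(ds.delta_S, series.time_us, n_states=2)
            fit3 = fit_global(ds.delta_S, series.time_us, n_states=3)
            if compare_models(fit2, fit3)["selected_n_states"] == 3:
                promoted += 1
        assert promoted <= 2

    def test_data_hash_mismatch_rejected(self, noiseless_series):
        cfg, series = noiseless_series
        ds = compute_difference(series)
        fit3 = fit_global(ds.delta_S, series.time_us, n_states=3)
        fit2 = fit_global(ds.delta_S * 1.5, series.time_us, n_states=2)
        with pytest.raises(ValueError, match="hash"):
            compare_models(fit2, fit3)
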