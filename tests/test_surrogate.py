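"""Tests for the surrogate ODE models and their solvers."""

import numpy as np
import pytest

import smorepars.surrogate as sm


@pytest.fixture
def treat_params():
    return sm.SMTreatmentParams(
        lam=0.3, alpha=0.25, K=2500, beta_1S=0.2, beta_2M=0.3,
        kappa_beta=1.5, m=1.2, delta=0.05, kappa_delta=2.0,
    )


class TestRHS:
    def test_extinction_fixed_point(self):
        p = sm.SMControlParams(lam=0.5, alpha=0.5, K=100)
        assert np.allclose(sm.control_rhs((0.0, 0.0), p), 0.0)

    def test_capacity_equilibrium(self):
        p = sm.SMControlParams(lam=1.0, alpha=1.0, K=100)
        assert np.allclose(sm.control_rhs((50.0, 50.0), p), 0.0)

    def test_uncrowded_growth_rate_is_dominant_eigenvalue(self):
        # K -> infinity, lam = alpha = 1: growth rate sqrt(2) - 1
        p = sm.SMControlParams(lam=1.0, alpha=1.0, K=1e12)
        traj = sm.solve(p, [50, 50], np.linspace(20, 30, 21))
        n = traj["N"].to_numpy()
        rate = np.diff(np.log(n)) / np.diff(traj["time_h"].to_numpy())
        assert rate[-1] == pytest.approx(np.sqrt(2) - 1, rel=1e-3)

    def test_treatment_reduces_to_control_at_zero_dose(self, treat_params):
        state = np.array([30.0, 20.0, 0.0, 0.0])
        d_treat = sm.treatment_rhs(state, treat_params, C=0.0)
        d_ctrl = sm.control_rhs(state[:2], treat_params)
        assert np.allclose(d_treat[:2], d_ctrl)
        assert np.allclose(d_treat[2:], 0.0)

    def test_saturation_limits(self, treat_params):
        p = treat_params
        state = np.array([10.0, 10.0, 5.0, 5.0])
        d = sm.treatment_rhs(state, p, C=1e9)
        # arrest fluxes approach beta_i * N_i, death flux approaches delta * A_i
        assert d[2] == pytest.approx(p.beta_1S * 10 - p.delta * 5, rel=1e-6)
        assert d[3] == pytest.approx(p.beta_2M * 10 - p.delta * 5, rel=1e-6)

    def test_total_derivative_identity(self, treat_params):
        """dN/dt = alpha*(1 - N/K)*N_2M - death_flux*(A_1S + A_2M), at random states."""
        rng = np.random.default_rng(0)
        p = treat_params
        for _ in range(20):
            state = rng.uniform(0, 500, size=4)
            C = rng.uniform(0, 10)
            d = sm.treatment_rhs(state, p, C)
            N = state.sum()
            death = p.delta * C / (p.kappa_delta + C)
            expected = p.alpha * (1 - N / p.K) * state[1] - death * (state[2] + state[3])
            assert d.sum() == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_hill_conventions(self):
        assert sm.hill(0.0, 2.0, 0.5) == 0.0
        assert sm.hill(2.0, 2.0, 3.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            sm.hill(1.0, -1.0)


class TestSolve:
    def test_initial_total_preserved(self):
        p = sm.SMControlParams(lam=0.1, alpha=0.08, K=2500)
        q = sm.stationary_split(p.lam, p.alpha)
        traj = sm.solve(p, [100 * q, 100 * (1 - q)], [0.0, 10.0])
        assert traj["N"].iloc[0] == pytest.approx(100.0, rel=1e-9)

    def test_control_converges_to_carrying_capacity(self):
        p = sm.SMControlParams(lam=0.2, alpha=0.15, K=1800)
        traj = sm.solve(p, [60, 40], [500.0])
        assert abs(traj["N"].iloc[-1] - p.K) / p.K < 1e-3

    def test_monotone_total_below_capacity(self):
        p = sm.SMControlParams(lam=0.2, alpha=0.15, K=1000)
        traj = sm.solve(p, [60, 40], np.linspace(1, 200, 100))
        assert np.all(np.diff(traj["N"].to_numpy()) > 0)

    def test_nonnegativity_and_fraction_range(self, treat_params):
        traj = sm.solve(treat_params, [60, 40, 0, 0], np.linspace(1, 200, 50), C=7.55)
        vals = traj[["N1S", "N2M", "A1S", "A2M"]].to_numpy()
        assert np.all(vals >= -1e-5)
        assert np.all((traj["g2m_fraction"] >= 0) & (traj["g2m_fraction"] <= 1))

    def test_treatment_zero_dose_equals_control_trajectory(self, treat_params):
        tg = [10, 24, 36, 48, 72]
        ctrl = sm.SMControlParams(lam=treat_params.lam, alpha=treat_params.alpha, K=treat_params.K)
        a = sm.solve(treat_params, [60, 40, 0, 0], tg, C=0.0)
        b = sm.solve(ctrl, [60, 40], tg)
        assert np.allclose(a[["N1S", "N2M"]], b[["N1S", "N2M"]], rtol=1e-5)

    def test_tolerance_convergence(self, treat_params):
        tg = [10, 24, 36, 48, 72]
        a = sm.solve(treat_params, [60, 40, 0, 0], tg, C=0.75, rtol=1e-6, atol=1e-9)
        b = sm.solve(treat_params, [60, 40, 0, 0], tg, C=0.75, rtol=1e-9, atol=1e-12)
        rel = np.abs(a["N"] - b["N"]) / np.abs(b["N"])
        assert np.max(rel.to_numpy()) < 1e-4

    def test_fast_path_matches_adaptive_solver(self, treat_params):
        tg = np.array([10.0, 24.0, 36.0, 48.0, 72.0])
        ref = sm.solve(treat_params, [60, 40, 0, 0], tg, C=0.75, rtol=1e-10, atol=1e-12)
        fast = sm.solve_fast(treat_params, [60, 40, 0, 0], tg, C=0.75)
        ref_vals = ref[["N1S", "N2M", "A1S", "A2M"]].to_numpy()
        assert np.allclose(fast, ref_vals, rtol=1e-6, atol=1e-8)

    def test_invalid_grid_and_negative_init(self):
        p = sm.SMControlParams(lam=0.1, alpha=0.1, K=100)
        with pytest.raises(ValueError):
            sm.solve(p, [1, 1], [])
        with pytest.raises(ValueError):
            sm.solve(p, [-1, 1], [1.0])

    def test_stationary_split_matches_long_run_ratio(self):
        p = sm.SMControlParams(lam=0.12, alpha=0.3, K=1e12)
        q = sm.stationary_split(p.lam, p.alpha)
        traj = sm.solve(p, [50, 50], [100.0])
        share = traj["N1S"].iloc[-1] / traj["N"].iloc[-1]
        assert share == pytest.approx(q, rel=1e-4)
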