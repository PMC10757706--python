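"""Unit and property tests for the lattice ABM."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

import smorepars.abm as abm


class TestScalarRules:
    @pytest.mark.parametrize(
        "ka,expected",
        [(9, (3, 3)), (10, (4, 3)), (2500, (50, 50)), (1, (1, 1)), (7, (3, 3))],
    )
    def test_microenvironment_dims(self, ka, expected):
        l, w = abm.microenvironment_dims(ka)
        assert (l, w) == expected
        assert l * w >= ka

    def test_microenvironment_dims_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            abm.microenvironment_dims(0)

    @pytest.mark.parametrize(
        "C,r,gamma,a,expected",
        [(0.0, 0.8, 1.0, 1.0, 0.0), (1.0, 0.8, 1.0, 1.0, 0.4), (3.0, 0.8, 1.0, 1.0, 0.6)],
    )
    def test_arrest_probability_values(self, C, r, gamma, a, expected):
        assert abm.arrest_probability(C, r, gamma, a) == pytest.approx(expected)

    def test_arrest_probability_monotone_and_bounded(self):
        doses = np.linspace(0, 50, 40)
        vals = [abm.arrest_probability(c, 0.7, 2.0) for c in doses]
        assert np.all(np.diff(vals) >= 0)
        assert max(vals) <= 0.7

    def test_apoptosis_rate_half_saturation_and_limit(self):
        assert abm.apoptosis_rate(0.0, 0.1, 2.0) == 0.0
        assert abm.apoptosis_rate(2.0, 0.1, 2.0) == pytest.approx(0.05)
        assert abm.apoptosis_rate(1e9, 0.1, 2.0) == pytest.approx(0.1, rel=1e-6)

    def test_hill_domain_errors(self):
        with pytest.raises(ValueError):
            abm.arrest_probability(1.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            abm.apoptosis_rate(1.0, 0.1, -1.0)

    def test_rate_to_step_probability(self):
        assert abm.rate_to_step_probability(0.0, 0.25) == 0.0
        assert abm.rate_to_step_probability(0.1, 0.25) == pytest.approx(
            1 - np.exp(-0.025)
        )
        with pytest.raises(ValueError):
            abm.rate_to_step_probability(-0.1, 0.25)

    @given(rate=st.floats(0, 100), dt=st.floats(1e-3, 10))
    def test_rate_probability_in_unit_interval(self, rate, dt):
        p = abm.rate_to_step_probability(rate, dt)
        # mathematically in [0, 1); float rounding can saturate at 1.0
        assert 0.0 <= p <= 1.0
        if rate * dt < 30:
            assert p < 1.0
        if rate * dt < 1e-4:
            assert p == pytest.approx(rate * dt, rel=1e-3)


class TestLattice:
    def test_seed_counts_and_determinism(self):
        control = abm.ABMControlParams(K_A=100)
        s1 = abm.seed_lattice(control, 100, rng_seed=3)
        s2 = abm.seed_lattice(control, 100, rng_seed=3)
        assert s1.n_alive == 100
        assert np.array_equal(s1.grid, s2.grid)
        assert np.array_equal(s1.phase, s2.phase)
        s1.check()

    def test_seed_empty_and_capacity_error(self):
        control = abm.ABMControlParams(K_A=9)
        assert abm.seed_lattice(control, 0, rng_seed=0).n_alive == 0
        with pytest.raises(ValueError):
            abm.seed_lattice(control, 10, rng_seed=0)

    def test_null_dynamics_leaves_state_unchanged(self):
        control = abm.ABMControlParams(
            K_A=100, s=0.0, rho_G1S=0.0, rho_SG2=0.0, rho_G2M=0.0, rho_MG1=0.0
        )
        state = abm.seed_lattice(control, 50, rng_seed=1)
        before = (state.grid.copy(), state.phase.copy())
        abm.step(state, control, seed=2)
        assert np.array_equal(state.grid, before[0])
        assert np.array_equal(state.phase, before[1])
        assert state.clock == 0.25

    def test_full_lattice_blocks_mitosis(self):
        # every site occupied, all agents in M with certain advance: no growth
        control = abm.ABMControlParams(
            K_A=9, T_con=1, s=0.0, rho_G1S=0.0, rho_SG2=0.0, rho_G2M=0.0, rho_MG1=1e9
        )
        state = abm.seed_lattice(control, 9, rng_seed=0, init_phases="g1")
        state.phase[:9] = 3  # force M
        abm.step(state, control, seed=4)
        assert state.n_alive == 9
        assert np.all(state.phase[:9] == 0)  # returned to G1 without mitosis

    def test_no_arrest_or_death_without_drug(self):
        control = abm.ABMControlParams(K_A=400)
        treat = abm.ABMTreatmentParams(r_G1=1.0, r_G2=1.0, delta_p=1.0)
        out = abm.simulate(control, treat=treat, C=0.0, t_grid=[0, 24], n_reps=3, rng_seed=7)
        assert np.all(out.counts[:, :, 4:] == 0)
        assert np.all(np.diff(out.total, axis=1) >= 0)

    def test_arrested_agents_are_absorbing(self):
        control = abm.ABMControlParams(K_A=400, s=2.0)
        treat = abm.ABMTreatmentParams(r_G1=1.0, r_G2=1.0, gamma1=0.1, delta_p=0.0)
        out = abm.simulate(
            control, treat=treat, C=50.0, t_grid=np.arange(0, 121.0, 8.0),
            n_reps=3, rng_seed=9,
        )
        arrested = out.counts[:, :, 4] + out.counts[:, :, 5]
        # with delta_p=0 arrested cells never leave: monotone nondecreasing
        assert np.all(np.diff(arrested, axis=1) >= 0)
        # high dose with r~1: essentially everyone ends up arrested
        cycling_final = out.counts[:, -1, :4].sum(axis=1)
        assert np.all(cycling_final <= 0.02 * out.total[:, -1])

    def test_simulate_determinism_and_output_invariants(self, small_abm_output):
        out = small_abm_output
        control = abm.ABMControlParams(K_A=900, s=1.0)
        again = abm.simulate(control, t_grid=[0.0, 10.0, 24.0, 48.0], n_reps=4, rng_seed=5)
        assert np.array_equal(out.counts, again.counts)
        assert np.all(out.counts >= 0)
        assert np.all(out.total <= 900)
        frac = out.g2m_fraction
        assert np.all((frac >= 0) & (frac <= 1))
        # total column equals the bucket sum in the tidy frame
        df = out.to_frame()
        assert (df[list(abm.COUNT_COLUMNS)].sum(axis=1) == df["total"]).all()

    def test_simulate_rejects_bad_grids(self):
        control = abm.ABMControlParams(K_A=100)
        with pytest.raises(ValueError):
            abm.simulate(control, t_grid=[])
        with pytest.raises(ValueError):
            abm.simulate(control, t_grid=[0.0, 0.33])  # not a multiple of dt


class TestMeanField:
    def test_sparse_lattice_matches_linear_cycle_oracle(self):
        """With T_con=0 and population << capacity, mean phase counts follow
        the linear 4-compartment cycle ODE (matrix exponential) within
        Monte-Carlo error."""
        rhos = np.array([0.15, 0.2, 0.3, 0.8])
        control = abm.ABMControlParams(
            K_A=10000, T_con=0, s=1.0,
            rho_G1S=rhos[0], rho_SG2=rhos[1], rho_G2M=rhos[2], rho_MG1=rhos[3],
        )
        t_grid = np.array([0.0, 6.0, 12.0, 18.0])
        out = abm.simulate(
            control, t_grid=t_grid, n_reps=60, dt=0.02, rng_seed=123, n0=100
        )
        Q = np.array(
            [
                [-rhos[0], 0, 0, 2 * rhos[3]],
                [rhos[0], -rhos[1], 0, 0],
                [0, rhos[1], -rhos[2], 0],
                [0, 0, rhos[2], -rhos[3]],
            ]
        )
        x0 = 100 * abm.stationary_phase_distribution(rhos)
        phase_counts = out.counts[:, :, :4].astype(float)
        mean = phase_counts.mean(axis=0)
        se = phase_counts.std(axis=0, ddof=1) / np.sqrt(out.n_reps)
        for ti, t in enumerate(t_grid[1:], start=1):
            expected = expm(Q * t) @ x0
            assert np.all(np.abs(mean[ti] - expected) <= 3 * np.maximum(se[ti], 1e-9))
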