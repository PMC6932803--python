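"""Unit and property tests of the tumor-immune-drug ODE core."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icisim import (
    DoseSchedule, GeneralParameters, SpecificParameters, StateVector,
    blocked_fraction, division_rates, initial_state, pd1_pressure,
    reinvigoration_percent, rhs, simulate, tumor_load,
)
from icisim.model import EFF, EM, EXH, SCM, CM, N_COMPARTMENTS, _rhs_flat

from .oracles import brute_force_rhs, euler_integrate

WEEK_H = 7 * 24.0


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------

class TestParameters:
    def test_defaults_are_reference_patient_values(self, sp):
        assert (sp.p_C, sp.kE0, sp.rho_D) == (1.828, 0.00603, 0.95)
        assert (sp.kC03, sp.kC04) == (0.0058, 0.00535)
        assert (sp.a_SCM, sp.a_CM, sp.a_EM, sp.a_EFF) == (0.05, 0.9, 0.03, 0.92)

    @pytest.mark.parametrize("field, value", [
        ("p_C", -1.0), ("kE0", np.nan), ("a_CM", 1.5), ("a_EFF", -0.1),
    ])
    def test_specific_validation(self, field, value):
        with pytest.raises(ValueError):
            SpecificParameters(**{field: value})

    @pytest.mark.parametrize("field, value", [
        ("m", 0),
        ("p_div", (0.01, 0.02, 0.03, 0.04)),      # must decrease
        ("mu", (1e-3, 1e-4, 1e-4, 1e-4, 1e-4)),   # must not decrease
        ("eps_div", 1.5),
        ("EC50", 0.0),
    ])
    def test_general_validation(self, field, value):
        with pytest.raises(ValueError):
            GeneralParameters(**{field: value})

    def test_division_rates_strictly_decreasing(self, gp):
        assert np.all(np.diff(gp.p_div) < 0)


class TestInitialState:
    def test_zero_pool_gives_empty_grid(self, gp):
        state = initial_state(0.0, 5.0, 2.0, gp)
        assert np.all(state.T == 0)
        assert (state.C, state.D_act, state.D_m, state.P) == (5.0, 2.0, 2.0, 0.0)

    def test_uniform_split_one_cell_per_bin(self, gp):
        n_bins = N_COMPARTMENTS * (gp.m + 1)
        state = initial_state(float(n_bins), 0.0, 0.0, gp)
        assert state.T.shape == (5, gp.m + 1)
        assert np.all(state.T == 1.0)

    def test_mass_conserved_and_exactly_uniform(self, gp):
        state = initial_state(260.0, 0.0, 0.0, gp)
        assert np.isclose(state.T.sum(), 260.0)
        assert state.T.max() == state.T.min()

    def test_negative_inputs_rejected(self, gp):
        with pytest.raises(ValueError):
            initial_state(-1.0, 0.0, 0.0, gp)


# ---------------------------------------------------------------------------
# Elementary signals
# ---------------------------------------------------------------------------

class TestSignals:
    def test_blocked_fraction_identities(self):
        assert blocked_fraction(0.0, 2.0) == 0.0
        assert blocked_fraction(2.0, 2.0) == 0.5
        assert np.isclose(blocked_fraction(9.0 * 2.0, 2.0), 0.9)
        with pytest.raises(ValueError):
            blocked_fraction(1.0, 0.0)

    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_blocked_fraction_monotone_and_bounded(self, p1, p2):
        lo, hi = sorted([p1, p2])
        b_lo, b_hi = blocked_fraction(lo, 3.0), blocked_fraction(hi, 3.0)
        assert 0.0 <= b_lo <= b_hi < 1.0

    def test_pd1_pressure_limits(self, gp):
        assert pd1_pressure(0.0, 0.5, 10, gp) == 0.0
        assert pd1_pressure(1e12, 1.0, gp.m, gp) == 0.0    # full blockade
        half = pd1_pressure(gp.K_PD, 0.0, gp.m, gp)
        assert np.isclose(half, 0.5)

    @given(st.floats(0, 1e13), st.floats(0, 1), st.integers(0, 25))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_pd1_pressure_in_unit_interval(self, C, B, j):
        g = pd1_pressure(C, B, j, GeneralParameters())
        assert 0.0 <= g <= 1.0


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

class TestRHS:
    def test_pure_drug_elimination(self, sp, gp):
        state = initial_state(0.0, 0.0, 0.0, gp)
        state.P = 8.0
        d = rhs(0.0, state, sp, gp)
        assert np.all(d.T == 0)
        assert d.C == 0 and d.D_m == 0 and d.D_act == 0
        assert np.isclose(d.P, -np.log(2) / gp.t_half * 8.0)

    def test_power_law_growth_exponent(self, sp, gp):
        state = initial_state(0.0, 8e9, 0.0, gp)
        d = rhs(0.0, state, sp, gp, killing_off=True)
        assert np.isclose(d.C, sp.p_C * 8e9 ** (2 / 3), rtol=1e-12)

    def test_single_cohort_routing_fluxes(self, sp, gp_small):
        """One SCM cohort at j=0 splits 2a / 2(1-a) into (SCM,1), (CM,1)."""
        N = 1000.0
        T = np.zeros((5, gp_small.m + 1))
        T[SCM, 0] = N
        state = StateVector(T=T, D_act=0.0, D_m=0.0, C=0.0, P=0.0)
        d = rhs(0.0, state, sp, gp_small, killing_off=True)
        r = gp_small.p_div[SCM]
        assert np.isclose(d.T[SCM, 1], 2 * sp.a_SCM * r * N, rtol=1e-9)
        assert np.isclose(d.T[CM, 1], 2 * (1 - sp.a_SCM) * r * N, rtol=1e-9)
        assert np.isclose(d.T[SCM, 0], -r * N, rtol=1e-6)

    def test_effector_differentiates_into_exhausted(self, sp, gp_small):
        T = np.zeros((5, gp_small.m + 1))
        T[EFF, 0] = 50.0
        state = StateVector(T=T, D_act=0.0, D_m=0.0, C=0.0, P=0.0)
        d = rhs(0.0, state, sp, gp_small, killing_off=True)
        r = gp_small.p_div[EFF]
        assert np.isclose(d.T[EXH, 1], 2 * (1 - sp.a_EFF) * r * 50.0, rtol=1e-9)

    def test_no_division_out_of_terminal_senescence_row(self, sp, gp):
        """Division flux out of j = m is identically zero."""
        T = np.zeros((5, gp.m + 1))
        T[:, gp.m] = 1e4
        state = StateVector(T=T, D_act=0.0, D_m=0.0, C=0.0, P=0.0)
        d = rhs(0.0, state, sp, gp, killing_off=True)
        # only natural death remains; no inflow anywhere else
        expected = np.zeros_like(T)
        expected[:, gp.m] = -np.asarray(gp.mu) * 1e4
        assert np.allclose(d.T, expected, rtol=1e-12, atol=0)

    def test_no_pd1_terms_without_tumor(self, sp, gp):
        """With C = 0 the PD-1 pressure vanishes: EM/EFF decay at mu only."""
        T = np.full((5, gp.m + 1), 100.0)
        state = StateVector(T=T, D_act=0.0, D_m=0.0, C=0.0, P=0.0)
        d = rhs(0.0, state, sp, gp, killing_off=True)
        sp0 = dataclasses.replace(sp, kC03=0.0, kC04=0.0)
        d0 = rhs(0.0, state, sp0, gp, killing_off=True)
        assert np.array_equal(d.T, d0.T)

    def test_matches_brute_force_oracle_on_toy_grid(self, sp, gp_small, rng):
        """Mean-field rhs equals a literal loop transcription of the rules."""
        T = rng.uniform(0, 100, size=(5, gp_small.m + 1))
        state = StateVector(T=T.copy(), D_act=3.0, D_m=7.0, C=5e8, P=4.0)
        d = rhs(0.0, state, sp, gp_small)
        dT, dDa, dDm, dC, dP = brute_force_rhs(
            T, 3.0, 7.0, 5e8, 4.0, sp, gp_small)
        assert np.allclose(d.T, dT, rtol=1e-12)
        assert np.isclose(d.D_act, dDa) and np.isclose(d.D_m, dDm)
        assert np.isclose(d.C, dC) and np.isclose(d.P, dP)

    def test_mass_doubles_per_division_flux(self, sp, gp_small):
        """No death/influx/kill: d(total)/dt equals the total division flux.

        Every division removes one mother and adds two daughters, so total
        cell count grows by exactly the division flux; checked against a
        forward-Euler brute-force integration on the small grid.
        """
        T0 = np.zeros((5, gp_small.m + 1))
        T0[SCM, 0] = 500.0
        T0[CM, 1] = 200.0
        state = StateVector(T=T0.copy(), D_act=0.0, D_m=0.0, C=0.0, P=0.0)
        d = rhs(0.0, state, sp, gp_small, killing_off=True)
        r = division_rates(state, sp, gp_small)
        assert np.isclose(d.T.sum(), (r * T0).sum(), rtol=1e-9)

        # against the independent Euler oracle over a finite horizon
        T_euler, *_ = euler_integrate(T0, sp, gp_small, t_end=10.0, dt=0.002)
        traj = simulate(sp, gp_small, DoseSchedule.none(), 10.0, state,
                        drug_off=True, killing_off=True, grid_h=10.0,
                        rtol=1e-10)
        T_ours = traj.states[-1][:5 * (gp_small.m + 1)]
        assert np.isclose(T_ours.sum(), T_euler.sum(), rtol=1e-4)
        assert T_euler.sum() > T0.sum()   # division only adds cells


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_zero_state_is_fixed_point(self, sp, gp):
        init = initial_state(0.0, 0.0, 0.0, gp)
        traj = simulate(sp, gp, DoseSchedule.none(), 200.0, init,
                        drug_off=True)
        assert np.all(traj.states == 0)

    def test_untreated_immune_free_tumor_matches_closed_form(self, sp, gp):
        """dC/dt = p_C C^(2/3) integrates to (C0^(1/3) + p_C t / 3)^3."""
        C0 = 1e10
        init = initial_state(0.0, C0, 0.0, gp)
        t_end = 28 * 30.4375 * 24.0
        traj = simulate(sp, gp, DoseSchedule.none(), t_end, init,
                        killing_off=True, drug_off=True, rtol=1e-10,
                        grid_h=24.0)
        closed = (C0 ** (1 / 3) + sp.p_C * traj.times / 3.0) ** 3
        rel = np.abs(traj.tumor_cells - closed) / closed
        assert rel.max() < 1e-6

    def test_drug_half_life_identity(self, sp, gp):
        """A single bolus decays to half its peak after one half-life."""
        init = initial_state(0.0, 0.0, 0.0, gp)
        sched = DoseSchedule(dose_times=(0.0,), dose_amounts=(120.0,))
        traj = simulate(sp, gp, sched, gp.t_half, init, rtol=1e-10, grid_h=gp.t_half / 8)
        peak = 120.0 / gp.V_d
        assert np.isclose(traj.drug_conc[0], peak, rtol=1e-9)
        assert np.isclose(traj.drug_conc[-1], peak / 2, rtol=1e-6)

    def test_dose_events_accumulate(self, sp, gp):
        init = initial_state(0.0, 0.0, 0.0, gp)
        sched = DoseSchedule.q3w(120.0, 4 * 504.0)
        traj = simulate(sp, gp, sched, 4 * 504.0, init)
        # trough just before each new dose keeps rising (accumulation)
        troughs = [traj.drug_conc[np.argmin(np.abs(traj.times - t))]
                   for t in (503.9, 1007.9, 1511.9)]
        assert np.all(np.diff(troughs) > 0)

    def test_tumor_load_week12_monotone_in_dose(self, sp, gp):
        """More drug never yields a larger 12-week tumor load."""
        loads = []
        for dose in (0.0, 60.0, 120.0, 240.0):
            init = initial_state(1e7, 1e10, 10.0, gp)
            sched = DoseSchedule.q3w(dose, 12 * WEEK_H)
            traj = simulate(sp, gp, sched, 12 * WEEK_H, init)
            loads.append(traj.tumor_cells[-1])
        assert np.all(np.diff(loads) <= 0)

    def test_invalid_inputs_rejected(self, sp, gp):
        init = initial_state(0.0, 0.0, 0.0, gp)
        with pytest.raises(ValueError):
            simulate(sp, gp, DoseSchedule.none(), -5.0, init)
        bad = initial_state(10.0, 1e9, 1.0, gp)
        bad.C = -1.0
        with pytest.raises(ValueError):
            simulate(sp, gp, DoseSchedule.none(), 10.0, bad)


# ---------------------------------------------------------------------------
# Derived statistics
# ---------------------------------------------------------------------------

class TestDerivedStatistics:
    def test_tumor_load_unit_conversion(self, sp, gp):
        init = initial_state(0.0, 1e9, 0.0, gp)
        traj = simulate(sp, gp, DoseSchedule.none(), 12.0, init,
                        killing_off=True, drug_off=True)
        series = tumor_load(traj)
        assert np.isclose(series.load_cm3[0], 1.0)
        assert np.isclose(series.weeks[-1] * WEEK_H, traj.times[-1])

    def test_reinvigoration_uniform_rate(self, sp):
        """Uniform division rate r over all occupied bins: 100 tau r."""
        gp = GeneralParameters(p_div=(0.08, 0.06, 0.04, 1.0 / 48.0))
        T = np.zeros((5, gp.m + 1))
        T[EFF, :gp.m] = 10.0          # only EFF occupied, below j=m
        state = StateVector(T=T, D_act=0.0, D_m=0.0, C=0.0, P=0.0)
        pct = reinvigoration_percent(state, sp, gp)
        assert np.isclose(pct, 100.0 * gp.tau / 48.0)   # 50%

    def test_reinvigoration_weighted_two_bins(self, sp):
        """Counts (90, 10) at rates (0, 1/24): 10% with tau = 24 h."""
        gp = GeneralParameters(p_div=(0.5, 0.3, 0.1, 1.0 / 24.0))
        T = np.zeros((5, gp.m + 1))
        T[EXH, 0] = 90.0              # exhausted cells never divide
        T[EFF, 0] = 10.0
        state = StateVector(T=T, D_act=0.0, D_m=0.0, C=0.0, P=0.0)
        assert np.isclose(reinvigoration_percent(state, sp, gp), 10.0)

    def test_reinvigoration_capped_and_undefined_cases(self, sp, gp):
        empty = initial_state(0.0, 0.0, 0.0, gp)
        with pytest.raises(ValueError):
            reinvigoration_percent(empty, sp, gp)
        full = initial_state(1e6, 0.0, 1e6, gp)
        assert reinvigoration_percent(full, sp, gp) <= 100.0
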