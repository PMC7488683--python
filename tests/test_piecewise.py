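import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringcycles.model_core import SpecValidationError, StepCircuitSpec
from ringcycles.piecewise import (
    countable_family,
    cycle_schedule,
    delay_from_period,
    exact_step_trajectory,
    period_from_delay,
    symmetric_family_nd,
)

LN2 = math.log(2.0)


class TestClosedForms:
    def test_reference_period(self):
        """alpha=2, tau=ln 2: (2e^tau-1)(2e^tau-2+1)/(2-1) = 9, so T = ln 9."""
        assert period_from_delay(2.0, LN2) == pytest.approx(math.log(9.0), abs=1e-14)

    def test_reference_delay(self):
        assert delay_from_period(2.0, math.log(9.0)) == pytest.approx(LN2, abs=1e-14)

    def test_short_delay_limit(self):
        assert period_from_delay(2.0, 1e-12) < 1e-10
        assert delay_from_period(2.0, 1e-12) < 1e-10

    def test_subcritical_alpha_rejected(self):
        with pytest.raises(SpecValidationError):
            period_from_delay(1.0, 0.5)
        with pytest.raises(SpecValidationError):
            delay_from_period(0.8, 1.0)

    @given(alpha=st.floats(1.5, 50.0), tau=st.floats(0.05, 5.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_inverse_roundtrip(self, alpha, tau):
        T = period_from_delay(alpha, tau)
        assert delay_from_period(alpha, T) == pytest.approx(tau, abs=1e-12)
        assert T > 2.0 * tau

    def test_schedule_reference_values(self):
        cyc = cycle_schedule(2.0, LN2)
        assert cyc.t2 == pytest.approx(math.log(3.0), abs=1e-14)
        assert cyc.x_min == pytest.approx(0.5, abs=1e-14)
        assert cyc.x_max == pytest.approx(1.5, abs=1e-14)
        assert cyc.t3 == pytest.approx(cyc.T - LN2, abs=1e-14)

    @pytest.mark.parametrize("alpha,tau", [(2.0, LN2), (5.0, 0.3), (30.0, 1.7)])
    def test_schedule_internal_consistency(self, alpha, tau):
        cyc = cycle_schedule(alpha, tau)
        assert 0 < cyc.t1 < cyc.t2 < cyc.t3 < cyc.T
        assert cyc.x_min < 1.0 < cyc.x_max
        assert cyc.t2 - cyc.t1 == pytest.approx(tau, abs=1e-12)
        assert cyc.T - cyc.t3 == pytest.approx(tau, abs=1e-12)
        assert cyc.x_min == pytest.approx(math.exp(-tau), abs=1e-14)


class TestEventDrivenSolver:
    def test_single_decay_crossing(self):
        spec = StepCircuitSpec(1, alpha=2.0, beta=1.0, tau=5.0)
        traj, events = exact_step_trajectory(spec, 2.0, 3.0)
        # history is 2 (> 1), so production stays off for the whole window
        down = [e for e in events if e.direction == "down"]
        assert len(down) == 1
        assert down[0].time == pytest.approx(LN2, abs=1e-12)

    def test_scalar_cycle_extrema_and_period(self):
        spec = StepCircuitSpec(1, alpha=2.0, beta=1.0, tau=LN2)
        traj, events = exact_step_trajectory(spec, 1.5, 80.0)
        # the extrema sit exactly at the production toggles, i.e. at the
        # starts of the stored exponential segments
        late_starts = [v for (t, v, _) in traj.meta["segments"][0] if t > 60.0]
        assert min(late_starts) == pytest.approx(0.5, abs=1e-10)
        assert max(late_starts) == pytest.approx(1.5, abs=1e-10)
        ups = [e.time for e in events if e.direction == "up" and e.time > 60.0]
        assert np.allclose(np.diff(ups), math.log(9.0), atol=1e-10)

    def test_period_formula_matches_simulation(self):
        """Closed-form periods against exact event times on a random grid."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            alpha = rng.uniform(1.5, 50.0)
            tau = rng.uniform(0.05, 5.0)
            T_formula = period_from_delay(alpha, tau)
            spec = StepCircuitSpec(1, alpha=alpha, beta=1.0, tau=tau)
            t_end = 30.0 * max(T_formula, 1.0)
            traj, events = exact_step_trajectory(spec, 0.5, t_end, sample_dt=t_end / 10)
            ups = [e.time for e in events if e.direction == "up"
                   and e.time > t_end - 6 * T_formula]
            assert len(ups) >= 3
            assert np.allclose(np.diff(ups), T_formula, atol=1e-9)

    def test_schedule_matches_event_times(self):
        alpha, tau = 2.0, LN2
        cyc = cycle_schedule(alpha, tau)
        spec = StepCircuitSpec(1, alpha=alpha, beta=1.0, tau=tau)
        traj, events = exact_step_trajectory(spec, 1.5, 90.0)
        ups = [e.time for e in events if e.direction == "up" and e.time > 70.0]
        downs = [e.time for e in events if e.direction == "down" and e.time > 70.0]
        # on the cycle, the down-crossing trails the up-crossing by t3 - t1
        gap = downs[-1] - ups[-2] if downs[-1] > ups[-2] else downs[-1] - ups[-3]
        assert gap % cyc.T == pytest.approx((cyc.t3 - cyc.t1) % cyc.T, abs=1e-9)
        assert cyc.t3 - cyc.t2 < tau

    def test_exponential_pieces_satisfy_ode(self):
        """Between events dx/dt must equal (on - x) exactly: spot-check by
        central differences on the exact solution."""
        spec = StepCircuitSpec(3, alpha=(2.0, 3.0, 4.0), beta=1.0, tau=0.0)
        traj, _ = exact_step_trajectory(spec, (0.3, 1.7, 0.6), 40.0, sample_dt=0.02)
        t = traj.times
        for i in range(3):
            x = traj.component(i)
            d = traj.meta["derivs"][:, i]
            num = (x[2:] - x[:-2]) / (t[2] - t[0])
            interior = np.abs(num - d[1:-1])
            # exclude samples straddling a switch event
            ev = [e.time for e in traj.meta["events"]]
            mask = np.ones(len(interior), bool)
            for te in ev:
                mask &= np.abs(t[1:-1] - te) > 2 * (t[1] - t[0])
            assert interior[mask].max() < 5e-4  # O(dt^2) finite-difference floor

    def test_odd_ring_cycles_even_ring_equilibrates(self):
        """tau=0 dichotomy: odd rings with all alpha>1 oscillate, even rings
        settle (no stable cycle)."""
        rng = np.random.default_rng(5)
        for n, expect_cycle in [(3, True), (5, True), (2, False), (4, False)]:
            spec = StepCircuitSpec(n, alpha=tuple(rng.uniform(1.5, 5.0, n)),
                                   beta=1.0, tau=0.0)
            x0 = tuple(rng.uniform(0.2, 1.8, n))
            _, events = exact_step_trajectory(spec, x0, 200.0, sample_dt=1.0)
            late = [e for e in events if e.time > 150.0]
            assert (len(late) > 0) == expect_cycle

    def test_subcritical_alpha_reaches_equilibrium(self):
        spec = StepCircuitSpec(3, alpha=(0.5, 3.0, 4.0), beta=1.0, tau=0.0)
        traj, events = exact_step_trajectory(spec, (0.3, 1.7, 0.6), 80.0)
        assert not [e for e in events if e.time > 60.0]

    def test_nonunit_beta_supported(self):
        spec = StepCircuitSpec(1, alpha=2.0, beta=2.0, tau=1.0)
        traj, _ = exact_step_trajectory(spec, 1.5, 30.0)
        assert np.all(traj.states >= 0.0)
        assert np.all(traj.states <= 2.0 + 1e-12)


class TestCycleFamilies:
    def test_main_branch_is_k0(self):
        fam = countable_family(2.0, 10.0, k_max=4)
        assert fam[0].k == 0
        assert fam[0].T_k == pytest.approx(period_from_delay(2.0, 10.0), abs=1e-12)

    def test_winding_relation_and_consistency(self):
        tau = 10.0
        fam = countable_family(2.0, tau, k_max=6)
        assert len(fam) == 7
        for e in fam:
            assert e.tau_k > 0
            assert e.tau_k + e.k * e.T_k == pytest.approx(tau, abs=1e-10)
            assert e.T_k == pytest.approx(period_from_delay(2.0, e.tau_k), abs=1e-10)

    def test_nonunit_beta_rejected_for_closed_forms(self):
        from ringcycles.piecewise import symmetric_cycle_seed, FamilyEntry

        spec = StepCircuitSpec(3, alpha=2.0, beta=2.0, tau=0.0)
        with pytest.raises(SpecValidationError):
            symmetric_cycle_seed(spec, FamilyEntry(k=0, p=1, tau_k=1.0, T_k=3.0))

    def test_five_ring_two_cycles_when_promoter_strong(self):
        """2*alpha > 5 + sqrt(5) admits both the p=1 and p=2 phase patterns."""
        fam = symmetric_family_nd(4.0, 0.0, 5)
        validated = [e for e in fam if e.validated]
        assert len(validated) >= 2
        assert {e.p for e in validated} >= {1, 2}

    def test_five_ring_single_cycle_when_weak(self):
        fam = symmetric_family_nd(2.0, 0.0, 5)
        validated = [e for e in fam if e.validated]
        assert {(e.p, e.k) for e in validated} == {(2, 0)}

    def test_three_ring_unique_cycle(self):
        fam = symmetric_family_nd(2.0, 0.0, 3)
        validated = [e for e in fam if e.validated]
        assert len(validated) == 1
        assert (validated[0].p, validated[0].k) == (1, 0)

    def test_periods_distinct_across_p_and_k(self):
        fam = symmetric_family_nd(4.0, 1.0, 5, k_max=2)
        periods = [round(e.T_k, 9) for e in fam]
        assert len(periods) == len(set(periods))

    def test_delayed_family_validates(self):
        fam = symmetric_family_nd(4.0, 1.0, 3, k_max=1)
        assert any(e.validated for e in fam)
        for e in fam:
            te = 1.0 + (e.p / 3 - e.k) * e.T_k
            assert te == pytest.approx(e.tau_k, abs=1e-10)
            assert e.T_k == pytest.approx(period_from_delay(4.0, te), abs=1e-9)
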