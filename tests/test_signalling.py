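"""Switch-module kinetics, steady states, bifurcation and trigger semantics.

Independent oracles: brute-force sign scans for roots and folds, and a stiff
ODE solve for the closed-form monostable transient.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cordsim import (TriggerStatus, apoptosis_trigger, bistable_fold_inputs,
                     bistable_rate, bistable_steady_states,
                     calibrate_module_match, effector_rate, monostable_rate,
                     monostable_steady_state, monostable_transient)
from cordsim.signalling import (basal_switch_state, bistable_rate_dR,
                                integrate_switch,
                                monostable_switching_threshold, time_to_kill)


class TestRates:
    def test_monostable_rate_values(self, sig):
        assert monostable_rate(0.0, 0.0, sig) == 0.0
        assert monostable_rate(0.5, sig.monostable.k_h, sig) == pytest.approx(0.0)
        # half-saturation from rest: k * 0.5
        assert monostable_rate(0.0, 1.0, sig) == pytest.approx(0.216)

    def test_monostable_rejects_negative_input(self, sig):
        with pytest.raises(ValueError):
            monostable_rate(0.2, -0.1, sig)

    def test_effector_rate_values(self, sig):
        assert effector_rate(0.0, 0.0, sig) == 0.0
        assert effector_rate(0.0, 1.0, sig) == pytest.approx(3.6)
        # steady state R1* = R/(R + k_r/k_f)
        R = 0.37
        R1 = R / (R + sig.effector.k_r / sig.effector.k_f)
        assert effector_rate(R1, R, sig) == pytest.approx(0.0, abs=1e-14)

    def test_effector_rejects_out_of_range(self, sig):
        with pytest.raises(ValueError):
            effector_rate(1.5, 0.5, sig)

    def test_bistable_rate_values(self, sig):
        b = sig.bistable
        # R = 1: only the saturated deactivation survives, forcing R <= 1
        assert bistable_rate(1.0, 5.0, sig) == pytest.approx(
            -b.V_r / (b.K_m2 + 1.0))
        # R = 0, I = 0: pure basal activation V_f/(K_m1+1)
        assert bistable_rate(0.0, 0.0, sig) == pytest.approx(27.0 / 101.0)
        with pytest.raises(ValueError):
            bistable_rate(0.5, -1.0, sig)

    def test_bistable_rate_derivative(self, sig):
        # finite-difference cross-check of the analytic dR derivative
        R0, I = 0.37, 0.8
        h = 1e-6
        fd = (bistable_rate(R0 + h, I, sig) - bistable_rate(R0 - h, I, sig)) / (2 * h)
        assert bistable_rate_dR(R0, I, sig) == pytest.approx(fd, rel=1e-6)


class TestMonostableSteadyState:
    def test_no_input(self, sig):
        s = monostable_steady_state(0.0, sig)
        assert (s.R, s.R1) == (0.0, 0.0)

    def test_half_saturation(self, sig):
        s = monostable_steady_state(sig.monostable.k_h, sig)
        assert s.R == pytest.approx(0.5)
        assert s.R1 == pytest.approx(0.5 / 0.54, rel=1e-12)  # k_r/k_f = 0.04

    def test_saturating_input(self, sig):
        s = monostable_steady_state(1e6, sig)
        assert s.R == pytest.approx(1.0, abs=1e-12)
        assert s.R1 == pytest.approx(1.0 / 1.04, rel=1e-9)


class TestMonostableTransient:
    def test_pure_decay(self, sig):
        k = sig.monostable.k
        for t in (0.5, 2.0, 10.0):
            assert monostable_transient(lambda w: 0.0, t, sig, R0=0.3) == \
                pytest.approx(0.3 * np.exp(-k * t), rel=1e-9)

    def test_constant_input_limit(self, sig):
        R_inf = monostable_steady_state(2.0, sig).R
        assert monostable_transient(lambda w: 2.0, 60.0, sig) == \
            pytest.approx(R_inf, abs=1e-8)

    @pytest.mark.parametrize("I_fn, breaks", [
        (lambda w: 2.0, ()),
        (lambda w: 1.5 if w < 3.0 else 0.0, (3.0,)),     # rectangular pulse
        (lambda w: 0.8 if 1.0 <= w < 4.0 else 0.1, (1.0, 4.0)),
    ])
    def test_matches_ode_oracle(self, sig, I_fn, breaks):
        """Closed-form convolution vs stiff numerical integration, 1e-6."""
        t_end = 8.0
        closed = monostable_transient(I_fn, t_end, sig, R0=0.1,
                                      breakpoints=breaks)
        edges = [0.0, *breaks, t_end]
        y = np.array([0.1])
        for a, b in zip(edges[:-1], edges[1:]):
            sol = solve_ivp(lambda t, y: [monostable_rate(y[0], I_fn(t), sig)],
                            (a, b), y, method="LSODA", rtol=1e-11, atol=1e-13)
            y = sol.y[:, -1]
        assert closed == pytest.approx(float(y[0]), abs=1e-6)


def _brute_force_roots(I, sig, step=1e-5):
    """Independent oracle: dense sign-change scan of the bistable rate."""
    R = np.arange(0.0, 1.0 + step, step)
    f = bistable_rate(R, I, sig)
    roots = []
    for j in range(len(R) - 1):
        if f[j] == 0.0 or f[j] * f[j + 1] < 0.0:
            roots.append(0.5 * (R[j] + R[j + 1]))
    return roots


class TestBistableSteadyStates:
    def test_basal_has_three_branches(self, sig):
        branches = bistable_steady_states(0.0, sig)
        assert [b.stability for b in branches] == ["stable", "unstable", "stable"]
        assert all(0.0 <= b.R_star <= 1.0 for b in branches)

    def test_high_input_monostable_high(self, sig):
        branches = bistable_steady_states(3.0, sig)
        assert len(branches) == 1
        assert branches[0].stability == "stable"
        assert branches[0].R_star > 0.7

    @pytest.mark.parametrize("I", [0.0, 0.5, 1.0, 1.5, 3.0])
    def test_against_brute_force_scan(self, sig, I):
        roots = [b.R_star for b in bistable_steady_states(I, sig)]
        brute = _brute_force_roots(I, sig)
        assert len(roots) == len(brute)
        np.testing.assert_allclose(roots, brute, atol=1e-5)


class TestFolds:
    def test_upper_fold_location(self, sig):
        rep = bistable_fold_inputs(sig)
        assert rep.is_bistable
        assert rep.upper == pytest.approx(1.0094, abs=2e-3)

    def test_fold_agrees_with_grid_scan(self, sig):
        """Fold bracketed by a brute-force branch-count scan at dI = 1e-4."""
        rep = bistable_fold_inputs(sig)
        I = np.arange(0.95, 1.05, 1e-4)
        counts = np.array([len(bistable_steady_states(x, sig)) for x in I])
        jump = np.flatnonzero(np.diff(counts) != 0)
        assert len(jump) == 1
        assert I[jump[0]] <= rep.upper <= I[jump[0] + 1]

    def test_decoupled_input_has_no_fold(self, sig):
        import dataclasses
        bi = dataclasses.replace(sig.bistable, q=0.0)
        s = dataclasses.replace(sig, bistable=bi)
        rep = bistable_fold_inputs(s)
        assert rep.folds == ()
        assert "monostable for all I" in rep.describe()


class TestTrigger:
    def test_latch_below_threshold(self, sig):
        st0 = TriggerStatus(mode="monostable_latch")
        assert not apoptosis_trigger(0.5, st0, sig).fired

    def test_latch_is_irreversible(self, sig):
        st0 = TriggerStatus(mode="monostable_latch")
        st1 = apoptosis_trigger(0.95, st0, sig, t=3.0)
        assert st1.fired and st1.time_fired == 3.0
        st2 = apoptosis_trigger(0.1, st1, sig, t=5.0)
        assert st2.fired and st2.time_fired == 3.0

    def test_reversible_tracks_threshold(self, sig):
        st0 = TriggerStatus(mode="bistable_reversible")
        st1 = apoptosis_trigger(0.95, st0, sig, t=3.0)
        assert st1.fired
        st2 = apoptosis_trigger(0.1, st1, sig, t=5.0)
        assert not st2.fired


class TestHysteresis:
    def test_step_up_then_down_stays_high(self, sig):
        """I stepped 0 -> 2 -> 0: R remains on the upper branch."""
        R0 = basal_switch_state("bistable", sig).R
        I_fn = lambda t: 2.0 if 5.0 <= t < 25.0 else 0.0
        t, R, _ = integrate_switch("bistable", I_fn, 80.0, sig,
                                   breakpoints=(5.0, 25.0))
        assert abs(R[-1] - R0) > 0.5
        upper = max(b.R_star for b in bistable_steady_states(0.0, sig))
        assert R[-1] == pytest.approx(upper, abs=1e-3)

    def test_pulse_duration_decides_permanence(self, sig):
        """Long enough supra-threshold pulses switch permanently; short do not."""
        R0 = basal_switch_state("bistable", sig).R
        finals = {}
        for dur in (0.3, 5.0):
            I_fn = lambda t, d=dur: 2.0 if t < d else 0.0
            t, R, _ = integrate_switch("bistable", I_fn, 60.0, sig,
                                       breakpoints=(dur,))
            finals[dur] = R[-1]
        assert finals[0.3] == pytest.approx(R0, abs=1e-3)
        assert finals[5.0] - R0 > 0.5


@settings(max_examples=25, deadline=None, derandomize=True)
@given(module=st.sampled_from(["monostable", "bistable"]),
       I=st.floats(0.0, 10.0),
       R0=st.floats(0.0, 1.0),
       R1_0=st.floats(0.0, 1.0))
def test_forward_invariance_of_unit_square(module, I, R0, R1_0):
    """(R, R1) stays in [0,1]^2 from any interior/boundary initial state."""
    sig = __import__("cordsim").default_parameters().signalling
    from cordsim.signalling import SwitchState
    t, R, R1 = integrate_switch(module, lambda w: I, 20.0, sig,
                                y0=SwitchState(R=R0, R1=R1_0))
    assert np.all(R >= -1e-7) and np.all(R <= 1.0 + 1e-7)
    assert np.all(R1 >= -1e-7) and np.all(R1 <= 1.0 + 1e-7)


class TestCalibration:
    def test_default_modules_are_matched(self, sig):
        rep = calibrate_module_match(sig)
        # both switching thresholds sit at I ~ 1
        assert rep.threshold_monostable == pytest.approx(1.0, abs=0.1)
        assert rep.threshold_bistable == pytest.approx(1.0, abs=0.1)
        assert rep.threshold_ratio == pytest.approx(1.0, abs=0.1)
        # comparable (same-hour-scale) times to kill at the reference input
        assert rep.time_monostable == pytest.approx(rep.time_bistable, rel=0.3)
        assert rep.matched

    def test_doubled_hill_constant_is_flagged(self, sig):
        import dataclasses
        mono = dataclasses.replace(sig.monostable, k_h=2.0)
        s = dataclasses.replace(sig, monostable=mono)
        rep = calibrate_module_match(s)
        assert rep.threshold_ratio == pytest.approx(2 * 0.944 / 1.009, rel=0.02)
        assert not rep.matched

    def test_threshold_inversion_formula(self, sig):
        I_star = monostable_switching_threshold(sig)
        s = monostable_steady_state(I_star, sig)
        assert s.R1 == pytest.approx(sig.effector.R1_th, abs=1e-12)

    def test_time_to_kill_below_threshold_is_infinite(self, sig):
        assert time_to_kill("monostable", 0.5, sig, t_max=50.0) == np.inf
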