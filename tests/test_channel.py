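"""Unit and property tests of the two-gate channel model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from hergsim.channel import (ChannelParams, GateState, TauCurve,
                             advance_gates, current, gate_tau, holding_state,
                             nernst_potassium, simulate_sweep,
                             simulate_sweep_mixture, steady_state_activation,
                             steady_state_availability)
from hergsim.variants import calibrate_gmax, simulated_tail_current, \
    variant_params


# --------------------------------------------------------------- steady state

def test_boltzmann_midpoints_exact(wt_params):
    assert steady_state_activation(wt_params.v_half_act, wt_params) == \
        pytest.approx(0.5, abs=1e-12)
    assert steady_state_availability(wt_params.v_half_inact, wt_params) == \
        pytest.approx(0.5, abs=1e-12)


def test_activation_matches_closed_form(wt_params):
    # direct high-precision evaluation of the Boltzmann at +30 mV
    expected = 1.0 / (1.0 + np.exp(-(30.0 - (-2.76)) / 8.50))
    assert steady_state_activation(30.0, wt_params) == \
        pytest.approx(expected, abs=1e-9)


@given(v1=st.floats(-120, 59), dv=st.floats(0.01, 60))
@settings(max_examples=50, deadline=None)
def test_steady_state_monotonicity(v1, dv):
    p = variant_params("WT")
    v2 = min(v1 + dv, 60.0)
    assert steady_state_activation(v2, p) > steady_state_activation(v1, p)
    assert steady_state_availability(v2, p) < steady_state_availability(v1, p)


def test_availability_asymptotes(wt_params):
    assert steady_state_availability(1e4, wt_params) == pytest.approx(0, abs=1e-12)
    assert steady_state_availability(-1e4, wt_params) == pytest.approx(1, abs=1e-12)


# ------------------------------------------------------------------ gate_tau

def test_gate_tau_direction_aware(wt_params):
    # depolarizing (a below target) uses the activation curve
    assert gate_tau(30.0, "activation", wt_params, value=0.0) == \
        pytest.approx(164.4, rel=1e-6)
    # repolarizing uses the deactivation curve
    assert gate_tau(-90.0, "activation", wt_params, value=1.0) == \
        pytest.approx(122.1, rel=1e-6)
    assert gate_tau(0.0, "availability", wt_params, value=1.0) == \
        pytest.approx(5.84, rel=1e-6)
    assert gate_tau(-20.0, "availability", wt_params, value=0.0) == \
        pytest.approx(4.63, rel=1e-6)


def test_gate_tau_out_of_domain(wt_params):
    with pytest.raises(ValueError, match="outside the model domain"):
        gate_tau(-200.0, "activation", wt_params, value=0.0)


# ------------------------------------------------------------- advance_gates

def test_advance_identity_and_fixed_point(wt_params):
    s = GateState(a=0.3, h=0.7)
    assert advance_gates(s, 0.0, 0.0, wt_params) == s
    far = advance_gates(s, 0.0, 1e9, wt_params)
    assert far.a == pytest.approx(steady_state_activation(0.0, wt_params), abs=1e-12)
    assert far.h == pytest.approx(steady_state_availability(0.0, wt_params), abs=1e-12)


@given(a=st.floats(0, 1), h=st.floats(0, 1), v=st.floats(-120, 60),
       dt1=st.floats(0.001, 500), dt2=st.floats(0.001, 500))
@settings(max_examples=100, deadline=None)
def test_advance_composition_law(a, h, v, dt1, dt2):
    """Advancing dt1 then dt2 equals one step of dt1+dt2 at constant V."""
    p = variant_params("WT")
    s = GateState(a=a, h=h)
    two = advance_gates(advance_gates(s, v, dt1, p), v, dt2, p)
    one = advance_gates(s, v, dt1 + dt2, p)
    assert two.a == pytest.approx(one.a, abs=1e-12)
    assert two.h == pytest.approx(one.h, abs=1e-12)
    assert 0.0 <= two.a <= 1.0 and 0.0 <= two.h <= 1.0


def test_advance_substep_equivalence(wt_params):
    """One 1-ms step equals 1000 steps of 1 us at constant voltage."""
    s = GateState(a=0.2, h=0.9)
    one = advance_gates(s, 10.0, 1.0, wt_params)
    many = s
    for _ in range(1000):
        many = advance_gates(many, 10.0, 0.001, wt_params)
    assert many.a == pytest.approx(one.a, abs=1e-9)
    assert many.h == pytest.approx(one.h, abs=1e-9)


def test_advance_negative_dt(wt_params):
    with pytest.raises(ValueError):
        advance_gates(GateState(0.5, 0.5), 0.0, -1.0, wt_params)


# ------------------------------------------------------------------- current

def test_current_reversal_zero_and_linearity(wt_params):
    s = GateState(a=0.4, h=0.6)
    assert current(s, wt_params.e_rev, wt_params) == 0.0
    assert current(GateState(0.0, 0.9), 0.0, wt_params) == 0.0
    assert current(GateState(0.9, 0.0), 0.0, wt_params) == 0.0
    doubled = wt_params.with_gmax(2.0 * wt_params.g_max)
    assert current(s, 0.0, doubled) == pytest.approx(
        2.0 * current(s, 0.0, wt_params), rel=1e-12)
    # sign follows the driving force
    assert current(s, wt_params.e_rev + 10, wt_params) > 0
    assert current(s, wt_params.e_rev - 10, wt_params) < 0


# ------------------------------------------------------------- simulate_sweep

def test_sweep_errors(wt_params):
    s = holding_state(-80.0, wt_params)
    with pytest.raises(ValueError, match="empty"):
        simulate_sweep([], wt_params, s, 1.0)
    with pytest.raises(ValueError):
        simulate_sweep([(0.0, -80.0)], wt_params, s, 1.0)
    with pytest.raises(ValueError):
        simulate_sweep([(10.0, -80.0)], wt_params, s, 0.0)


def test_sweep_steady_holding_current(wt_params):
    """Long holding at -80 mV settles to g*a_inf*h_inf*(V - E_rev)."""
    s = holding_state(-80.0, wt_params)
    rec, _ = simulate_sweep([(1000.0, -80.0)], wt_params, s, 1.0)
    expected = (wt_params.g_max
                * steady_state_activation(-80.0, wt_params)
                * steady_state_availability(-80.0, wt_params)
                * (-80.0 - wt_params.e_rev))
    assert rec.i_pa[-1] == pytest.approx(expected, rel=1e-12)


def _euler_oracle(segments, params, state, sample_interval, dt=0.001):
    """1-us explicit-Euler integration with the same direction-aware
    time-constant convention; independent of the exponential closed
    form.  At constant voltage the Euler recursion
    g <- g + dt*(g_inf - g)/tau has the exact solution
    g_n = g_inf - (g_inf - g_0)*(1 - dt/tau)**n, which is evaluated at
    the sample times instead of looping a million steps per segment."""
    total = sum(d for d, _ in segments)
    n_samples = int(np.floor(total / sample_interval + 1e-9)) + 1
    t_samp = np.arange(n_samples) * sample_interval
    i_out = np.empty(n_samples)
    a, h = state.a, state.h
    t0 = 0.0
    for d, v in segments:
        a_inf = float(steady_state_activation(v, params))
        h_inf = float(steady_state_availability(v, params))
        ta = float(params.tau_act_curve(v) if a_inf > a
                   else params.tau_deact_curve(v))
        th = float(params.tau_rec_curve(v) if h_inf > h
                   else params.tau_inact_curve(v))
        sel = (t_samp >= t0 - 1e-9) & (t_samp < t0 + d - 1e-9)
        n_step = np.round((t_samp[sel] - t0) / dt).astype(np.int64)
        a_t = a_inf - (a_inf - a) * (1.0 - dt / ta) ** n_step
        h_t = h_inf - (h_inf - h) * (1.0 - dt / th) ** n_step
        i_out[sel] = params.g_max * a_t * h_t * (v - params.e_rev)
        n_seg = int(round(d / dt))
        a = a_inf - (a_inf - a) * (1.0 - dt / ta) ** n_seg
        h = h_inf - (h_inf - h) * (1.0 - dt / th) ** n_seg
        t0 += d
    i_out[-1] = params.g_max * a * h * (segments[-1][1] - params.e_rev)
    return i_out


@pytest.mark.parametrize("proto_name,label", [
    ("activation", 30), ("activation", -20),
    ("deactivation", -90), ("inactivation_tau", 0),
    ("ss_inactivation", -40), ("recovery", -80),
])
def test_sweep_against_euler_oracle(protocols, wt_params, proto_name, label):
    """Closed-form sweep agrees with a 1-us explicit-Euler integration
    to within 0.1% of the dynamic range on every protocol family."""
    segs = protocols[proto_name].sweeps[label]
    s = holding_state(-80.0, wt_params)
    rec, _ = simulate_sweep(segs, wt_params, s, 5.0)
    oracle = _euler_oracle(segs, wt_params, s, 5.0)
    n = min(rec.i_pa.size, oracle.size)
    scale = np.abs(oracle).max()
    assert np.max(np.abs(rec.i_pa[:n] - oracle[:n])) < 1e-3 * scale


def test_sweep_against_ode_solver(protocols, wt_params):
    """Independent stiff-ODE integration of the two-gate system."""
    segs = protocols["activation"].sweeps[30]
    s = holding_state(-80.0, wt_params)
    rec, _ = simulate_sweep(segs, wt_params, s, 10.0)

    bounds = np.cumsum([d for d, _ in segs])

    def rhs(t, y):
        seg = min(int(np.searchsorted(bounds, t, side="right")), len(segs) - 1)
        v = segs[seg][1]
        a_inf = float(steady_state_activation(v, wt_params))
        h_inf = float(steady_state_availability(v, wt_params))
        ta = (wt_params.tau_act_curve(v) if a_inf > y[0]
              else wt_params.tau_deact_curve(v))
        th = (wt_params.tau_rec_curve(v) if h_inf > y[1]
              else wt_params.tau_inact_curve(v))
        return [(a_inf - y[0]) / ta, (h_inf - y[1]) / th]

    sol = solve_ivp(rhs, (0.0, bounds[-1]), [s.a, s.h], method="LSODA",
                    t_eval=rec.t_ms, rtol=1e-10, atol=1e-12, max_step=5.0)
    v_of_t = rec.v_mv
    i_ode = wt_params.g_max * sol.y[0] * sol.y[1] * (v_of_t - wt_params.e_rev)
    scale = np.abs(rec.i_pa).max()
    assert np.max(np.abs(rec.i_pa - i_ode)) < 1e-3 * scale


# ------------------------------------------------------- mixture & calibration

def test_mixture_is_mean_of_components(protocols):
    """1:1 coexpression at equal g_max = arithmetic mean of pure traces."""
    p1 = variant_params("S1021Qfs*98").with_gmax(10.0)
    p2 = variant_params("A228V").with_gmax(10.0)
    segs = protocols["activation"].sweeps[30]
    states = [holding_state(-80.0, p) for p in (p1, p2)]
    mix, _ = simulate_sweep_mixture(segs, [p1, p2], [0.5, 0.5], states, 2.0)
    r1, _ = simulate_sweep(segs, p1, states[0], 2.0)
    r2, _ = simulate_sweep(segs, p2, states[1], 2.0)
    np.testing.assert_allclose(mix.i_pa, 0.5 * (r1.i_pa + r2.i_pa),
                               rtol=0, atol=1e-12)


def test_calibrate_gmax(wt_params):
    cal = calibrate_gmax(wt_params, 362.7, 30.0)
    assert simulated_tail_current(cal, 30.0) == pytest.approx(362.7, abs=1e-6)
    assert calibrate_gmax(wt_params, 0.0, 30.0).g_max == 0.0
    twice = calibrate_gmax(wt_params, 2 * 362.7, 30.0)
    assert twice.g_max == pytest.approx(2.0 * cal.g_max, rel=1e-12)


# --------------------------------------------------------------- serialization

def test_params_json_round_trip(wt_params):
    d = wt_params.to_dict()
    back = ChannelParams.from_dict(d)
    assert back.v_half_act == wt_params.v_half_act
    assert back.tau_rec_curve == wt_params.tau_rec_curve
    assert back.g_max == wt_params.g_max
    with pytest.raises(ValueError, match="schema"):
        ChannelParams.from_dict({**d, "schema": "bogus/9"})


def test_tau_curve_clamps_and_validates():
    c = TauCurve([-80.0, 0.0], [1.0, 10.0])
    assert c(-200.0) == pytest.approx(c(-80.0))
    assert c(50.0) == pytest.approx(c(0.0))
    with pytest.raises(ValueError):
        TauCurve([0.0, -10.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        TauCurve([0.0, 10.0], [1.0, -1.0])


def test_nernst_default():
    # Tyrode/pipette solutions at 37 degC put E_K near -87 mV
    assert nernst_potassium() == pytest.approx(-87.1, abs=0.2)
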