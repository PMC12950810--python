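"""Two-gate Hodgkin-Huxley model of the Kv11.1 (hERG) current.

The channel is described by an activation gate ``a`` and an availability
gate ``h`` (1 - inactivation), each relaxing mono-exponentially toward a
Boltzmann steady state.  Under a piecewise-constant command voltage the
gate trajectories have a closed form, so voltage-clamp sweeps can be
synthesized exactly (no ODE solver error).

Current follows the ohmic form ``I = g_max * a * h * (V - E_rev)``;
inward rectification of the macroscopic current is emergent from the
voltage dependence of ``h``.

Units: time ms, voltage mV, current pA, conductance nS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "VOLTAGE_DOMAIN",
    "TauCurve",
    "ChannelParams",
    "GateState",
    "SweepRecording",
    "steady_state_activation",
    "steady_state_availability",
    "gate_tau",
    "advance_gates",
    "current",
    "simulate_sweep",
    "simulate_sweep_mixture",
    "holding_state",
    "nernst_potassium",
]

#: Command-voltage range covered by the stimulation protocols (mV).
VOLTAGE_DOMAIN = (-120.0, 60.0)

GateName = Literal["activation", "availability"]


def nernst_potassium(k_out_mm: float = 4.8, k_in_mm: float = 125.0,
                     temperature_k: float = 310.15) -> float:
    """K+ reversal potential (mV) from the Nernst equation.

    Defaults correspond to a Tyrode bath (4.8 mM K+) against a
    K-aspartate pipette solution (~125 mM K+) at 37 degC.
    """
    R, F = 8314.462, 96485.332
    return R * temperature_k / F * np.log(k_out_mm / k_in_mm)


class TauCurve:
    """Monotone interpolant of a voltage-dependent time constant.

    Interpolation is shape-preserving (PCHIP) in ``log tau`` over the
    anchor voltages and clamped to the end anchors outside their range,
    which keeps tau positive everywhere on the protocol domain.
    """

    def __init__(self, voltages_mv: Sequence[float], taus_ms: Sequence[float]):
        v = np.asarray(voltages_mv, dtype=float)
        tau = np.asarray(taus_ms, dtype=float)
        if v.ndim != 1 or v.size < 1 or v.size != tau.size:
            raise ValueError("anchor arrays must be 1-D and equally sized")
        if np.any(np.diff(v) <= 0):
            raise ValueError("anchor voltages must be strictly increasing")
        if np.any(tau <= 0):
            raise ValueError("time constants must be positive")
        self.anchors_v = v
        self.anchors_tau = tau
        if v.size == 1:
            self._interp = None
        else:
            self._interp = PchipInterpolator(v, np.log(tau))

    def __call__(self, v_mv):
        v = np.clip(v_mv, self.anchors_v[0], self.anchors_v[-1])
        if self._interp is None:
            return np.full_like(np.asarray(v, dtype=float), self.anchors_tau[0]) \
                if np.ndim(v) else float(self.anchors_tau[0])
        out = np.exp(self._interp(v))
        return float(out) if np.ndim(v_mv) == 0 else out

    def scaled(self, factor: float) -> "TauCurve":
        return TauCurve(self.anchors_v, self.anchors_tau * factor)

    def to_dict(self) -> dict:
        return {"v_mv": self.anchors_v.tolist(), "tau_ms": self.anchors_tau.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TauCurve":
        return cls(d["v_mv"], d["tau_ms"])

    def __eq__(self, other):
        return (isinstance(other, TauCurve)
                and np.array_equal(self.anchors_v, other.anchors_v)
                and np.array_equal(self.anchors_tau, other.anchors_tau))


@dataclass(frozen=True)
class ChannelParams:
    """Full kinetic description of one Kv11.1 variant."""

    v_half_act: float          # mV, half-maximal activation
    k_act: float               # mV, activation slope factor (> 0)
    v_half_inact: float        # mV, half-maximal inactivation
    k_inact: float             # mV, inactivation slope factor (> 0)
    tau_act_curve: TauCurve    # ms, activation (depolarizing a-gate)
    tau_deact_curve: TauCurve  # ms, deactivation (repolarizing a-gate)
    tau_inact_curve: TauCurve  # ms, inactivation (h decreasing)
    tau_rec_curve: TauCurve    # ms, recovery from inactivation (h increasing)
    g_max: float = 1.0         # nS
    e_rev: float = field(default_factory=nernst_potassium)  # mV

    def __post_init__(self):
        if self.k_act <= 0 or self.k_inact <= 0:
            raise ValueError("slope factors must be positive")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        grid = np.linspace(*VOLTAGE_DOMAIN, 181)
        for name in ("tau_act_curve", "tau_deact_curve",
                     "tau_inact_curve", "tau_rec_curve"):
            if np.any(getattr(self, name)(grid) <= 0):
                raise ValueError(f"{name} must be positive on the protocol domain")

    def with_gmax(self, g_max: float) -> "ChannelParams":
        return replace(self, g_max=g_max)

    def to_dict(self) -> dict:
        return {
            "schema": "hergsim.channel_params/1",
            "v_half_act": self.v_half_act, "k_act": self.k_act,
            "v_half_inact": self.v_half_inact, "k_inact": self.k_inact,
            "tau_act_curve": self.tau_act_curve.to_dict(),
            "tau_deact_curve": self.tau_deact_curve.to_dict(),
            "tau_inact_curve": self.tau_inact_curve.to_dict(),
            "tau_rec_curve": self.tau_rec_curve.to_dict(),
            "g_max": self.g_max, "e_rev": self.e_rev,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelParams":
        schema = d.get("schema", "hergsim.channel_params/1")
        if schema != "hergsim.channel_params/1":
            raise ValueError(f"unsupported channel-params schema: {schema!r}")
        return cls(
            v_half_act=d["v_half_act"], k_act=d["k_act"],
            v_half_inact=d["v_half_inact"], k_inact=d["k_inact"],
            tau_act_curve=TauCurve.from_dict(d["tau_act_curve"]),
            tau_deact_curve=TauCurve.from_dict(d["tau_deact_curve"]),
            tau_inact_curve=TauCurve.from_dict(d["tau_inact_curve"]),
            tau_rec_curve=TauCurve.from_dict(d["tau_rec_curve"]),
            g_max=d.get("g_max", 1.0), e_rev=d.get("e_rev", nernst_potassium()),
        )


@dataclass(frozen=True)
class GateState:
    """Instantaneous gate values; both dimensionless fractions in [0, 1]."""

    a: float
    h: float

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError(f"gate values out of [0, 1]: a={self.a}, h={self.h}")


@dataclass
class SweepRecording:
    """One uniformly sampled voltage-clamp sweep (simulated or loaded)."""

    t_ms: np.ndarray
    i_pa: np.ndarray
    v_mv: np.ndarray                       # command voltage at each sample
    segments: tuple                        # ((duration_ms, voltage_mv), ...)
    label: float | str | None = None      # e.g. the varied sweep voltage

    @property
    def sample_interval(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    def segment_slice(self, index: int) -> slice:
        """Samples belonging to segment ``index`` (boundary sample goes to
        the *later* segment, i.e. it carries the post-step voltage)."""
        starts = np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])
        dt = self.sample_interval
        lo = int(np.ceil(starts[index] / dt - 1e-9))
        hi = int(np.ceil(starts[index + 1] / dt - 1e-9))
        return slice(lo, min(hi, self.t_ms.size))


def steady_state_activation(v_mv, params: ChannelParams):
    """Boltzmann steady-state activation a_inf(V); strictly increasing."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v_mv, dtype=float) - params.v_half_act)
                               / params.k_act))


def steady_state_availability(v_mv, params: ChannelParams):
    """Boltzmann steady-state availability h_inf(V); strictly decreasing."""
    return 1.0 / (1.0 + np.exp((np.asarray(v_mv, dtype=float) - params.v_half_inact)
                               / params.k_inact))


def _check_domain(v_mv: float):
    lo, hi = VOLTAGE_DOMAIN
    if not (lo <= v_mv <= hi):
        raise ValueError(
            f"voltage {v_mv} mV outside the model domain [{lo}, {hi}] mV")


def gate_tau(v_mv: float, gate: GateName, params: ChannelParams,
             value: float) -> float:
    """Direction-aware time constant at voltage ``v_mv``.

    The a-gate relaxes with tau_act when activating (a_inf > a) and
    tau_deact otherwise; the h-gate uses tau_inact when inactivating
    (h_inf < h) and tau_rec when recovering.  ``value`` is the current
    gate value, which fixes the direction of relaxation.
    """
    _check_domain(v_mv)
    if gate == "activation":
        target = steady_state_activation(v_mv, params)
        curve = params.tau_act_curve if target > value else params.tau_deact_curve
    elif gate == "availability":
        target = steady_state_availability(v_mv, params)
        curve = params.tau_rec_curve if target > value else params.tau_inact_curve
    else:
        raise ValueError(f"unknown gate {gate!r}")
    return float(curve(v_mv))


def advance_gates(state: GateState, v_mv: float, dt_ms: float,
                  params: ChannelParams) -> GateState:
    """Exact exponential relaxation of both gates over ``dt_ms`` at
    constant voltage: g(t+dt) = g_inf - (g_inf - g) * exp(-dt/tau)."""
    if dt_ms < 0:
        raise ValueError("dt must be non-negative")
    a_inf = float(steady_state_activation(v_mv, params))
    h_inf = float(steady_state_availability(v_mv, params))
    tau_a = gate_tau(v_mv, "activation", params, state.a)
    tau_h = gate_tau(v_mv, "availability", params, state.h)
    a = a_inf - (a_inf - state.a) * np.exp(-dt_ms / tau_a)
    h = h_inf - (h_inf - state.h) * np.exp(-dt_ms / tau_h)
    return GateState(a=float(a), h=float(h))


def current(state: GateState, v_mv: float, params: ChannelParams) -> float:
    """Ohmic current I = g_max * a * h * (V - E_rev) in pA (nS * mV)."""
    return params.g_max * state.a * state.h * (v_mv - params.e_rev)


def holding_state(v_mv: float, params: ChannelParams) -> GateState:
    """Gate state after indefinitely long holding at ``v_mv``."""
    return GateState(a=float(steady_state_activation(v_mv, params)),
                     h=float(steady_state_availability(v_mv, params)))


def simulate_sweep(segments: Sequence[tuple], params: ChannelParams,
                   initial_state: GateState, sample_interval: float,
                   label=None) -> tuple[SweepRecording, GateState]:
    """Simulate one sweep of a piecewise-constant voltage schedule.

    ``segments`` is a sequence of (duration_ms, voltage_mv) pairs.  The
    gate update uses the closed-form relaxation segment by segment; the
    current trace is sampled uniformly from sweep start, with a sample
    on a step boundary carrying the post-step voltage.  Returns the
    recording and the gate state at the end of the last segment.
    """
    segments = tuple((float(d), float(v)) for d, v in segments)
    if not segments:
        raise ValueError("empty voltage schedule")
    if any(d <= 0 for d, _ in segments):
        raise ValueError("segment durations must be positive")
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")

    total = sum(d for d, _ in segments)
    n = int(np.floor(total / sample_interval + 1e-9)) + 1
    t = np.arange(n) * sample_interval
    i_out = np.empty(n)
    v_out = np.empty(n)

    a, h = initial_state.a, initial_state.h
    t0 = 0.0
    for d, v in segments:
        a_inf = float(steady_state_activation(v, params))
        h_inf = float(steady_state_availability(v, params))
        tau_a = gate_tau(v, "activation", params, a)
        tau_h = gate_tau(v, "availability", params, h)
        lo = int(np.ceil((t0 - 1e-9) / sample_interval))
        hi = int(np.ceil((t0 + d - 1e-9) / sample_interval))
        idx = slice(lo, min(hi, n))
        trel = t[idx] - t0
        a_t = a_inf - (a_inf - a) * np.exp(-trel / tau_a)
        h_t = h_inf - (h_inf - h) * np.exp(-trel / tau_h)
        i_out[idx] = params.g_max * a_t * h_t * (v - params.e_rev)
        v_out[idx] = v
        a = a_inf - (a_inf - a) * np.exp(-d / tau_a)
        h = h_inf - (h_inf - h) * np.exp(-d / tau_h)
        t0 += d
    # final sample sits exactly at the end of the last segment
    if hi >= n - 1:
        a_end = GateState(a=min(max(a, 0.0), 1.0), h=min(max(h, 0.0), 1.0))
        i_out[-1] = current(a_end, segments[-1][1], params)
        v_out[-1] = segments[-1][1]
    rec = SweepRecording(t_ms=t, i_pa=i_out, v_mv=v_out,
                         segments=segments, label=label)
    return rec, GateState(a=min(max(a, 0.0), 1.0), h=min(max(h, 0.0), 1.0))


def simulate_sweep_mixture(segments, components: Sequence[ChannelParams],
                           weights: Sequence[float], initial_states,
                           sample_interval: float, label=None):
    """Sweep of a mixed channel population (e.g. 1:1 coexpression).

    Each component gates independently; because the current is linear in
    conductance, the mixture trace is the weighted sum of the pure
    component traces.  Returns (recording, list of final states).
    """
    if len(components) != len(weights) or len(components) != len(initial_states):
        raise ValueError("components, weights and initial_states must align")
    recs, finals = [], []
    for p, s in zip(components, initial_states):
        r, f = simulate_sweep(segments, p, s, sample_interval, label=label)
        recs.append(r)
        finals.append(f)
    i_mix = sum(w * r.i_pa for w, r in zip(weights, recs))
    rec = SweepRecording(t_ms=recs[0].t_ms, i_pa=i_mix, v_mv=recs[0].v_mv,
                         segments=recs[0].segments, label=label)
    return rec, finals
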