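"""Packaged kinetic parameter sets for the measured channel populations.

The four groups are the wild-type channel (WT), the C-terminal
frameshift S1021Qfs*98, the benign N-terminal missense A228V, and the
1:1 coexpression S1021Qfs*98/A228V emulating the compound-heterozygous
state.  Each group's parameters are the measured medians; the maximal
conductance is calibrated so that the simulated activation-protocol
tail current at the anchored prepulse voltage reproduces the measured
median tail amplitude.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .channel import ChannelParams, holding_state, simulate_sweep
from .protocols import HOLDING_MV, builtin_protocols

GROUPS = ("WT", "S1021Qfs*98", "A228V", "S1021Qfs*98/A228V")

__all__ = ["GROUPS", "variant_params", "variant_metadata", "calibrate_gmax",
           "simulated_tail_current"]


@lru_cache(maxsize=1)
def _raw() -> dict:
    with resources.files("hergsim.data").joinpath("variants.json").open() as fh:
        return json.load(fh)


def variant_metadata(group: str) -> dict:
    """Raw fixture entry for a group (kinetics, tail target, C_m/R_a)."""
    groups = _raw()["groups"]
    if group not in groups:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
    return groups[group]


def simulated_tail_current(params: ChannelParams, prepulse_mv: float,
                           sample_interval: float = 0.1,
                           tail_window_ms: float = 100.0) -> float:
    """Peak tail current (signed extremum) at the start of the second
    pulse of the activation protocol, after equilibration at -80 mV."""
    proto = builtin_protocols()["activation"]
    if prepulse_mv not in proto.sweeps:
        raise ValueError(f"no activation sweep at {prepulse_mv} mV")
    rec, _ = simulate_sweep(proto.sweeps[prepulse_mv], params,
                            holding_state(HOLDING_MV, params),
                            sample_interval, label=prepulse_mv)
    sl = rec.segment_slice(proto.analysis_windows["tail"])
    n = min(int(round(tail_window_ms / sample_interval)) + 1,
            sl.stop - sl.start)
    window = rec.i_pa[sl.start:sl.start + n]
    return float(window[int(abs(window).argmax())])


def calibrate_gmax(params: ChannelParams, target_tail_pa: float,
                   at_voltage_mv: float = 30.0) -> ChannelParams:
    """Scale g_max so the activation-protocol tail at ``at_voltage_mv``
    equals ``target_tail_pa`` (exact: the current is linear in g_max)."""
    if target_tail_pa < 0:
        raise ValueError("target tail current must be non-negative")
    unit = params.with_gmax(1.0)
    tail = simulated_tail_current(unit, at_voltage_mv)
    if tail == 0.0:
        raise ValueError("unit-conductance tail current is zero; "
                         "cannot calibrate g_max")
    return params.with_gmax(target_tail_pa / tail)


@lru_cache(maxsize=None)
def variant_params(group: str, calibrated: bool = True) -> ChannelParams:
    """ChannelParams for one group; by default g_max is calibrated to
    the group's measured median tail current."""
    meta = variant_metadata(group)
    params = ChannelParams.from_dict({k: meta[k] for k in (
        "v_half_act", "k_act", "v_half_inact", "k_inact",
        "tau_act_curve", "tau_deact_curve", "tau_inact_curve",
        "tau_rec_curve")})
    if calibrated:
        t = meta["tail_target"]
        params = calibrate_gmax(params, t["i_pa"], t["v_mv"])
    return params
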