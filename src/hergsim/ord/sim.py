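"""Pacing protocols: baseline, acute hypokalemia, beta-adrenergic
stimulation with rate increase."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import OrdConfig
from .metrics import EadEvent, apd90, cat_amplitude, detect_eads
from .model import initial_state, run_segment

__all__ = ["OrdResult", "pace_to_steady_state", "run_paced",
           "hypokalemia_protocol", "beta_as_protocol"]


@dataclass
class OrdResult:
    """Recorded traces and per-beat metrics of one simulation."""

    t_ms: np.ndarray
    v_mv: np.ndarray
    cai_mm: np.ndarray
    beat_starts_ms: np.ndarray
    apd90_ms: list                 # per recorded beat; NaN = failed repol.
    cat_amplitude_mm: list
    diastolic_v_mv: list
    ead_events: list               # of EadEvent
    beats_paced: int               # pre-beats before the recorded window
    converged: bool                # beat-to-beat tolerance reached
    final_state: np.ndarray = field(repr=False, default=None)

    @property
    def first_ead_time_ms(self) -> float | None:
        return self.ead_events[0].time_ms if self.ead_events else None

    @property
    def ead_beats(self) -> list[int]:
        return sorted({e.beat for e in self.ead_events})


def _check_finite(y: np.ndarray, where: str) -> None:
    if not np.all(np.isfinite(y)):
        from .model import STATE_NAMES
        bad = [STATE_NAMES[i] for i in np.nonzero(~np.isfinite(y))[0]]
        raise FloatingPointError(f"non-finite state after {where}: {bad}")


def pace_to_steady_state(config: OrdConfig, y0: np.ndarray | None = None,
                         params: np.ndarray | None = None
                         ) -> tuple[np.ndarray, int, bool]:
    """Pace until the beat-to-beat relative L2 state change drops below
    the configured tolerance or ``n_beats`` is reached.

    Returns (state, beats run, converged flag).
    """
    y = initial_state() if y0 is None else np.array(y0, dtype=float)
    p = config.params() if params is None else params
    empty = np.empty((0, 2))
    prev = y.copy()
    converged = False
    beats = 0
    for b in range(config.n_beats):
        run_segment(y, config.cycle_length, config.dt, p, True, empty, 1)
        beats = b + 1
        if b % 10 == 9:
            _check_finite(y, f"beat {beats}")
        diff = np.sqrt(np.mean(((y - prev) / (np.abs(prev) + 1e-9)) ** 2))
        if diff < config.convergence_tol:
            converged = True
            break
        prev[:] = y
    _check_finite(y, f"beat {beats}")
    return y, beats, converged


def _record_beats(y: np.ndarray, config: OrdConfig, n_beats: int,
                  params: np.ndarray | None = None,
                  cycle_length: float | None = None):
    """Record ``n_beats`` paced beats from state ``y`` (updated in place)."""
    p = config.params() if params is None else params
    cl = config.cycle_length if cycle_length is None else cycle_length
    stride = max(1, int(round(config.record_interval / config.dt)))
    per_beat = int(round(cl / config.dt)) // stride + 1
    rec = np.empty((per_beat, 2))
    t_all, v_all, cai_all, starts = [], [], [], []
    t0 = 0.0
    for b in range(n_beats):
        n = run_segment(y, cl, config.dt, p, True, rec, stride)
        t_all.append(t0 + np.arange(n) * config.dt * stride)
        v_all.append(rec[:n, 0].copy())
        cai_all.append(rec[:n, 1].copy())
        starts.append(t0)
        t0 += cl
        if b % 10 == 9:
            _check_finite(y, f"recorded beat {b + 1}")
    _check_finite(y, "recording end")
    return (np.concatenate(t_all), np.concatenate(v_all),
            np.concatenate(cai_all), np.asarray(starts))


def _metrics(t, v, cai, starts, config: OrdConfig) -> dict:
    apds, cats, dias = [], [], []
    bounds = np.concatenate([starts, [t[-1] + config.record_interval]])
    for b in range(starts.size):
        lo = int(np.searchsorted(t, bounds[b]))
        hi = int(np.searchsorted(t, bounds[b + 1]))
        try:
            apds.append(apd90(t[lo:hi], v[lo:hi]))
        except ValueError:
            apds.append(float("nan"))
        cats.append(cat_amplitude(cai[lo:hi]))
        dias.append(float(v[lo]))
    eads = detect_eads(t, v, starts, delta_mv=config.ead_delta_mv,
                       floor_mv=config.ead_floor_mv,
                       blank_ms=config.ead_blank_ms)
    return {"apd90_ms": apds, "cat_amplitude_mm": cats,
            "diastolic_v_mv": dias, "ead_events": eads}


def run_paced(config: OrdConfig, record_beats: int = 2,
              y0: np.ndarray | None = None) -> OrdResult:
    """Pace to steady state at the configured cycle length, then record
    the final ``record_beats`` beats with metrics."""
    y, beats, converged = pace_to_steady_state(config, y0=y0)
    t, v, cai, starts = _record_beats(y, config, record_beats)
    m = _metrics(t, v, cai, starts, config)
    return OrdResult(t_ms=t, v_mv=v, cai_mm=cai, beat_starts_ms=starts,
                     beats_paced=beats, converged=converged,
                     final_state=y, **m)


def hypokalemia_protocol(config: OrdConfig, k_o_low: float = 3.0,
                         post_beats: int = 30,
                         steady_state: np.ndarray | None = None,
                         stim_duration_low_k: float = 1.0) -> OrdResult:
    """Acute extracellular K+ drop at a stimulus boundary.

    The cell is paced to steady state at the configured [K+]e (5.4 mM
    baseline), then [K+]e switches instantaneously to ``k_o_low`` and
    pacing continues for ``post_beats`` recorded beats.

    The K+ drop hyperpolarizes the resting membrane by ~15 mV (it
    follows E_K); ``stim_duration_low_k`` lengthens the stimulus after
    the switch so pacing stays suprathreshold, mimicking suprathreshold
    field stimulation at constant amplitude.
    """
    if steady_state is None:
        y, beats, converged = pace_to_steady_state(config)
    else:
        y, beats, converged = np.array(steady_state, dtype=float), 0, True
    low = config.replace(k_o=k_o_low,
                         stim_duration=stim_duration_low_k)
    t, v, cai, starts = _record_beats(y, low, post_beats)
    m = _metrics(t, v, cai, starts, low)
    return OrdResult(t_ms=t, v_mv=v, cai_mm=cai, beat_starts_ms=starts,
                     beats_paced=beats, converged=converged,
                     final_state=y, **m)


def beta_as_protocol(config: OrdConfig, fast_cycle_length: float = 400.0,
                     duration_ms: float = 60000.0,
                     steady_state: np.ndarray | None = None) -> OrdResult:
    """Beta-adrenergic stimulation with a simultaneous rate increase.

    From the 1 Hz non-stimulated steady state, the isoproterenol effect
    set switches on and the cycle length drops to ``fast_cycle_length``
    (2.5 Hz default); the run covers at least ``duration_ms``.  EAD
    times are measured from the switch.
    """
    base = config.replace(beta_as=False)
    if steady_state is None:
        y, beats, converged = pace_to_steady_state(base)
    else:
        y, beats, converged = np.array(steady_state, dtype=float), 0, True
    iso = config.replace(beta_as=True, cycle_length=fast_cycle_length)
    n_beats = int(np.ceil(duration_ms / fast_cycle_length))
    t, v, cai, starts = _record_beats(y, iso, n_beats)
    m = _metrics(t, v, cai, starts, iso)
    return OrdResult(t_ms=t, v_mv=v, cai_mm=cai, beat_starts_ms=starts,
                     beats_paced=beats, converged=converged,
                     final_state=y, **m)
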