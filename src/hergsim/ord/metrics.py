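"""Action-potential and Ca2+-transient metrics.

APD_90 is measured from the maximal upstroke velocity to the
(interpolated) first crossing of V_rest + 0.1 * (V_peak - V_rest),
where V_rest is the voltage immediately before the stimulus.  An early
afterdepolarization (EAD) is a local voltage minimum followed by a
local maximum with a rise of at least ``delta_mv``, occurring after
the AP peak and before terminal repolarization below ``floor_mv``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["apd90", "detect_eads", "EadEvent", "cat_amplitude"]


@dataclass(frozen=True)
class EadEvent:
    time_ms: float   # absolute time of the secondary depolarization peak
    beat: int        # 0-based beat index
    delta_v: float   # mV rise from the preceding local minimum


def apd90(t_ms: np.ndarray, v_mv: np.ndarray) -> float:
    """APD_90 (ms) of a single-beat trace starting at the stimulus.

    Returns NaN when the beat fails to repolarize to the 90% level
    (e.g. when EADs hold the membrane depolarized).
    Offset-invariant: shifting the whole trace in V leaves it unchanged.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mv, dtype=float)
    if t.size < 5:
        raise ValueError("trace too short for APD measurement")
    v_rest = v[0]
    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(dvdt))
    i_peak = i_up + int(np.argmax(v[i_up:]))
    v_peak = v[i_peak]
    if v_peak - v_rest < 10.0:
        raise ValueError("no action potential in trace (peak < 10 mV "
                         "above rest)")
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    below = np.nonzero(v[i_peak:] <= v90)[0]
    if below.size == 0:
        return float("nan")
    k = i_peak + below[0]
    if k == 0 or v[k] == v[k - 1]:
        t_cross = t[k]
    else:
        frac = (v[k - 1] - v90) / (v[k - 1] - v[k])
        t_cross = t[k - 1] + frac * (t[k] - t[k - 1])
    return float(t_cross - t[i_up])


def cat_amplitude(cai_mm: np.ndarray) -> float:
    """Ca2+-transient amplitude of one beat (peak minus pre-stim level)."""
    cai = np.asarray(cai_mm, dtype=float)
    return float(cai.max() - cai[0])


def detect_eads(t_ms: np.ndarray, v_mv: np.ndarray,
                beat_starts_ms: np.ndarray, delta_mv: float = 1.0,
                floor_mv: float = -40.0,
                blank_ms: float = 100.0) -> list[EadEvent]:
    """Scan each beat for secondary depolarizations.

    ``beat_starts_ms``: stimulus times bounding the beats.  The first
    ``blank_ms`` of each beat are skipped so the upstroke and the
    physiological spike-notch-dome complex are never counted; the
    search then runs to the first sample at or below ``floor_mv`` (or
    the beat end when repolarization never gets there).  Each
    local-minimum -> local-maximum excursion rising by at least
    ``delta_mv`` is one event, timestamped at the secondary peak.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mv, dtype=float)
    starts = np.asarray(beat_starts_ms, dtype=float)
    events: list[EadEvent] = []
    bounds = np.concatenate([starts, [t[-1] + (t[1] - t[0])]])
    for b in range(starts.size):
        lo = int(np.searchsorted(t, bounds[b] + blank_ms))
        hi = int(np.searchsorted(t, bounds[b + 1]))
        if hi - lo < 5:
            continue
        seg_v = v[lo:hi]
        seg_t = t[lo:hi]
        below = np.nonzero(seg_v <= floor_mv)[0]
        end = int(below[0]) + 1 if below.size else seg_v.size
        vv = seg_v[:end]
        tt = seg_t[:end]
        run_min = vv[0]
        k = 1
        while k < vv.size:
            if vv[k] <= run_min:
                run_min = vv[k]
                k += 1
            elif vv[k] - run_min >= delta_mv:
                # climb exceeds threshold: advance to the local maximum
                while k + 1 < vv.size and vv[k + 1] >= vv[k]:
                    k += 1
                events.append(EadEvent(time_ms=float(tt[k]), beat=b,
                                       delta_v=float(vv[k] - run_min)))
                run_min = vv[k]
                k += 1
            else:
                k += 1
    return events
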