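"""The five whole-cell stimulation protocols used to characterize Kv11.1.

Each protocol is a list of sweeps; a sweep is a piecewise-constant
command-voltage schedule (duration ms, voltage mV).  Cells are held at
-80 mV between sweeps.  Two of the protocols (steady-state inactivation
and recovery from inactivation) share one schedule and differ only in
which part of the sweep is analysed, so five protocol values are built
over four distinct schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

HOLDING_MV = -80.0

__all__ = ["VoltageProtocol", "builtin_protocols", "HOLDING_MV"]


@dataclass(frozen=True)
class VoltageProtocol:
    """Per-sweep command-voltage schedule with inter-sweep timing.

    ``sweeps`` maps a sweep label (the varied voltage, mV) to a tuple of
    (duration_ms, voltage_mv) segments.  ``analysis_windows`` names the
    segment indices the feature extraction operates on.
    """

    name: str
    sweeps: dict
    stimulation_frequency: float             # Hz, sweep-start to sweep-start
    analysis_windows: dict = field(default_factory=dict)
    min_holding_ms: float = 2000.0           # enforced -80 mV gap if 1/f is short

    def __post_init__(self):
        for label, segs in self.sweeps.items():
            if any(d <= 0 for d, _ in segs):
                raise ValueError(f"{self.name}: non-positive segment duration "
                                 f"in sweep {label}")

    def sweep_duration(self, label) -> float:
        return float(sum(d for d, _ in self.sweeps[label]))

    def holding_interval(self, label) -> float:
        """-80 mV interval between the end of this sweep and the next one.

        The nominal period is 1/stimulation_frequency; when a sweep is
        longer than the period (which the printed protocol timings allow),
        a minimum holding interval is used instead so that the channel
        always re-equilibrates partially at the holding potential.
        """
        period = 1000.0 / self.stimulation_frequency
        return max(period - self.sweep_duration(label), self.min_holding_ms)


def _activation() -> VoltageProtocol:
    # hold -80; P1 2 s at -50..+50 (10-mV steps); P2 2 s at -50; 0.2 Hz
    sweeps = {v: ((2000.0, float(v)), (2000.0, -50.0))
              for v in range(-50, 60, 10)}
    return VoltageProtocol(
        name="activation", sweeps=sweeps, stimulation_frequency=0.2,
        analysis_windows={"prepulse": 0, "tail": 1})


def _deactivation() -> VoltageProtocol:
    # 2-s prepulse to +50; 6-s test steps 0..-120 (10-mV steps); 0.25 Hz
    sweeps = {v: ((2000.0, 50.0), (6000.0, float(v)))
              for v in range(0, -130, -10)}
    return VoltageProtocol(
        name="deactivation", sweeps=sweeps, stimulation_frequency=0.25,
        analysis_windows={"prepulse": 0, "tail": 1})


def _inactivation_tau() -> VoltageProtocol:
    # 500-ms prepulse +50; 2 ms at -120 (full recovery, no deactivation);
    # 500-ms test at +60..-60 (10-mV steps); 0.2 Hz
    sweeps = {v: ((500.0, 50.0), (2.0, -120.0), (500.0, float(v)))
              for v in range(60, -70, -10)}
    return VoltageProtocol(
        name="inactivation_tau", sweeps=sweeps, stimulation_frequency=0.2,
        analysis_windows={"prepulse": 0, "recovery_gap": 1, "test": 2})


def _ss_inactivation_schedule() -> dict:
    # 500- to 480-ms prepulse +50; interpulse -120..+60, starting at 2 ms
    # and prolonging by 2 ms per 10-mV step (slower gating at less
    # negative voltages); 500-ms test at +50; 0.2 Hz
    sweeps = {}
    for i, v in enumerate(range(-120, 70, 10)):
        gap = 2.0 + 2.0 * i
        pre = max(480.0, 500.0 - 2.0 * i)
        sweeps[v] = ((pre, 50.0), (gap, float(v)), (500.0, 50.0))
    return sweeps


def _ss_inactivation() -> VoltageProtocol:
    return VoltageProtocol(
        name="ss_inactivation", sweeps=_ss_inactivation_schedule(),
        stimulation_frequency=0.2,
        analysis_windows={"prepulse": 0, "interpulse": 1, "test": 2})


def _recovery() -> VoltageProtocol:
    return VoltageProtocol(
        name="recovery", sweeps=_ss_inactivation_schedule(),
        stimulation_frequency=0.2,
        analysis_windows={"prepulse": 0, "interpulse": 1, "test": 2})


def builtin_protocols() -> dict[str, VoltageProtocol]:
    """The five stimulation protocols keyed by name."""
    ps = [_activation(), _deactivation(), _inactivation_tau(),
          _ss_inactivation(), _recovery()]
    return {p.name: p for p in ps}
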