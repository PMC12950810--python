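"""Synthetic whole-cell cohorts with the statistical structure of the
measured channel populations.

Each virtual cell draws its kinetic parameters around the group medians:
time constants, slope factors and the maximal conductance get
independent log-normal multipliers (keeping them positive), half-
activation voltages get additive Gaussian shifts (they are signed
quantities).  The spread of each parameter is derived from the measured
interquartile range: for a log-normal multiplier
``sigma = ln(Q3/Q1) / 1.349`` and for an additive shift
``sd = (Q3 - Q1) / 1.349`` (1.349 = IQR of a standard normal).
Recording noise is additive white Gaussian, applied after simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path

import h5py
import numpy as np

from .channel import ChannelParams, SweepRecording, \
    advance_gates, holding_state, simulate_sweep
from .protocols import HOLDING_MV, VoltageProtocol, builtin_protocols
from .variants import GROUPS, variant_params

__all__ = ["CohortSpec", "CellRecording", "default_variability",
           "generate_cohort", "write_cohort", "read_cohort",
           "DEFAULT_SAMPLE_INTERVALS", "group_reference"]

_IQR_NORMAL = 1.3489795  # IQR of the standard normal distribution

#: Per-protocol sampling intervals (ms); the brief inactivation /
#: recovery relaxations (tau down to ~0.5 ms) need fine sampling, the
#: slow activation/deactivation kinetics do not.
DEFAULT_SAMPLE_INTERVALS = {
    "activation": 1.0,
    "deactivation": 1.0,
    "inactivation_tau": 0.05,
    "ss_inactivation": 0.05,
    "recovery": 0.05,
}


@lru_cache(maxsize=1)
def group_reference() -> dict:
    """Measured per-group summary statistics (median, Q1, Q3, n)."""
    with resources.files("hergsim.data").joinpath("table1.json").open() as fh:
        return json.load(fh)["parameters"]


def _lognormal_sigma(param: str, group: str) -> float:
    ref = group_reference()[param][group]
    return float(np.log(ref["q3"] / ref["q1"]) / _IQR_NORMAL)


def _additive_sd(param: str, group: str) -> float:
    ref = group_reference()[param][group]
    return float((ref["q3"] - ref["q1"]) / _IQR_NORMAL)


def default_variability(group: str) -> dict[str, float]:
    """Per-parameter spread for one group, derived from the measured
    interquartile ranges.  Keys ending in ``_sd`` are additive (mV);
    the rest are log-normal sigmas of multiplicative factors."""
    return {
        "g_max": _lognormal_sigma("i_tail_30mv_pa", group),
        "k_act": _lognormal_sigma("k_act_mv", group),
        "k_inact": _lognormal_sigma("k_inact_mv", group),
        "tau_act": _lognormal_sigma("tau_act_30mv_ms", group),
        "tau_deact": _lognormal_sigma("tau_deact_m90mv_ms", group),
        "tau_inact": _lognormal_sigma("tau_inact_0mv_ms", group),
        "tau_rec": _lognormal_sigma("tau_rec_m20mv_ms", group),
        "v_half_act_sd": _additive_sd("v_half_act_mv", group),
        "v_half_inact_sd": _additive_sd("v_half_inact_mv", group),
        "c_m": _lognormal_sigma("c_m_pf", group),
        "r_a": _lognormal_sigma("r_a_mohm", group),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cell population."""

    group_label: str
    n_cells: int
    seed: int = 0
    base_params: ChannelParams | None = None   # defaults to the group medians
    variability: dict | None = None            # None -> measured IQRs; {} -> none
    noise_sd: float = 5.0                      # pA additive recording noise
    sample_intervals: dict = field(default_factory=lambda: dict(
        DEFAULT_SAMPLE_INTERVALS))

    def __post_init__(self):
        if self.group_label not in GROUPS:
            raise ValueError(f"unknown group {self.group_label!r}; "
                             f"expected one of {GROUPS}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.variability is not None and any(
                v < 0 for v in self.variability.values()):
            raise ValueError("variability entries must be non-negative")


@dataclass
class CellRecording:
    """Simulated (or loaded) recordings of one cell across protocols."""

    cell_id: str
    group_label: str
    c_m: float      # pF, metadata only
    r_a: float      # MOhm, metadata only
    sweeps: dict    # protocol name -> {sweep label: SweepRecording}
    params: ChannelParams | None = None  # generating parameters, if synthetic


def _perturb_params(base: ChannelParams, var: dict,
                    rng: np.random.Generator) -> ChannelParams:
    ln = lambda key: float(np.exp(rng.normal(0.0, var.get(key, 0.0))))
    add = lambda key: float(rng.normal(0.0, var.get(key, 0.0)))
    return replace(
        base,
        v_half_act=base.v_half_act + add("v_half_act_sd"),
        k_act=base.k_act * ln("k_act"),
        v_half_inact=base.v_half_inact + add("v_half_inact_sd"),
        k_inact=base.k_inact * ln("k_inact"),
        tau_act_curve=base.tau_act_curve.scaled(ln("tau_act")),
        tau_deact_curve=base.tau_deact_curve.scaled(ln("tau_deact")),
        tau_inact_curve=base.tau_inact_curve.scaled(ln("tau_inact")),
        tau_rec_curve=base.tau_rec_curve.scaled(ln("tau_rec")),
        g_max=base.g_max * ln("g_max"),
    )


def simulate_cell_protocol(params: ChannelParams, protocol: VoltageProtocol,
                           sample_interval: float) -> dict:
    """All sweeps of one protocol for one cell, with the inter-sweep
    holding interval at -80 mV carried between sweeps."""
    state = holding_state(HOLDING_MV, params)
    out = {}
    for label in protocol.sweeps:
        rec, state = simulate_sweep(protocol.sweeps[label], params, state,
                                    sample_interval, label=label)
        out[label] = rec
        state = advance_gates(state, HOLDING_MV,
                              protocol.holding_interval(label), params)
    return out


def generate_cohort(spec: CohortSpec,
                    protocols: list[VoltageProtocol] | None = None
                    ) -> list[CellRecording]:
    """Generate a deterministic (seeded) cohort of virtual cells."""
    if protocols is None:
        protocols = list(builtin_protocols().values())
    base = spec.base_params if spec.base_params is not None \
        else variant_params(spec.group_label)
    var = spec.variability if spec.variability is not None \
        else default_variability(spec.group_label)
    rng = np.random.default_rng(spec.seed)

    ref = group_reference()
    cm_med = ref["c_m_pf"][spec.group_label]["median"]
    ra_med = ref["r_a_mohm"][spec.group_label]["median"]

    cells = []
    for i in range(spec.n_cells):
        params = _perturb_params(base, var, rng)
        c_m = cm_med * float(np.exp(rng.normal(0.0, var.get("c_m", 0.0))))
        r_a = ra_med * float(np.exp(rng.normal(0.0, var.get("r_a", 0.0))))
        sweeps = {}
        for proto in protocols:
            dt = spec.sample_intervals.get(proto.name, 0.1)
            recs = simulate_cell_protocol(params, proto, dt)
            if spec.noise_sd > 0:
                for rec in recs.values():
                    rec.i_pa = rec.i_pa + rng.normal(
                        0.0, spec.noise_sd, rec.i_pa.shape)
            sweeps[proto.name] = recs
        cells.append(CellRecording(
            cell_id=f"{spec.group_label}-{i:03d}", group_label=spec.group_label,
            c_m=c_m, r_a=r_a, sweeps=sweeps, params=params))
    return cells


# ---------------------------------------------------------------------------
# container I/O: HDF5 traces + JSON metadata sidecar
# ---------------------------------------------------------------------------

def write_cohort(path, cells: list[CellRecording]) -> None:
    """Write a cohort to HDF5 (groups = cells, datasets = sweeps) with a
    JSON metadata sidecar next to it."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = "hergsim.cohort/1"
        root = f.create_group("cells")
        for cell in cells:
            g = root.create_group(cell.cell_id)
            g.attrs["group_label"] = cell.group_label
            g.attrs["c_m_pf"] = cell.c_m
            g.attrs["r_a_mohm"] = cell.r_a
            if cell.params is not None:
                g.attrs["params_json"] = json.dumps(cell.params.to_dict())
            for proto_name, sweeps in cell.sweeps.items():
                pg = g.create_group(proto_name)
                for label, rec in sweeps.items():
                    ds = pg.create_dataset(str(label), data=rec.i_pa)
                    ds.attrs["sample_interval_ms"] = rec.sample_interval
                    ds.attrs["segments"] = np.asarray(rec.segments)
                    ds.attrs["label"] = float(label)
    meta = {
        "schema": "hergsim.cohort_meta/1",
        "n_cells": len(cells),
        "groups": sorted({c.group_label for c in cells}),
        "cells": [{"cell_id": c.cell_id, "group_label": c.group_label,
                   "c_m_pf": c.c_m, "r_a_mohm": c.r_a} for c in cells],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1))


def read_cohort(path) -> list[CellRecording]:
    """Read a cohort written by :func:`write_cohort` (lossless)."""
    path = Path(path)
    cells = []
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("schema") != "hergsim.cohort/1":
                raise ValueError(f"{path}: not a hergsim cohort file "
                                 f"(schema={f.attrs.get('schema')!r})")
            for cell_id, g in f["cells"].items():
                sweeps = {}
                for proto_name, pg in g.items():
                    recs = {}
                    for key, ds in pg.items():
                        segs = tuple((float(d), float(v))
                                     for d, v in ds.attrs["segments"])
                        dt = float(ds.attrs["sample_interval_ms"])
                        i_pa = np.asarray(ds)
                        label = float(ds.attrs["label"])
                        if label == int(label):
                            label = int(label)
                        recs[label] = SweepRecording(
                            t_ms=np.arange(i_pa.size) * dt, i_pa=i_pa,
                            v_mv=_command_trace(segs, i_pa.size, dt),
                            segments=segs, label=label)
                    sweeps[proto_name] = recs
                params = None
                if "params_json" in g.attrs:
                    params = ChannelParams.from_dict(
                        json.loads(g.attrs["params_json"]))
                cells.append(CellRecording(
                    cell_id=cell_id, group_label=str(g.attrs["group_label"]),
                    c_m=float(g.attrs["c_m_pf"]),
                    r_a=float(g.attrs["r_a_mohm"]),
                    sweeps=sweeps, params=params))
    except OSError as exc:
        raise ValueError(f"cannot read cohort file {path}: {exc}") from exc
    return sorted(cells, key=lambda c: c.cell_id)


def _command_trace(segments, n, dt):
    v = np.empty(n)
    t0 = 0.0
    for d, volt in segments:
        lo = int(np.ceil((t0 - 1e-9) / dt))
        hi = min(int(np.ceil((t0 + d - 1e-9) / dt)), n)
        v[lo:hi] = volt
        t0 += d
    if hi < n:
        v[hi:] = segments[-1][1]
    return v
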