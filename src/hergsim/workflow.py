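"""Reproducible end-to-end runs: cohort synthesis -> clamp analysis ->
group report, and the three myocyte simulation scenarios.

Every run emits a JSON manifest (config snapshot, package version,
seeds, output digests) sufficient to reproduce the seeded stages
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CohortSpec, generate_cohort, group_reference
from .ord import OrdConfig
from .ord.sim import (OrdResult, beta_as_protocol, hypokalemia_protocol,
                      run_paced)
from .pipeline import cells_to_frame, summarize_cohorts
from .variants import GROUPS

__all__ = ["write_manifest", "reproduce_table1", "reproduce_fig7"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict,
                   seeds: dict | None, outputs: list,
                   wall_time_s: float) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "schema": "hergsim.manifest/1",
        "package_version": __version__,
        "command": command,
        "config": config,
        "seeds": seeds or {},
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
        "wall_time_s": round(wall_time_s, 3),
        "python": platform.python_version(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def reproduce_table1(out_dir, seed: int = 0, noiseless: bool = False,
                     n_cells: dict | None = None) -> dict:
    """Synthesize all four cohorts at the measured group sizes, run the
    full clamp analysis, and write the per-cell table plus the group
    summary (median, Q1, Q3, n, significance flags, percent reductions).
    """
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = group_reference()
    cells = []
    seeds = {}
    for k, group in enumerate(GROUPS):
        n = (n_cells or {}).get(group,
                                ref["i_tail_30mv_pa"][group]["n"])
        gseed = seed * 1000 + k
        seeds[group] = gseed
        spec = CohortSpec(group, n, seed=gseed,
                          variability={} if noiseless else None,
                          noise_sd=0.0 if noiseless else 5.0)
        cells.extend(generate_cohort(spec))
    frame = cells_to_frame(cells)
    summary = summarize_cohorts(frame)
    cell_csv = out_dir / "cell_parameters.csv"
    frame.to_csv(cell_csv, index=False)
    summary_json = out_dir / "group_summary.json"
    summary_json.write_text(json.dumps(summary, indent=1))
    write_manifest(out_dir, "reproduce-table1",
                   {"seed": seed, "noiseless": noiseless}, seeds,
                   [cell_csv, summary_json], time.time() - t0)
    return summary


def _result_payload(res: OrdResult) -> dict:
    return {
        "apd90_ms": [None if np.isnan(a) else round(a, 2)
                     for a in res.apd90_ms],
        "cat_amplitude_mm": [round(c, 6) for c in res.cat_amplitude_mm],
        "diastolic_v_mv": [round(d, 2) for d in res.diastolic_v_mv],
        "ead_events": [{"time_ms": round(e.time_ms, 1), "beat": e.beat,
                        "delta_v_mv": round(e.delta_v, 2)}
                       for e in res.ead_events],
        "beats_paced": res.beats_paced,
        "converged": res.converged,
        "first_ead_time_ms": res.first_ead_time_ms,
    }


def _write_traces(out_dir: Path, name: str, res: OrdResult) -> Path:
    import pandas as pd
    path = out_dir / f"{name}_trace.csv"
    pd.DataFrame({"t_ms": res.t_ms, "v_mv": res.v_mv,
                  "cai_mm": res.cai_mm}).to_csv(path, index=False)
    return path


def reproduce_fig7(out_dir, dt: float = 0.005, n_beats: int = 1000,
                   plots: bool = True) -> dict:
    """Run the three simulation scenarios for the control and the
    g_Kr-reduced model: steady-state pacing at 1 Hz, acute hypokalemia
    (5.4 -> 3.0 mM), and beta-adrenergic stimulation at 2.5 Hz.

    Writes per-scenario trace CSVs, a metrics JSON, optional V/CaT
    plots, and a manifest.  Returns the metrics dict.
    """
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics: dict = {}
    outputs: list = []
    steady = {}
    for label, gkr in (("control", 1.0), ("variant", 0.31)):
        cfg = OrdConfig(g_kr_scale=gkr, dt=dt, n_beats=n_beats)
        base = run_paced(cfg, record_beats=2)
        steady[label] = base.final_state
        hypo = hypokalemia_protocol(cfg, steady_state=base.final_state,
                                    post_beats=30)
        beta = beta_as_protocol(cfg, steady_state=base.final_state,
                                duration_ms=60000.0)
        metrics[label] = {
            "baseline": _result_payload(base),
            "hypokalemia": _result_payload(hypo),
            "beta_as": _result_payload(beta),
        }
        for scen, res in (("baseline", base), ("hypokalemia", hypo),
                          ("beta_as", beta)):
            outputs.append(_write_traces(out_dir, f"{label}_{scen}", res))
            if plots:
                outputs.append(_plot(out_dir, f"{label}_{scen}", res))
    apd_c = metrics["control"]["baseline"]["apd90_ms"][-1]
    apd_v = metrics["variant"]["baseline"]["apd90_ms"][-1]
    metrics["apd90_prolongation_pct"] = round(100.0 * (apd_v / apd_c - 1.0), 1)
    metrics_json = out_dir / "metrics.json"
    metrics_json.write_text(json.dumps(metrics, indent=1))
    outputs.append(metrics_json)
    write_manifest(out_dir, "reproduce-fig7",
                   {"dt": dt, "n_beats": n_beats}, None, outputs,
                   time.time() - t0)
    return metrics


def _plot(out_dir: Path, name: str, res: OrdResult) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax1.plot(res.t_ms / 1000.0, res.v_mv, lw=0.7)
    ax1.set_ylabel("V (mV)")
    ax2.plot(res.t_ms / 1000.0, res.cai_mm * 1e3, lw=0.7, color="tab:red")
    ax2.set_ylabel("[Ca$^{2+}$]$_i$ ($\\mu$M)")
    ax2.set_xlabel("time (s)")
    for e in res.ead_events:
        ax1.plot(e.time_ms / 1000.0, 30, "v", color="k", ms=3)
    fig.suptitle(name)
    path = out_dir / f"{name}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
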