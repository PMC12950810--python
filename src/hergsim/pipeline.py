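"""End-to-end analysis: per-cell kinetic parameters and group reports.

``extract_cell_parameters`` runs the whole clamp-analysis stack on one
cell in dependency order (deactivation first, because its time
constants feed the drift compensation of the recovery and steady-state
availability analyses).  ``summarize_cohorts`` turns per-cell tables
into a median (Q1, Q3) report with Kruskal-Wallis/Dunn significance
flags, including the percent current reduction of each variant group
relative to the wild type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import analysis as an
from .cohort import CellRecording
from .protocols import builtin_protocols
from .stats import kruskal_dunn, significance_flag, summarize_group

__all__ = ["extract_cell_parameters", "cells_to_frame", "summarize_cohorts"]

#: Parameter keys produced per cell (voltage-anchored scalars).
PARAMETER_KEYS = (
    "i_tail_30mv_pa", "v_half_act_mv", "k_act_mv", "tau_act_30mv_ms",
    "tau_deact_m90mv_ms", "v_half_inact_mv", "k_inact_mv",
    "tau_inact_0mv_ms", "tau_rec_m80mv_ms", "tau_rec_m20mv_ms",
)


def extract_cell_parameters(cell: CellRecording, protocols=None,
                            drift_compensation: bool = True) -> dict:
    """All Table-style kinetic parameters of one cell.

    Returns a flat dict of the anchored scalars plus the per-voltage
    detail (tails, tau dictionaries, fitted curves).
    """
    if protocols is None:
        protocols = builtin_protocols()

    tails = an.extract_tail_current(cell, protocols["activation"])
    _, _, act_fit = an.activation_curve(cell, protocols["activation"])
    tau_act = an.activation_tau(cell, protocols["activation"])
    tau_deact = an.deactivation_tau(cell, protocols["deactivation"])
    tau_inact = an.inactivation_tau(cell, protocols["inactivation_tau"])
    deact = tau_deact if drift_compensation else None
    _, _, inact_fit = an.steady_state_inactivation_curve(
        cell, protocols["ss_inactivation"], deactivation=deact)
    tau_rec = an.recovery_tau(cell, protocols["recovery"], deactivation=deact)

    return {
        "cell_id": cell.cell_id,
        "group": cell.group_label,
        "c_m_pf": cell.c_m,
        "r_a_mohm": cell.r_a,
        "i_tail_30mv_pa": tails[30],
        "v_half_act_mv": act_fit.v_half,
        "k_act_mv": act_fit.k,
        "tau_act_30mv_ms": tau_act[30].tau,
        "tau_deact_m90mv_ms": tau_deact[-90].tau,
        "v_half_inact_mv": inact_fit.v_half,
        "k_inact_mv": inact_fit.k,
        "tau_inact_0mv_ms": tau_inact[0].tau,
        "tau_rec_m80mv_ms": tau_rec[-80].tau,
        "tau_rec_m20mv_ms": tau_rec[-20].tau,
        "detail": {
            "tails_pa": tails,
            "activation_fit": act_fit,
            "inactivation_fit": inact_fit,
            "tau_act": tau_act, "tau_deact": tau_deact,
            "tau_inact": tau_inact, "tau_rec": tau_rec,
        },
    }


def cells_to_frame(cells, protocols=None,
                   drift_compensation: bool = True) -> pd.DataFrame:
    """Tidy per-cell parameter table (one row per cell)."""
    rows = []
    for cell in cells:
        row = extract_cell_parameters(cell, protocols, drift_compensation)
        row.pop("detail")
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohorts(frame: pd.DataFrame,
                      reference_group: str = "WT") -> dict:
    """Group report: per-parameter median (Q1, Q3, n), Dunn significance
    flags versus every other group, and percent tail-current reductions
    relative to ``reference_group``.
    """
    groups = list(dict.fromkeys(frame["group"]))
    out = {"groups": groups, "parameters": {}, "reductions_pct": {}}
    for key in PARAMETER_KEYS:
        per_group = {g: frame.loc[frame["group"] == g, key].to_numpy()
                     for g in groups}
        per_group = {g: v[np.isfinite(v)] for g, v in per_group.items()
                     if np.isfinite(v).sum() >= 2}
        entry = {}
        for g, vals in per_group.items():
            s = summarize_group(vals)
            entry[g] = {"median": s.median, "q1": s.q1, "q3": s.q3, "n": s.n}
        if len(per_group) >= 2:
            kd = kruskal_dunn(per_group)
            entry["_kruskal"] = {"H": kd.h_statistic, "p": kd.p_value}
            entry["_pairwise"] = {
                f"{d.group_a} vs {d.group_b}": {
                    "p_adj": d.p_adjusted,
                    "flag": significance_flag(d.p_adjusted)}
                for d in kd.pairwise}
        out["parameters"][key] = entry
    tails = out["parameters"].get("i_tail_30mv_pa", {})
    ref = tails.get(reference_group)
    if ref:
        for g in groups:
            if g == reference_group or g not in tails:
                continue
            out["reductions_pct"][g] = an.percent_reduction(
                ref["median"], tails[g]["median"])
    return out
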