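"""Curve fitting, feature extraction and group statistics against
independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from hergsim.analysis import (extract_tail_current, fit_boltzmann,
                              fit_single_exponential, percent_reduction)
from hergsim.cohort import CellRecording
from hergsim.channel import SweepRecording
from hergsim.protocols import builtin_protocols
from hergsim.stats import kruskal_dunn, significance_flag, summarize_group


# ------------------------------------------------------------ Boltzmann fits

def test_boltzmann_exact_self_consistency():
    v = np.arange(-60.0, 61.0, 10.0)
    y = 1.0 / (1.0 + np.exp(-(v - 0.0) / 10.0))
    fit = fit_boltzmann(v, y)
    assert fit.converged
    assert fit.v_half == pytest.approx(0.0, abs=1e-6)
    assert fit.k == pytest.approx(10.0, abs=1e-6)
    assert fit.a1 == pytest.approx(0.0, abs=1e-6)
    assert fit.a2 == pytest.approx(1.0, abs=1e-6)


def test_boltzmann_decreasing_orientation():
    v = np.arange(-120.0, 61.0, 10.0)
    y = 1.0 / (1.0 + np.exp((v + 60.4) / 23.1))
    fit = fit_boltzmann(v, y)
    assert fit.v_half == pytest.approx(-60.4, abs=1e-6)
    assert fit.k == pytest.approx(23.1, abs=1e-6)
    assert fit.a1 > fit.a2          # decreasing curve


def test_boltzmann_against_grid_search_oracle():
    """Least-squares optimum agrees with an exhaustive lattice search
    over (V1/2, k) to within the lattice resolution."""
    rng = np.random.default_rng(3)
    v = np.arange(-60.0, 61.0, 10.0)
    truth = 1.0 / (1.0 + np.exp(-(v - 4.3) / 9.1))
    y = truth + rng.normal(0, 0.01, v.size)
    fit = fit_boltzmann(v, y, fix_extremes=True)
    a1, a2 = y.min(), y.max()
    vh_grid = np.arange(2.0, 7.0, 0.01)
    k_grid = np.arange(7.0, 11.0, 0.01)
    vv, kk = np.meshgrid(vh_grid, k_grid, indexing="ij")
    pred = (a1 - a2) / (1.0 + np.exp((v[None, None, :] - vv[..., None])
                                     / kk[..., None])) + a2
    rss = ((pred - y[None, None, :]) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    assert fit.v_half == pytest.approx(vh_grid[i], abs=0.01)
    assert fit.k == pytest.approx(k_grid[j], abs=0.01)


def test_boltzmann_needs_five_points():
    with pytest.raises(ValueError):
        fit_boltzmann([0, 1, 2, 3], [0, 0.2, 0.8, 1.0])


# ---------------------------------------------------------- exponential fits

def test_exponential_exact_recovery():
    t = np.arange(0.0, 500.0, 1.0)
    y = 50.0 * np.exp(-t / 100.0) + 5.0
    fit = fit_single_exponential(t, y)
    assert fit.converged
    assert fit.tau == pytest.approx(100.0, abs=1e-6)
    assert fit.amplitude == pytest.approx(50.0, abs=1e-6)
    assert fit.offset == pytest.approx(5.0, abs=1e-6)


def test_exponential_rising_trace():
    t = np.arange(0.0, 30.0, 0.1)
    y = -8.0 * np.exp(-t / 4.63) + 9.0
    fit = fit_single_exponential(t, y)
    assert fit.tau == pytest.approx(4.63, abs=1e-6)
    assert fit.amplitude == pytest.approx(-8.0, abs=1e-6)


def test_exponential_refine_window_isolates_fast_component():
    """A fast decay riding on a slow drift is recovered once the fit
    window shrinks to ~10 fitted time constants."""
    t = np.arange(0.0, 500.0, 0.05)
    y = 40.0 * np.exp(-t / 5.84) + 20.0 * np.exp(-t / 1200.0)
    full = fit_single_exponential(t, y)
    refined = fit_single_exponential(t, y, refine_window=10.0)
    assert abs(refined.tau - 5.84) < abs(full.tau - 5.84)
    assert refined.tau == pytest.approx(5.84, rel=0.05)


def test_exponential_needs_ten_samples():
    with pytest.raises(ValueError):
        fit_single_exponential(np.arange(5.0), np.arange(5.0))


# -------------------------------------------------------------- tail currents

def test_zero_trace_gives_zero_tails():
    proto = builtin_protocols()["activation"]
    sweeps = {}
    for v, segs in proto.sweeps.items():
        n = int(sum(d for d, _ in segs)) + 1
        sweeps[v] = SweepRecording(
            t_ms=np.arange(n, dtype=float), i_pa=np.zeros(n),
            v_mv=np.zeros(n), segments=segs, label=v)
    cell = CellRecording("z", "WT", 10.0, 4.0, {"activation": sweeps})
    tails = extract_tail_current(cell, proto)
    assert all(t == 0.0 for t in tails.values())


def test_missing_sweep_reported():
    proto = builtin_protocols()["activation"]
    cell = CellRecording("m", "WT", 10.0, 4.0, {"activation": {}})
    with pytest.raises(ValueError, match="missing sweeps"):
        extract_tail_current(cell, proto)


# ---------------------------------------------------------- percent reduction

def test_percent_reduction_measured_values():
    # medians of the tail current at +30 mV
    assert round(percent_reduction(362.7, 110.5), 1) == 69.5
    assert round(percent_reduction(362.7, 111.8), 1) == 69.2


def test_percent_reduction_properties():
    assert percent_reduction(123.4, 123.4) == 0.0
    a = percent_reduction(362.7, 110.5)
    assert percent_reduction(3.627, 1.105) == pytest.approx(a, rel=1e-12)
    with pytest.raises(ValueError):
        percent_reduction(0.0, 1.0)
    with pytest.raises(ValueError):
        percent_reduction(-5.0, 1.0)


# ------------------------------------------------------------------ summaries

def test_summarize_group_simple():
    s = summarize_group([1.0, 2.0, 3.0])
    assert (s.median, s.n) == (2.0, 3)
    c = summarize_group([4.2] * 7)
    assert c.q1 == c.median == c.q3 == 4.2


def _quartile_oracle(x, q):
    """Type-7 quantile by direct sort-based linear interpolation."""
    xs = np.sort(np.asarray(x, dtype=float))
    pos = q * (xs.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, xs.size - 1)
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def test_summarize_group_against_sort_oracle():
    rng = np.random.default_rng(11)
    for n in (2, 3, 5, 10, 37):
        x = rng.normal(size=n)
        s = summarize_group(x)
        assert s.q1 == pytest.approx(_quartile_oracle(x, 0.25), abs=1e-12)
        assert s.median == pytest.approx(_quartile_oracle(x, 0.5), abs=1e-12)
        assert s.q3 == pytest.approx(_quartile_oracle(x, 0.75), abs=1e-12)


def test_summarize_empty_raises():
    with pytest.raises(ValueError):
        summarize_group([])


# ------------------------------------------------------------- Kruskal / Dunn

def test_identical_groups_not_significant():
    g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
    res = kruskal_dunn(g)
    assert res.p_value > 0.9
    assert all(d.p_adjusted > 0.9 for d in res.pairwise)


def test_all_tied_degenerate():
    res = kruskal_dunn({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
    assert res.h_statistic == 0.0
    assert res.p_value == 1.0


def _h_statistic(groups):
    """Independent H computation with tie correction."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    off = np.concatenate([[0], np.cumsum([len(g) for g in groups])])
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * ranks[off[i]:off[i + 1]].mean() ** 2
        for i, g in enumerate(groups)) - 3 * (n + 1)
    _, cnt = np.unique(pooled, return_counts=True)
    return h / (1.0 - np.sum(cnt**3 - cnt) / (n**3 - n))


def test_kruskal_against_permutation_oracle():
    """Chi-square p-value agrees with the exact permutation null of H
    on a tiny three-group data set (all label assignments enumerated)."""
    data = [4.1, 1.2, 3.3, 9.0, 0.5, 5.5, 2.2, 7.7]
    sizes = (3, 3, 2)
    groups = {"a": data[:3], "b": data[3:6], "c": data[6:]}
    res = kruskal_dunn(groups)
    assert res.h_statistic == pytest.approx(
        _h_statistic([data[:3], data[3:6], data[6:]]), abs=1e-10)

    h_obs = res.h_statistic
    count = total = 0
    for perm in set(itertools.permutations(range(8))):
        arr = [data[i] for i in perm]
        h = _h_statistic([arr[:3], arr[3:6], arr[6:]])
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    p_perm = count / total
    assert res.p_value == pytest.approx(p_perm, abs=0.1)


def test_dunn_detects_clear_shift():
    rng = np.random.default_rng(5)
    res = kruskal_dunn({
        "lo": rng.normal(0, 1, 15),
        "hi": rng.normal(6, 1, 15),
        "mid": rng.normal(0.4, 1, 15)})
    pair = {(" vs ".join((d.group_a, d.group_b))): d for d in res.pairwise}
    assert pair["lo vs hi"].p_adjusted < 0.001
    assert pair["lo vs mid"].p_adjusted > 0.05
    # Bonferroni adjustment over 3 pairs
    assert all(d.p_adjusted == pytest.approx(min(1.0, 3 * d.p_unadjusted))
               for d in res.pairwise)


def test_significance_flags():
    assert significance_flag(0.5) == ""
    assert significance_flag(0.04) == "*"
    assert significance_flag(0.009) == "**"
    assert significance_flag(0.0009) == "***"


def test_kruskal_input_validation():
    with pytest.raises(ValueError):
        kruskal_dunn({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        kruskal_dunn({"a": [1.0], "b": [1.0, 2.0]})
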