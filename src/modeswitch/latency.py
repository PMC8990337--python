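"""Response-latency estimation at the neuron, population, area, and
kinematic level.

Single neurons use a two-step Poisson test on pooled 1-ms spike counts: the
first post-cue bin significant at alpha = 0.001 anchors the detection, and
the latency is pulled back to the start of the contiguous run of bins
significant at alpha = 0.05 that contains it.  The two-step rule avoids
calling latency on small-amplitude drifts while still reporting the earliest
credible departure from baseline.

Population projections use the analogous 5-sigma / 2-sigma rule on the
baseline-standardized, causally smoothed projection trace.  An area's
latency is the first time at which 1% of its analyzed cells (including
non-responders in the denominator) have responded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LatencyResult",
    "neuron_go_latency",
    "pooled_counts",
    "area_latency",
    "projection_latency",
    "kinematic_onset",
    "tongue_onset",
]


@dataclass
class LatencyResult:
    latency_ms: float | None
    direction: str | None          # "up" or "down"
    t_p001_ms: float | None        # first alpha = 0.001 crossing
    baseline_rate: float
    n_trials: int
    reason: str = ""               # why latency is absent, if it is


def pooled_counts(spike_times: np.ndarray, trial_go_times: Sequence[float],
                  window: tuple[float, float], bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts per peri-cue bin summed over trials (half-open bins).

    Returns (bin_start_times_ms, counts)."""
    bin_s = bin_ms * 1e-3
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = window[0] + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for tg in trial_go_times:
        rel = spike_times - tg
        sel = rel[(rel >= edges[0]) & (rel < edges[-1])]
        if sel.size:
            counts += np.bincount(((sel - edges[0]) // bin_s).astype(int),
                                  minlength=n_bins)[:n_bins]
    return edges[:-1] * 1e3, counts


def _poisson_two_sided_p(counts: np.ndarray, mu: float) -> np.ndarray:
    """Exact two-sided Poisson tail probability per bin, p = 2*min(tails)."""
    lower = stats.poisson.cdf(counts, mu)
    upper = stats.poisson.sf(counts - 1, mu)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def neuron_go_latency(
    counts: np.ndarray,
    bin_times_ms: np.ndarray,
    n_trials: int,
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
    search_window_ms: tuple[float, float] = (0.0, 200.0),
    alpha1: float = 0.001,
    alpha2: float = 0.05,
    bin_ms: float = 1.0,
    rule: str = "run_start",
) -> LatencyResult:
    """Two-step Poisson latency on pooled per-bin spike counts.

    ``counts`` are spikes per ``bin_ms`` bin summed across trials and
    ``bin_times_ms`` the bin start times relative to the go cue.  The
    baseline rate comes from the pre-cue window; each post-cue bin is tested
    two-sided against Poisson(baseline_rate * n_trials * bin width).
    T_p001 is the first bin with p < alpha1; the latency is then pulled back
    through the contiguous run of bins with p < alpha2 that contains T_p001
    (``rule="run_start"``), or, with ``rule="last_crossing"``, set to the
    last bin at or before T_p001 at which p first drops below alpha2 after
    being above it (the literal "last crossing" reading).
    """
    counts = np.asarray(counts, float)
    bin_times_ms = np.asarray(bin_times_ms, float)
    if rule not in ("run_start", "last_crossing"):
        raise ValueError(f"unknown rule {rule!r}")

    bmask = (bin_times_ms >= baseline_window_ms[0]) & (bin_times_ms < baseline_window_ms[1])
    if not bmask.any():
        raise ValueError("baseline window outside provided bins")
    base_count = counts[bmask].sum()
    base_dur_s = bmask.sum() * bin_ms * 1e-3
    baseline_rate = base_count / (base_dur_s * n_trials)

    # post-cue bins (T_go, T_search]: a bin starting at T_go covers times > T_go
    smask = (bin_times_ms >= search_window_ms[0]) & (bin_times_ms < search_window_ms[1])
    idx = np.flatnonzero(smask)
    if idx.size == 0:
        raise ValueError("search window outside provided bins")
    mu = baseline_rate * n_trials * bin_ms * 1e-3

    if mu == 0.0:
        # zero baseline: a down response is undetectable
        p = stats.poisson.sf(counts[idx] - 1, 1e-12)  # any spike is significant
        up_hit = counts[idx] > 0
        if not up_hit.any():
            return LatencyResult(None, None, None, baseline_rate, n_trials,
                                 reason="zero baseline and no post-cue spikes")
        first = idx[np.argmax(up_hit)]
        t = float(bin_times_ms[first])
        return LatencyResult(t, "up", t, baseline_rate, n_trials)

    p = _poisson_two_sided_p(counts[idx], mu)
    sig1 = p < alpha1
    if not sig1.any():
        return LatencyResult(None, None, None, baseline_rate, n_trials,
                             reason="no alpha1 crossing in search window")
    k1 = int(np.argmax(sig1))
    t_p001 = float(bin_times_ms[idx[k1]])
    direction = "up" if counts[idx[k1]] > mu else "down"
    if direction == "down" and baseline_rate == 0.0:
        return LatencyResult(None, None, t_p001, baseline_rate, n_trials,
                             reason="down response with zero baseline")

    sig2 = p < alpha2
    if rule == "run_start":
        j = k1
        while j > 0 and sig2[j - 1]:
            j -= 1
        latency = float(bin_times_ms[idx[j]])
    else:  # last_crossing: latest above->below alpha2 transition in (T_go, T_p001]
        j = k1
        for m in range(k1, 0, -1):
            if sig2[m] and not sig2[m - 1]:
                j = m
                break
        else:
            j = 0 if sig2[0] else k1
        latency = float(bin_times_ms[idx[j]])
    return LatencyResult(latency, direction, t_p001, baseline_rate, n_trials)


def area_latency(
    results: Sequence[LatencyResult],
    fraction: float = 0.01,
    direction: str = "up",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Area-level latency: earliest time by which ``fraction`` of all
    analyzed cells show a spike-rate change in ``direction``.

    Non-responders stay in the denominator.  SEM comes from resampling cells
    with replacement ``n_boot`` times; draws are returned for ordering tests.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    lats = np.array([r.latency_ms if (r.latency_ms is not None and r.direction == direction)
                     else np.nan for r in results])
    n = len(lats)
    if n == 0:
        raise ValueError("no latency results supplied")

    def point(lat_arr: np.ndarray) -> float:
        need = int(np.ceil(fraction * len(lat_arr)))
        vals = np.sort(lat_arr[np.isfinite(lat_arr)])
        if len(vals) < need:
            return np.nan
        return float(vals[need - 1])

    est = point(lats)
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = point(lats[rng.integers(0, n, n)])
    ok = np.isfinite(draws)
    out = {
        "latency_ms": est if np.isfinite(est) else None,
        "sem": float(np.nanstd(draws[ok])) if ok.any() else None,
        "draws": draws,
        "n_cells": n,
        "n_responders": int(np.isfinite(lats).sum()),
    }
    if not np.isfinite(est):
        out["reason"] = f"fewer than {fraction:.0%} of cells responded"
    return out


def _causal_boxcar(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    xp = np.concatenate([np.full(k - 1, x[0]), x])
    return np.convolve(xp, np.ones(k) / k, mode="valid")


def projection_latency(
    values: np.ndarray,
    time: np.ndarray,
    baseline_window: tuple[float, float] = (-0.1, 0.0),
    hi: float = 5.0,
    lo: float = 2.0,
    smooth_s: float = 0.010,
    search_window: tuple[float, float] = (0.0, 0.2),
) -> float | None:
    """Latency of a population projection by the 5-sigma / 2-sigma rule.

    The trace is causally boxcar-smoothed (10 ms default), standardized by
    the pre-cue baseline mean/SD, and scanned for the first post-cue bin with
    |z| >= hi (T_std5); the latency (ms) is the earliest bin of the
    contiguous |z| >= lo run containing T_std5.  Returns None if the trace
    never reaches the hi threshold.
    """
    values = np.asarray(values, float)
    time = np.asarray(time, float)
    dt = time[1] - time[0]
    sm = _causal_boxcar(values, max(1, int(round(smooth_s / dt))))
    bmask = (time >= baseline_window[0]) & (time < baseline_window[1])
    mu, sd = sm[bmask].mean(), sm[bmask].std()
    if sd == 0:
        raise ValueError("zero baseline SD: trace cannot be standardized")
    z = np.abs((sm - mu) / sd)
    idx = np.flatnonzero((time > search_window[0]) & (time <= search_window[1]))
    hi_hits = z[idx] >= hi
    if not hi_hits.any():
        return None
    k = int(np.argmax(hi_hits))
    lo_hits = z[idx] >= lo
    j = k
    while j > 0 and lo_hits[j - 1]:
        j -= 1
    return float(time[idx[j]] * 1e3)


def _resample_hierarchy(rng: np.random.Generator, hierarchy: np.ndarray | None,
                        n: int) -> np.ndarray:
    """Indices of a bootstrap draw: flat over trials, or animal -> session ->
    trial when a (n, 2) hierarchy label array is given."""
    if hierarchy is None:
        return rng.integers(0, n, n)
    animals = np.unique(hierarchy[:, 0])
    picked_animals = rng.choice(animals, size=len(animals), replace=True)
    out = []
    for a in picked_animals:
        sess = np.unique(hierarchy[hierarchy[:, 0] == a, 1])
        for s in rng.choice(sess, size=len(sess), replace=True):
            rows = np.flatnonzero((hierarchy[:, 0] == a) & (hierarchy[:, 1] == s))
            out.append(rows[rng.integers(0, len(rows), len(rows))])
    return np.concatenate(out)


def kinematic_onset(
    traces: np.ndarray,
    time: np.ndarray,
    detrend_window: tuple[float, float] = (-0.6, 0.0),
    baseline_window_s: float = 0.1,
    k: float = 3.0,
    n_boot: int = 1000,
    seed: int = 0,
    hierarchy: np.ndarray | None = None,
) -> dict:
    """Movement onset from a kinematic trace ensemble (trials x samples).

    Per bootstrap draw: resample trials (hierarchically if labels given),
    average, linearly detrend using a fit on ``detrend_window`` (late delay),
    and report the first post-cue sample whose absolute detrended excursion
    exceeds ``k`` times the SD of the pre-cue baseline (last
    ``baseline_window_s`` before the cue).  Returns mean/SEM over draws (ms).
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    time = np.asarray(time, float)
    n = traces.shape[0]
    dmask = (time >= detrend_window[0]) & (time < detrend_window[1])
    bmask = (time >= -baseline_window_s) & (time < 0.0)
    post = np.flatnonzero(time >= 0.0)
    rng = np.random.Generator(np.random.PCG64(int(seed)))

    def onset_of(mean_trace: np.ndarray) -> float:
        coef = np.polyfit(time[dmask], mean_trace[dmask], 1)
        det = mean_trace - np.polyval(coef, time)
        sd = det[bmask].std()
        # flat (or numerically flat) baseline: no detectable event
        if sd <= 1e-9 * max(1.0, np.abs(det).max()):
            return np.nan
        hits = np.abs(det[post]) > k * sd
        if not hits.any():
            return np.nan
        return float(time[post[np.argmax(hits)]] * 1e3)

    draws = np.empty(n_boot)
    for b in range(n_boot):
        rows = _resample_hierarchy(rng, hierarchy, n)
        draws[b] = onset_of(traces[rows].mean(axis=0))
    ok = np.isfinite(draws)
    if not ok.any():
        return {"onset_ms": None, "sem": None, "draws": draws,
                "reason": "no threshold crossing in any draw"}
    return {"onset_ms": float(draws[ok].mean()), "sem": float(draws[ok].std()),
            "draws": draws, "n_detected": int(ok.sum())}


def tongue_onset(
    times_cond: np.ndarray,
    times_null: np.ndarray,
    threshold: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    hierarchy_cond: np.ndarray | None = None,
    hierarchy_null: np.ndarray | None = None,
    grid_ms: float = 1.0,
    t_max_ms: float = 1000.0,
) -> dict:
    """Movement onset from first-detection-time c.d.f. difference.

    The empirical c.d.f. of first tongue-detection times (NaN = never
    detected; those trials stay in the denominator) for the condition of
    interest minus the c.d.f. for the null (go-cue-omitted) condition; onset
    is the first grid time at which the difference exceeds ``threshold``.
    Hierarchical bootstrap gives mean and SEM (ms).
    """
    times_cond = np.asarray(times_cond, float)
    times_null = np.asarray(times_null, float)
    grid = np.arange(0.0, t_max_ms + grid_ms, grid_ms) * 1e-3
    rng = np.random.Generator(np.random.PCG64(int(seed)))

    def cdf(samples: np.ndarray) -> np.ndarray:
        if len(samples) == 0:
            return np.zeros_like(grid)
        finite = samples[np.isfinite(samples)]
        return np.searchsorted(np.sort(finite), grid, side="right") / len(samples)

    def onset_of(tc: np.ndarray, tn: np.ndarray) -> float:
        diff = cdf(tc) - cdf(tn)
        hits = diff > threshold
        if not hits.any():
            return np.nan
        return float(grid[np.argmax(hits)] * 1e3)

    est = onset_of(times_cond, times_null)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        rc = _resample_hierarchy(rng, hierarchy_cond, len(times_cond))
        rn = (_resample_hierarchy(rng, hierarchy_null, len(times_null))
              if len(times_null) else np.empty(0, int))
        draws[b] = onset_of(times_cond[rc], times_null[rn] if len(times_null) else times_null)
    ok = np.isfinite(draws)
    out = {"onset_ms": est if np.isfinite(est) else None,
           "mean_ms": float(draws[ok].mean()) if ok.any() else None,
           "sem": float(draws[ok].std()) if ok.any() else None,
           "draws": draws}
    if not np.isfinite(est):
        out["reason"] = "c.d.f. difference never exceeds threshold"
    return out
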