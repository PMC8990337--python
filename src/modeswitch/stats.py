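"""Resampling inference, selectivity tests, decoding, correlation structure,
regression, and auxiliary quantifications.

The central tool is the three-level hierarchical bootstrap: animals are
resampled with replacement, then sessions within each sampled animal, then
trials within each sampled session.  This respects the nesting of the data
(trials within sessions within animals) that a flat trial bootstrap would
ignore.  All bootstrap loops default to 1,000 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BootstrapResult",
    "hierarchical_bootstrap",
    "epoch_selectivity_test",
    "roc_decode",
    "population_vector_correlation",
    "trial_mode_correlation",
    "go_response_amplitude",
    "logit_lick_model",
    "sinusoidal_modulation",
    "density_map",
    "lda_boundary",
    "response_rate",
]


@dataclass
class BootstrapResult:
    point_estimate: float
    draws: np.ndarray
    ci_low: float
    ci_high: float
    p_value: float | None
    n_iter: int
    seed: int
    hierarchy_spec: str
    n_failed_draws: int = 0


def hierarchical_bootstrap(
    data: Mapping[str, Mapping[str, np.ndarray]],
    statistic: Callable[[np.ndarray], float],
    n_iter: int = 1000,
    seed: int = 0,
    null_value: float | None = None,
    alternative: str = "greater",
    max_failed_fraction: float = 0.05,
) -> BootstrapResult:
    """Three-level (animal -> session -> trial) bootstrap of a statistic.

    ``data`` maps animal id -> session id -> array of per-trial values (1-D,
    or 2-D with trials as rows).  Each iteration resamples animals with
    replacement, then sessions of each sampled animal, then trials within
    each sampled session; ``statistic`` is evaluated on the concatenated
    resampled rows.

    The one-sided p-value tests the null stated by ``alternative``: with
    ``"greater"`` the alternative is statistic > null_value, and p is the
    fraction of draws <= null_value (floored at 1/n_iter).  A draw on which
    the statistic raises is rejected and counted; more than
    ``max_failed_fraction`` failures aborts.
    """
    animals = sorted(data.keys())
    if not animals:
        raise ValueError("empty hierarchy")
    sessions = {a: sorted(data[a].keys()) for a in animals}
    arrays = {a: {s: np.atleast_1d(np.asarray(data[a][s])) for s in sessions[a]} for a in animals}

    rng = np.random.Generator(np.random.PCG64(int(seed)))
    point = statistic(np.concatenate([arrays[a][s] for a in animals for s in sessions[a]]))

    draws = np.empty(n_iter)
    n_failed = 0
    max_failed = int(max_failed_fraction * n_iter)
    b = 0
    while b < n_iter:
        parts = []
        for a in rng.choice(animals, size=len(animals), replace=True):
            sess = sessions[a]
            for s in rng.choice(sess, size=len(sess), replace=True):
                arr = arrays[a][s]
                parts.append(arr[rng.integers(0, arr.shape[0], arr.shape[0])])
        sample = np.concatenate(parts)
        try:
            draws[b] = statistic(sample)
        except Exception:
            n_failed += 1
            if n_failed > max_failed:
                raise RuntimeError(
                    f"statistic failed on {n_failed} bootstrap draws (cap {max_failed})")
            continue
        b += 1

    ci_low, ci_high = np.percentile(draws, [2.5, 97.5])
    p = None
    if null_value is not None:
        if alternative == "greater":
            frac = np.mean(draws <= null_value)
        elif alternative == "less":
            frac = np.mean(draws >= null_value)
        else:
            raise ValueError("alternative must be 'greater' or 'less'")
        p = max(float(frac), 1.0 / n_iter)
    return BootstrapResult(point_estimate=float(point), draws=draws,
                           ci_low=float(ci_low), ci_high=float(ci_high),
                           p_value=p, n_iter=n_iter, seed=seed,
                           hierarchy_spec="animal>session>trial",
                           n_failed_draws=n_failed)


def epoch_selectivity_test(
    counts_right: np.ndarray,
    counts_left: np.ndarray,
    n_sub: int = 40,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Two-sided rank-sum test of per-trial spike counts, lick-right vs
    lick-left, on a random ``n_sub``-trial subsample per type.

    Returns p-value, preferred direction (side with the larger mean count),
    and the selectivity flag at ``alpha``.
    """
    counts_right = np.asarray(counts_right, float)
    counts_left = np.asarray(counts_left, float)
    if len(counts_right) < n_sub or len(counts_left) < n_sub:
        raise ValueError(f"need >= {n_sub} trials per type")
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    r = counts_right[rng.choice(len(counts_right), n_sub, replace=False)]
    l = counts_left[rng.choice(len(counts_left), n_sub, replace=False)]
    res = sps.mannwhitneyu(r, l, alternative="two-sided", method="auto")
    return {
        "p_value": float(res.pvalue),
        "preferred_direction": "lick_right" if r.mean() >= l.mean() else "lick_left",
        "selective": bool(res.pvalue < alpha),
    }


def roc_decode(projections: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """AUC per time bin for discriminating the two trial types from
    single-trial projections (trials x bins; labels boolean/0-1).

    AUC is the Mann-Whitney U statistic scaled by n1*n2, ties mid-ranked.
    """
    from sklearn.metrics import roc_auc_score

    proj = np.atleast_2d(np.asarray(projections, float))
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("need both labels present")
    if proj.ndim == 2 and proj.shape[0] != len(y):
        raise ValueError("projections and labels disagree on trial count")
    return np.array([roc_auc_score(y, proj[:, b]) for b in range(proj.shape[1])])


def population_vector_correlation(psth, mode: str = "selectivity",
                                  condition: str | None = None) -> np.ndarray:
    """Time x time Pearson correlation matrix of the population vector.

    ``mode="selectivity"`` correlates the selectivity vector w_t across time
    points; ``mode="within_type"`` correlates the condition PSTH vector r_t
    (``condition`` picks the trial type, default averages the two).
    """
    from .modes import selectivity_vector

    if mode == "selectivity":
        x = selectivity_vector(psth)
    elif mode == "within_type":
        x = psth.condition(condition) if condition else psth.rates.mean(axis=2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    return np.corrcoef(x.T)


def trial_mode_correlation(
    proj_a: np.ndarray,
    proj_b: np.ndarray,
    shuffle_control: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Trial-by-trial Pearson correlation between two per-trial projection
    matrices (trials x bins_a, trials x bins_b), for every bin pair.

    With ``shuffle_control`` the trial pairing of ``proj_b`` is permuted,
    destroying shared trial-to-trial structure while keeping marginals.
    """
    a = np.atleast_2d(np.asarray(proj_a, float))
    b = np.atleast_2d(np.asarray(proj_b, float))
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] != b.shape[0]:
        raise ValueError("projections must use the same trial set")
    if shuffle_control:
        rng = np.random.Generator(np.random.PCG64(int(seed)))
        b = b[rng.permutation(b.shape[0])]
    az = (a - a.mean(0)) / a.std(0)
    bz = (b - b.mean(0)) / b.std(0)
    return az.T @ bz / a.shape[0]


def go_response_amplitude(psth, window_s: float = 0.1,
                          condition: str | None = None) -> np.ndarray:
    """Per-neuron cue-response amplitude: mean rate in (0, window) minus mean
    rate in (-window, 0), per trial type or pooled (spikes/s)."""
    r = psth.condition(condition) if condition else psth.rates.mean(axis=2)
    pre = psth.window_mask((-window_s, 0.0))
    post = psth.window_mask((0.0, window_s))
    return r[:, post].mean(axis=1) - r[:, pre].mean(axis=1)


def logit_lick_model(
    X: pd.DataFrame,
    licked: np.ndarray,
    hierarchy: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Logistic (logit) regression of lick outcome on per-trial activity
    covariates, with hierarchical-bootstrap confidence intervals.

    Maximum-likelihood binomial fit (statsmodels).  Complete separation is
    detected (perfect in-sample prediction or diverging coefficients) and
    reported in the ``separation`` flag.  ``hierarchy`` gives per-trial
    animal_id / session_id columns; without it the bootstrap is flat.
    """
    import statsmodels.api as sm

    y = np.asarray(licked).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("both outcome classes must be present")
    Xd = sm.add_constant(np.asarray(X, float), has_constant="add")
    names = ["const"] + list(X.columns)

    import warnings as _warnings

    def fit(Xm, ym, full=False):
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(ym, Xm).fit(disp=0, maxiter=100)
        return (res.params, bool(res.mle_retvals.get("converged", True))) if full else res.params

    params, converged = fit(Xd, y, full=True)
    pred = 1.0 / (1.0 + np.exp(-(Xd @ params)))
    perfect = bool(np.all((pred > 0.5) == (y == 1)))
    separation = perfect and (not converged or np.max(np.abs(params)) > 10.0)

    rng = np.random.Generator(np.random.PCG64(int(seed)))
    n = len(y)
    if hierarchy is not None:
        hier = np.column_stack([hierarchy["animal_id"].astype(str),
                                hierarchy["session_id"].astype(str)])
    else:
        hier = None
    from .latency import _resample_hierarchy

    draws = np.full((n_boot, len(params)), np.nan)
    n_failed = 0
    for b in range(n_boot):
        rows = _resample_hierarchy(rng, hier, n)
        yb = y[rows]
        if len(np.unique(yb)) < 2:
            n_failed += 1
            continue
        try:
            draws[b] = fit(Xd[rows], yb)
        except Exception:
            n_failed += 1
    ok = np.all(np.isfinite(draws), axis=1)
    ci = np.nanpercentile(draws[ok], [2.5, 97.5], axis=0) if ok.any() else np.full((2, len(params)), np.nan)
    return {
        "coefficients": dict(zip(names, params)),
        "ci_low": dict(zip(names, ci[0])),
        "ci_high": dict(zip(names, ci[1])),
        "separation": separation,
        "n_failed_draws": int(n_failed),
        "draws": draws,
        "names": names,
    }


def sinusoidal_modulation(rate: np.ndarray, time: np.ndarray, freq: float = 40.0
                          ) -> tuple[float, float]:
    """Amplitude and phase of the rate modulation at ``freq`` (Fourier
    coefficient of the mean peri-stimulus rate over an integer number of
    cycles).  Amplitude >= 0 (spikes/s), phase in (-pi, pi].
    """
    rate = np.asarray(rate, float)
    time = np.asarray(time, float)
    dt = time[1] - time[0]
    T = len(time) * dt
    n_cycles = T * freq
    if abs(n_cycles - round(n_cycles)) > 1e-6:
        raise ValueError("analysis window must span an integer number of cycles")
    c = 2.0 / len(time) * np.sum(rate * np.exp(-2j * np.pi * freq * time))
    amp = float(np.abs(c))
    phase = float(np.angle(c)) if amp > 0 else 0.0
    if phase <= -np.pi:
        phase += 2 * np.pi
    return amp, phase


def density_map(
    coords_um: np.ndarray,
    flags: np.ndarray,
    grid_extent_um: tuple[float, float, float, float],
    pixel_um: float = 10.0,
    gaussian_half_width_um: float = 250.0,
) -> dict:
    """Smoothed density of flagged neurons over a 2-D map.

    Per pixel: (Gaussian-smoothed flagged count) / (smoothed total count +
    0.05); the 0.05 regularizer keeps sparsely sampled pixels from exploding.
    The kernel's half-width at half-maximum is ``gaussian_half_width_um``.
    """
    coords = np.atleast_2d(np.asarray(coords_um, float))
    flags = np.asarray(flags, bool)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    x0, x1, y0, y1 = grid_extent_um
    xs = np.arange(x0, x1, pixel_um) + pixel_um / 2
    ys = np.arange(y0, y1, pixel_um) + pixel_um / 2
    sigma = gaussian_half_width_um / np.sqrt(2.0 * np.log(2.0))
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    total = np.zeros_like(gx)
    flagged = np.zeros_like(gx)
    for (cx, cy), fl in zip(coords, flags):
        k = np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))
        total += k
        if fl:
            flagged += k
    return {"x_um": xs, "y_um": ys, "density": flagged / (total + 0.05),
            "total": total, "flagged": flagged}


def lda_boundary(points: np.ndarray, labels: np.ndarray) -> dict:
    """Fisher LDA decision boundary for 2-D per-trial mode activity.

    Returns the discriminant direction w (pooled-covariance solution),
    threshold c (boundary: w . x = c), and slope/intercept of the boundary
    line in the (x, y) plane (slope None if the boundary is vertical).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    pts = np.asarray(points, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(pts, y)
    w = lda.coef_[0]
    c = -lda.intercept_[0]
    if abs(w[1]) < 1e-12 * max(1.0, abs(w[0])):
        return {"w": w, "threshold": float(c), "slope": None,
                "x_intercept": float(c / w[0])}
    return {"w": w, "threshold": float(c), "slope": float(-w[0] / w[1]),
            "intercept": float(c / w[1])}


def response_rate(trials, window_rel_delay: tuple[float, float] = (1.2, 1.8),
                  mode: str = "response") -> float:
    """Proportion of trials with the first lick inside the half-open window
    [T_delay + t0, T_delay + t1).

    ``mode="response"`` excludes early-lick trials and reports the lick
    probability; ``mode="correct"`` additionally excludes no-response trials
    and reports the fraction of in-window first licks in the instructed
    direction.
    """
    t0, t1 = window_rel_delay
    if mode == "response":
        pool = [t for t in trials if t.outcome != "early_lick"]
        if not pool:
            return np.nan
        hits = sum(
            1 for t in pool
            if t.first_lick_time is not None
            and t.t_delay_on + t0 <= t.first_lick_time < t.t_delay_on + t1
        )
        return hits / len(pool)
    if mode == "correct":
        pool = [
            t for t in trials
            if t.outcome not in ("early_lick", "no_response")
            and t.first_lick_time is not None
            and t.t_delay_on + t0 <= t.first_lick_time < t.t_delay_on + t1
        ]
        if not pool:
            return np.nan
        return sum(1 for t in pool if t.first_lick_direction == t.type) / len(pool)
    raise ValueError(f"unknown mode {mode!r}")
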