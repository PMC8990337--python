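"""Activity-mode estimation in neural state space.

With n recorded neurons, trial-averaged activity is a trajectory in
n-dimensional state space.  The modes here are subtraction-defined unit
vectors:

* ``CD_delay``  — mean selectivity vector w_t = r_right - r_left over the
  last 600 ms of the delay epoch, normalized: the direction carrying
  preparatory (plan) selectivity.
* ``CD_response`` — mean w_t over the first 400 ms after the go cue,
  Gram-Schmidt-orthogonalized to CD_delay: the movement-command direction.
* ``D_go``   — post-cue minus pre-cue mean of the trial-type-averaged
  activity (100 ms windows): the condition-invariant cue response.
* ``D_ramp`` — pre-cue minus pre-trial mean: non-selective ramping.
* ``D_stim`` — stimulation minus cue-omitted post-stimulus mean.

Modes are estimated on a random half of unperturbed correct trials and
applied to the held-out half, so projections are never evaluated on the
trials that defined the direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import InsufficientTrialsError, PSTHMatrix, Trial, TRIAL_TYPES

__all__ = [
    "ModeVector",
    "ProjectionTrace",
    "Normalization",
    "DegenerateModeError",
    "selectivity_vector",
    "compute_cd_delay",
    "compute_cd_response",
    "compute_d_go",
    "compute_d_ramp",
    "compute_d_stim",
    "orthogonalize_set",
    "project",
    "fit_normalization",
    "normalize_projection",
    "split_train_test",
    "build_pseudopopulation",
    "selectivity_explained",
    "activity_explained",
    "mode_angle",
]

UNIT_NORM_TOL = 1e-12


class DegenerateModeError(ValueError):
    """The defining vector has (numerically) zero norm or is linearly
    dependent on an earlier mode."""


def _degenerate(v: np.ndarray) -> bool:
    # scale-free zero test: norm below 1e-9 * sqrt(n)
    return float(np.linalg.norm(v)) < 1e-9 * np.sqrt(v.size)


@dataclass
class ModeVector:
    weights: np.ndarray
    neuron_ids: list[str]
    kind: str
    defining_window: tuple[float, float] | None = None
    defining_trials: object = None
    orthogonalized_against: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if len(self.neuron_ids) != self.weights.size:
            raise ValueError("neuron_ids must match weight length")
        if abs(np.linalg.norm(self.weights) - 1.0) > 1e-6:
            raise ValueError("mode weights must be unit-norm")


@dataclass
class ProjectionTrace:
    values: np.ndarray           # (n_bins, n_conditions) or (n_trials,) / (n_trials, n_bins)
    mode_kind: str
    time: np.ndarray | None = None
    condition_labels: list[str] | None = None
    normalization: str = "raw"


@dataclass
class Normalization:
    """Affine anchors fitted on training-trial condition means and applied
    unchanged to held-out trials: x -> (x - offset) / scale."""

    mode_kind: str
    offset: float
    scale: float

    def apply(self, trace: ProjectionTrace) -> ProjectionTrace:
        return ProjectionTrace(values=(trace.values - self.offset) / self.scale,
                               mode_kind=trace.mode_kind, time=trace.time,
                               condition_labels=trace.condition_labels,
                               normalization="paper_scheme")


def _unitize(v: np.ndarray, kind: str) -> np.ndarray:
    if _degenerate(v):
        raise DegenerateModeError(f"{kind}: defining vector has zero norm")
    return v / np.linalg.norm(v)


def selectivity_vector(psth: PSTHMatrix) -> np.ndarray:
    """w_t = r_lick_right - r_lick_left, (n_neurons, n_bins), exact subtraction."""
    for lbl in TRIAL_TYPES:
        if lbl not in psth.condition_labels:
            raise ValueError(f"PSTH lacks condition {lbl!r}")
    return psth.condition("lick_right") - psth.condition("lick_left")


def _window_mean(psth: PSTHMatrix, x: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = psth.window_mask(window)
    if not mask.any():
        raise ValueError(f"window {window} outside PSTH time base")
    return x[:, mask].mean(axis=1)


def compute_cd_delay(psth: PSTHMatrix, window: tuple[float, float] = (-0.6, 0.0)) -> ModeVector:
    """Delay coding direction: mean selectivity over the last 600 ms of the
    delay epoch, unit-normalized."""
    w = _window_mean(psth, selectivity_vector(psth), window)
    return ModeVector(_unitize(w, "CD_delay"), list(psth.neuron_ids), "CD_delay",
                      defining_window=window)


def compute_cd_response(
    psth: PSTHMatrix,
    window: tuple[float, float] = (0.0, 0.4),
    cd_delay: ModeVector | None = None,
    orthogonalize: bool = True,
) -> ModeVector:
    """Response coding direction; by default Gram-Schmidt-orthogonalized to
    CD_delay so it isolates selectivity that emerges after the cue."""
    w = _window_mean(psth, selectivity_vector(psth), window)
    ortho: list[str] = []
    if orthogonalize:
        if cd_delay is None:
            raise ValueError("orthogonalization requires cd_delay")
        if cd_delay.neuron_ids != list(psth.neuron_ids):
            raise ValueError("CD_delay neuron set differs from PSTH")
        w = w - (w @ cd_delay.weights) * cd_delay.weights
        ortho = ["CD_delay"]
        if _degenerate(w):
            raise DegenerateModeError("CD_response: parallel to CD_delay")
    return ModeVector(_unitize(w, "CD_response"), list(psth.neuron_ids), "CD_response",
                      defining_window=window, orthogonalized_against=ortho)


def compute_d_go(
    psth: PSTHMatrix,
    pre_window: tuple[float, float] = (-0.1, 0.0),
    post_window: tuple[float, float] = (0.0, 0.1),
) -> ModeVector:
    """Go direction: post-cue minus pre-cue mean of the across-type average."""
    mean_act = psth.rates.mean(axis=2)
    v = _window_mean(psth, mean_act, post_window) - _window_mean(psth, mean_act, pre_window)
    return ModeVector(_unitize(v, "D_go"), list(psth.neuron_ids), "D_go",
                      defining_window=post_window)


def compute_d_ramp(
    psth: PSTHMatrix,
    pre_trial_window: tuple[float, float],
    pre_cue_window: tuple[float, float] = (-0.1, 0.0),
) -> ModeVector:
    """Ramping direction: pre-cue (0.1 s) minus pre-trial (0.6 s) mean of the
    across-type average."""
    mean_act = psth.rates.mean(axis=2)
    v = _window_mean(psth, mean_act, pre_cue_window) - _window_mean(psth, mean_act, pre_trial_window)
    return ModeVector(_unitize(v, "D_ramp"), list(psth.neuron_ids), "D_ramp",
                      defining_window=pre_cue_window)


def compute_d_stim(
    psth_omitted: PSTHMatrix,
    psth_stim: PSTHMatrix,
    window: tuple[float, float] = (0.0, 0.1),
) -> ModeVector:
    """Stimulation direction: stimulation minus cue-omitted post-stimulus mean."""
    if psth_omitted.neuron_ids != psth_stim.neuron_ids:
        raise ValueError("condition PSTHs must share the neuron set")
    a = _window_mean(psth_stim, psth_stim.rates.mean(axis=2), window)
    b = _window_mean(psth_omitted, psth_omitted.rates.mean(axis=2), window)
    return ModeVector(_unitize(a - b, "D_stim"), list(psth_stim.neuron_ids), "D_stim",
                      defining_window=window)


def orthogonalize_set(modes: Sequence[ModeVector], order: Sequence[str] | None = None
                      ) -> list[ModeVector]:
    """Sequential Gram-Schmidt in the given order (default: input order).

    The first mode is unchanged; each later mode has its projections on all
    earlier ones removed and is renormalized.  Linear dependence raises
    :class:`DegenerateModeError` naming the offending mode.
    """
    by_kind = {m.kind: m for m in modes}
    kinds = list(order) if order is not None else [m.kind for m in modes]
    if set(kinds) != set(by_kind):
        raise ValueError("order must be a permutation of the mode kinds")
    ids = modes[0].neuron_ids
    for m in modes:
        if m.neuron_ids != ids:
            raise ValueError("all modes must share the neuron set")

    basis: list[np.ndarray] = []
    out: list[ModeVector] = []
    for kind in kinds:
        v = by_kind[kind].weights.copy()
        for b in basis:
            v -= (v @ b) * b
        if _degenerate(v):
            raise DegenerateModeError(f"{kind}: linearly dependent on earlier modes")
        v /= np.linalg.norm(v)
        basis.append(v)
        out.append(ModeVector(v, list(ids), kind,
                              defining_window=by_kind[kind].defining_window,
                              defining_trials=by_kind[kind].defining_trials,
                              orthogonalized_against=kinds[: kinds.index(kind)]))
    return out


def project(rates: PSTHMatrix | np.ndarray, mode: ModeVector) -> ProjectionTrace:
    """Inner product of activity with the mode, per time bin / per trial.

    Accepts a :class:`PSTHMatrix` (returns bins x conditions) or a
    (trials x neurons) array (returns one value per trial).
    """
    if isinstance(rates, PSTHMatrix):
        if list(rates.neuron_ids) != mode.neuron_ids:
            raise ValueError("neuron sets do not align")
        vals = np.einsum("ntc,n->tc", rates.rates, mode.weights)
        return ProjectionTrace(values=vals, mode_kind=mode.kind, time=rates.time,
                               condition_labels=list(rates.condition_labels))
    arr = np.asarray(rates, float)
    if arr.shape[-1] != mode.weights.size:
        raise ValueError("neuron sets do not align")
    return ProjectionTrace(values=arr @ mode.weights, mode_kind=mode.kind)


_NORM_WINDOWS = {"CD_delay": (-0.1, 0.0), "CD_response": (0.0, 0.4)}


def fit_normalization(
    train_trace: ProjectionTrace,
    mode_kind: str,
    dgo_windows: tuple[tuple[float, float], tuple[float, float]] = ((-0.1, 0.0), (0.0, 0.1)),
    tol: float = 1e-9,
) -> Normalization:
    """Fit the pooling scheme's affine anchors on training condition means.

    CD modes: lick-left window mean -> 0, lick-right -> 1 (window (-0.1, 0)
    for CD_delay, (0, 0.4) for CD_response).  D_go: pre-cue mean -> 0 and the
    pre-to-post change (100 ms windows) -> 1.
    """
    t = train_trace.time
    if t is None or train_trace.condition_labels is None:
        raise ValueError("normalization needs a condition-resolved trace with a time base")
    vals = train_trace.values

    def wmean(col: np.ndarray, window: tuple[float, float]) -> float:
        mask = (t >= window[0]) & (t < window[1])
        if not mask.any():
            raise ValueError(f"window {window} outside trace")
        return float(col[mask].mean())

    if mode_kind in _NORM_WINDOWS:
        win = _NORM_WINDOWS[mode_kind]
        left = wmean(vals[:, train_trace.condition_labels.index("lick_left")], win)
        right = wmean(vals[:, train_trace.condition_labels.index("lick_right")], win)
        scale = right - left
        if abs(scale) < tol:
            raise DegenerateModeError(f"{mode_kind}: normalization anchor denominator ~ 0")
        return Normalization(mode_kind, offset=left, scale=scale)
    if mode_kind == "D_go":
        pre_w, post_w = dgo_windows
        mean_trace = vals.mean(axis=1)
        pre = wmean(mean_trace, pre_w)
        post = wmean(mean_trace, post_w)
        if abs(post - pre) < tol:
            raise DegenerateModeError("D_go: normalization anchor denominator ~ 0")
        return Normalization(mode_kind, offset=pre, scale=post - pre)
    raise ValueError(f"no normalization scheme for mode kind {mode_kind!r}")


def normalize_projection(trace: ProjectionTrace, norm: Normalization) -> ProjectionTrace:
    return norm.apply(trace)


def split_train_test(
    trials: Sequence[Trial], fraction: float = 0.5, seed: int = 0
) -> tuple[list[Trial], list[Trial]]:
    """Disjoint, type-balanced split of unperturbed correct trials into
    mode-defining and projection halves.  Deterministic given seed."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    train: list[Trial] = []
    test: list[Trial] = []
    for ty in TRIAL_TYPES:
        pool = [t for t in trials if t.type == ty and t.outcome == "correct"
                and t.perturbation == "none"]
        if len(pool) < 2:
            raise InsufficientTrialsError(f"fewer than 2 unperturbed correct {ty} trials")
        n_train = int(round(fraction * len(pool)))
        n_train = min(max(n_train, 1), len(pool) - 1)
        perm = rng.permutation(len(pool))
        train.extend(pool[i] for i in perm[:n_train])
        test.extend(pool[i] for i in perm[n_train:])
    key = lambda t: t.trial_index
    return sorted(train, key=key), sorted(test, key=key)


def build_pseudopopulation(
    unit_trials: Sequence[tuple],
    n_cells: int,
    trials_per_type: int = 20,
    seed: int = 0,
    psth_fn=None,
):
    """Pool cells across sessions into a pseudopopulation PSTH pair.

    ``unit_trials`` is a sequence of (session, unit, trials) triples where
    ``trials`` are that unit's unperturbed correct trials.  Cells with fewer
    than 2 * trials_per_type correct trials per lick direction are excluded
    (logged, not fatal).  For each sampled cell (with replacement) a disjoint
    train/test set of ``trials_per_type`` trials per type is drawn; the
    caller's ``psth_fn(session, trials, units=[unit])`` computes the per-cell
    PSTH.  Returns (train PSTHMatrix, test PSTHMatrix, exclusion_log).

    Call repeatedly with different seeds for the resampling loop.
    """
    from .core import compute_psth

    if psth_fn is None:
        psth_fn = lambda session, trials, units: compute_psth(
            session, trials, align="go", window=(-3.0, 1.0), bin_width=0.01,
            smoothing="boxcar_centered_100ms", units=units)

    rng = np.random.Generator(np.random.PCG64(int(seed)))
    eligible = []
    excluded = []
    for session, unit, trials in unit_trials:
        ok = all(
            sum(1 for t in trials if t.type == ty and t.outcome == "correct"
                and t.perturbation == "none") >= 2 * trials_per_type
            for ty in TRIAL_TYPES
        )
        if ok:
            eligible.append((session, unit, trials))
        else:
            excluded.append(unit.unit_id)
    if not eligible:
        raise InsufficientTrialsError("no eligible cells for pseudopopulation")

    picks = rng.integers(0, len(eligible), size=n_cells)
    train_stack, test_stack = [], []
    time = None
    ids = []
    for j, pick in enumerate(picks):
        session, unit, trials = eligible[pick]
        tr_train, tr_test = [], []
        for ty in TRIAL_TYPES:
            pool = [t for t in trials if t.type == ty and t.outcome == "correct"
                    and t.perturbation == "none"]
            idx = rng.choice(len(pool), size=2 * trials_per_type, replace=False)
            tr_train.extend(pool[i] for i in idx[:trials_per_type])
            tr_test.extend(pool[i] for i in idx[trials_per_type:])
        p_train = psth_fn(session, tr_train, [unit])
        p_test = psth_fn(session, tr_test, [unit])
        train_stack.append(p_train.rates[0])
        test_stack.append(p_test.rates[0])
        time = p_train.time
        ids.append(f"cell{j:04d}:{unit.unit_id}")

    proto = psth_fn(eligible[0][0], [t for t in eligible[0][2]
                                     if t.outcome == "correct"][:2], [eligible[0][1]])
    train = PSTHMatrix(rates=np.stack(train_stack), time=time, bin_width=proto.bin_width,
                       smoothing=proto.smoothing, alignment=proto.alignment,
                       condition_labels=list(proto.condition_labels), neuron_ids=ids)
    test = PSTHMatrix(rates=np.stack(test_stack), time=time, bin_width=proto.bin_width,
                      smoothing=proto.smoothing, alignment=proto.alignment,
                      condition_labels=list(proto.condition_labels), neuron_ids=ids)
    return train, test, excluded


def selectivity_explained(
    psth: PSTHMatrix, modes: Sequence[ModeVector], window: tuple[float, float] | None = None
) -> dict:
    """Fraction of squared population selectivity captured by each mode.

    Per time bin: (w_t . m)^2 / ||w_t||^2 per mode, plus the cumulative sum
    over modes.  Bins with zero total selectivity are NaN (flagged, not 0).
    Modes must be orthonormal for the cumulative fraction to be meaningful.
    """
    w = selectivity_vector(psth)
    mask = psth.window_mask(window) if window is not None else np.ones(len(psth.time), bool)
    w = w[:, mask]
    total = np.sum(w**2, axis=0)
    per_mode = {}
    for i, m in enumerate(modes):
        if m.neuron_ids != list(psth.neuron_ids):
            raise ValueError("mode neuron set differs from PSTH")
        num = (m.weights @ w) ** 2
        key = m.kind if m.kind not in per_mode else f"{m.kind}_{i}"
        per_mode[key] = np.where(total > 0, num / np.where(total > 0, total, 1.0), np.nan)
    cumulative = np.sum(list(per_mode.values()), axis=0)
    return {"time": psth.time[mask], "per_mode": per_mode, "cumulative": cumulative,
            "total_selectivity": total}


def activity_explained(
    psth: PSTHMatrix,
    modes: Sequence[ModeVector],
    baseline_window: tuple[float, float],
    window: tuple[float, float] | None = None,
) -> dict:
    """As :func:`selectivity_explained` with baseline-subtracted condition
    PSTHs in place of w_t, computed per trial type."""
    mask = psth.window_mask(window) if window is not None else np.ones(len(psth.time), bool)
    out = {"time": psth.time[mask], "per_condition": {}}
    for ci, lbl in enumerate(psth.condition_labels):
        r = psth.rates[:, :, ci]
        base = _window_mean(psth, r, baseline_window)
        x = (r - base[:, None])[:, mask]
        total = np.sum(x**2, axis=0)
        per_mode = {}
        for i, m in enumerate(modes):
            num = (m.weights @ x) ** 2
            key = m.kind if m.kind not in per_mode else f"{m.kind}_{i}"
            per_mode[key] = np.where(total > 0, num / np.where(total > 0, total, 1.0), np.nan)
        out["per_condition"][lbl] = {
            "per_mode": per_mode,
            "cumulative": np.sum(list(per_mode.values()), axis=0),
            "total_activity": total,
        }
    return out


def mode_angle(m1: ModeVector, m2: ModeVector) -> float:
    """Angle between two unit mode vectors, radians in [0, pi]."""
    if m1.neuron_ids != m2.neuron_ids:
        raise ValueError("modes must share the neuron set")
    return float(np.arccos(np.clip(m1.weights @ m2.weights, -1.0, 1.0)))
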