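"""Data model, I/O, unit/trial filtering, and PSTH construction.

Time convention: seconds; peri-cue analyses use t = 0 at go-cue onset; time
bins are half-open [t, t + dt) so every spike belongs to exactly one bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "Trial",
    "SessionData",
    "PSTHMatrix",
    "SessionFormatError",
    "MissingMetricError",
    "InsufficientTrialsError",
    "QUALITY_THRESHOLDS",
    "read_session",
    "write_session",
    "read_nwb_session",
    "filter_units",
    "select_trials",
    "compute_psth",
    "trial_rate_vectors",
]

TRIAL_TYPES = ("lick_right", "lick_left")
OUTCOMES = ("correct", "incorrect", "no_response", "early_lick")
PERTURBATIONS = ("none", "silencing", "stimulation", "go_omitted", "different_tone", "fake_cue")


class SessionFormatError(ValueError):
    """Malformed session file; message names the offending table/column."""


class MissingMetricError(ValueError):
    """A quality metric required by the active filter profile is missing."""


class InsufficientTrialsError(ValueError):
    """Not enough qualifying trials: the session/unit is ineligible, the
    caller decides whether to exclude it."""


@dataclass
class Unit:
    unit_id: str
    spike_times: np.ndarray  # seconds, session clock, sorted ascending
    area_label: str = ""
    depth_um: float = np.nan
    spike_width_ms: float = np.nan
    amplitude_uv: float = np.nan
    isi_violation: float = np.nan
    amplitude_cutoff: float = np.nan
    snr: float = np.nan
    presence_ratio: float = np.nan
    coordinates_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < 0):
                raise ValueError(f"unit {self.unit_id}: spike_times not sorted")
            if self.spike_times[0] < 0:
                raise ValueError(f"unit {self.unit_id}: negative spike time")


@dataclass
class Trial:
    trial_index: int
    type: str
    outcome: str
    t_sample_on: float
    t_delay_on: float
    t_go: float
    perturbation: str = "none"
    first_lick_time: float | None = None
    first_lick_direction: str | None = None

    def __post_init__(self) -> None:
        if self.type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.type!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if not (self.t_sample_on < self.t_delay_on < self.t_go):
            raise ValueError(
                f"trial {self.trial_index}: event order must be sample < delay < go"
            )


@dataclass
class SessionData:
    animal_id: str
    session_id: str
    units: list[Unit]
    trials: list[Trial]

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("unit_ids must be unique within a session")

    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]


@dataclass
class PSTHMatrix:
    """Trial-averaged (or per-trial) spike rates: neurons x time x conditions."""

    rates: np.ndarray          # (n_neurons, n_bins, n_conditions)
    time: np.ndarray           # bin centers, s relative to alignment event
    bin_width: float
    smoothing: str
    alignment: str
    condition_labels: list[str]
    neuron_ids: list[str]
    baseline_stats: np.ndarray | None = None  # (n_neurons, 2) mean/sd if z-scored
    valid_neurons: np.ndarray | None = None   # mask, False where z-scoring failed

    def __post_init__(self) -> None:
        dt = np.diff(self.time)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("time base must be strictly increasing and uniform")

    def condition(self, label: str) -> np.ndarray:
        return self.rates[:, :, self.condition_labels.index(label)]

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Bins whose centers fall in the half-open window [t0, t1)."""
        t0, t1 = window
        return (self.time >= t0) & (self.time < t1)


# ---------------------------------------------------------------------------
# Session format I/O: directory with units.csv, spikes.csv, trials.csv
# ---------------------------------------------------------------------------

def write_session(session: SessionData, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    urows = []
    for u in session.units:
        x, y = (u.coordinates_um if u.coordinates_um is not None else (np.nan, np.nan))
        urows.append(
            dict(unit_id=u.unit_id, area_label=u.area_label, depth_um=u.depth_um,
                 spike_width_ms=u.spike_width_ms, amplitude_uv=u.amplitude_uv,
                 isi_violation=u.isi_violation, amplitude_cutoff=u.amplitude_cutoff,
                 snr=u.snr, presence_ratio=u.presence_ratio, x_um=x, y_um=y)
        )
    pd.DataFrame(urows, columns=["unit_id", "area_label", "depth_um", "spike_width_ms",
                                 "amplitude_uv", "isi_violation", "amplitude_cutoff",
                                 "snr", "presence_ratio", "x_um", "y_um"]
                 ).to_csv(path / "units.csv", index=False, float_format="%.17g")

    sp = [(u.unit_id, t) for u in session.units for t in u.spike_times]
    pd.DataFrame(sp, columns=["unit_id", "spike_time"]).to_csv(
        path / "spikes.csv", index=False, float_format="%.17g")

    trows = []
    for t in session.trials:
        trows.append(
            dict(trial_index=t.trial_index, type=t.type, outcome=t.outcome,
                 t_sample_on=t.t_sample_on, t_delay_on=t.t_delay_on, t_go=t.t_go,
                 perturbation=t.perturbation,
                 first_lick_time=np.nan if t.first_lick_time is None else t.first_lick_time,
                 first_lick_direction="" if t.first_lick_direction is None else t.first_lick_direction)
        )
    pd.DataFrame(trows, columns=["trial_index", "type", "outcome", "t_sample_on",
                                 "t_delay_on", "t_go", "perturbation",
                                 "first_lick_time", "first_lick_direction"]
                 ).to_csv(path / "trials.csv", index=False, float_format="%.17g")

    meta = pd.DataFrame([dict(animal_id=session.animal_id, session_id=session.session_id)])
    meta.to_csv(path / "session.csv", index=False)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{table}: missing column(s) {missing}")


def read_session(path: str | Path) -> SessionData:
    path = Path(path)
    for fname in ("units.csv", "spikes.csv", "trials.csv", "session.csv"):
        if not (path / fname).exists():
            raise SessionFormatError(f"{fname}: file not found in {path}")
    units_df = pd.read_csv(path / "units.csv", dtype={"unit_id": str},
                           float_precision="round_trip")
    spikes_df = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str},
                            float_precision="round_trip")
    trials_df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    meta = pd.read_csv(path / "session.csv")

    _require_columns(units_df, ["unit_id", "spike_width_ms"], "units.csv")
    _require_columns(spikes_df, ["unit_id", "spike_time"], "spikes.csv")
    _require_columns(trials_df, ["trial_index", "type", "outcome",
                                 "t_sample_on", "t_delay_on", "t_go"], "trials.csv")

    by_unit = {uid: grp["spike_time"].to_numpy() for uid, grp in spikes_df.groupby("unit_id")}
    units = []
    for _, row in units_df.iterrows():
        coords = None
        if "x_um" in row and np.isfinite(row.get("x_um", np.nan)):
            coords = (float(row["x_um"]), float(row["y_um"]))
        units.append(
            Unit(unit_id=row["unit_id"],
                 spike_times=np.sort(by_unit.get(row["unit_id"], np.empty(0))),
                 area_label=str(row.get("area_label", "")),
                 depth_um=float(row.get("depth_um", np.nan)),
                 spike_width_ms=float(row["spike_width_ms"]),
                 amplitude_uv=float(row.get("amplitude_uv", np.nan)),
                 isi_violation=float(row.get("isi_violation", np.nan)),
                 amplitude_cutoff=float(row.get("amplitude_cutoff", np.nan)),
                 snr=float(row.get("snr", np.nan)),
                 presence_ratio=float(row.get("presence_ratio", np.nan)),
                 coordinates_um=coords)
        )
    trials = []
    for _, row in trials_df.iterrows():
        flt = row.get("first_lick_time", np.nan)
        fld = row.get("first_lick_direction", "")
        trials.append(
            Trial(trial_index=int(row["trial_index"]), type=row["type"],
                  outcome=row["outcome"], t_sample_on=float(row["t_sample_on"]),
                  t_delay_on=float(row["t_delay_on"]), t_go=float(row["t_go"]),
                  perturbation=str(row.get("perturbation", "none")),
                  first_lick_time=None if pd.isna(flt) else float(flt),
                  first_lick_direction=None if (pd.isna(fld) or fld == "") else str(fld))
        )
    return SessionData(animal_id=str(meta["animal_id"].iloc[0]),
                       session_id=str(meta["session_id"].iloc[0]),
                       units=units, trials=trials)


def read_nwb_session(path: str | Path, animal_id: str = "", session_id: str = "") -> SessionData:
    """Read the standard NWB (HDF5) ``units`` and ``intervals/trials`` tables.

    Maps ragged ``units/spike_times`` (+ ``spike_times_index``) and the trial
    event/label columns onto :class:`SessionData`.  Extension columns beyond
    the ones used here are ignored.
    """
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        if "units" not in f:
            raise SessionFormatError("units: group not found in NWB file")
        ug = f["units"]
        st = np.asarray(ug["spike_times"])
        idx = np.asarray(ug["spike_times_index"])
        ids = np.asarray(ug["id"]) if "id" in ug else np.arange(len(idx))

        def col(group, name, n, default=np.nan):
            if name in group:
                return np.asarray(group[name])
            return np.full(n, default)

        n_units = len(idx)
        widths = col(ug, "spike_width_ms", n_units)
        depth = col(ug, "depth_um", n_units)
        starts = np.concatenate([[0], idx[:-1]])
        units = []
        for i in range(n_units):
            units.append(
                Unit(unit_id=str(ids[i]), spike_times=np.sort(st[starts[i]:idx[i]]),
                     spike_width_ms=float(widths[i]), depth_um=float(depth[i]))
            )

        if "intervals" not in f or "trials" not in f["intervals"]:
            raise SessionFormatError("intervals/trials: group not found in NWB file")
        tg = f["intervals"]["trials"]
        n_trials = len(np.asarray(tg["start_time"]))

        def scol(name, default):
            if name in tg:
                arr = np.asarray(tg[name])
                if arr.dtype.kind in "SO":
                    return [v.decode() if isinstance(v, bytes) else str(v) for v in arr]
                return arr
            return [default] * n_trials

        t_sample = np.asarray(tg["t_sample_on"])
        t_delay = np.asarray(tg["t_delay_on"])
        t_go = np.asarray(tg["t_go"])
        types = scol("type", "lick_right")
        outcomes = scol("outcome", "correct")
        perturb = scol("perturbation", "none")
        trials = [
            Trial(trial_index=i, type=types[i], outcome=outcomes[i],
                  t_sample_on=float(t_sample[i]), t_delay_on=float(t_delay[i]),
                  t_go=float(t_go[i]), perturbation=perturb[i])
            for i in range(n_trials)
        ]
    return SessionData(animal_id=animal_id or path.stem, session_id=session_id or path.stem,
                       units=units, trials=trials)


# ---------------------------------------------------------------------------
# Unit quality filtering
# ---------------------------------------------------------------------------

# (metric, op, threshold): all comparisons strict, matching the published cuts
QUALITY_THRESHOLDS = (
    ("amplitude_uv", ">", 100.0),
    ("isi_violation", "<", 0.5),
    ("amplitude_cutoff", "<", 0.1),
    ("snr", ">", 2.5),
    ("spike_width_ms", "<", 1.2),
    ("presence_ratio", ">", 0.95),
)

# extra spike-width cut per profile: ALM putative pyramidal > 0.5 ms,
# thalamus > 0.35 ms, SNr (substantia nigra pars reticulata) < 0.35 ms
PROFILE_WIDTH = {
    "alm_pyramidal": ("spike_width_ms", ">", 0.5),
    "thalamus": ("spike_width_ms", ">", 0.35),
    "snr": ("spike_width_ms", "<", 0.35),
    "generic": None,
}


def _passes(value: float, op: str, thr: float) -> bool:
    return value > thr if op == ">" else value < thr


def filter_units(units: Sequence[Unit], profile: str = "generic"
                 ) -> tuple[list[Unit], list[dict]]:
    """Apply the quality filter; a unit is kept iff it passes every criterion.

    Returns (kept_units, rejection_log); the log has one record per rejected
    unit listing every failed criterion.  A missing (NaN) metric raises
    :class:`MissingMetricError` rather than passing silently.
    """
    if profile not in PROFILE_WIDTH:
        raise ValueError(f"unknown filter profile {profile!r}")
    criteria = list(QUALITY_THRESHOLDS)
    extra = PROFILE_WIDTH[profile]
    if extra is not None:
        criteria.append(extra)

    kept: list[Unit] = []
    log: list[dict] = []
    for u in units:
        failed = []
        for metric, op, thr in criteria:
            val = getattr(u, metric)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise MissingMetricError(f"unit {u.unit_id}: metric {metric!r} missing")
            if not _passes(val, op, thr):
                failed.append(f"{metric} {op} {thr}")
        if failed:
            log.append({"unit_id": u.unit_id, "failed": failed})
        else:
            kept.append(u)
    return kept, log


# ---------------------------------------------------------------------------
# Trial selection
# ---------------------------------------------------------------------------

def select_trials(
    session: SessionData,
    types: Sequence[str] = TRIAL_TYPES,
    outcomes: Sequence[str] = ("correct",),
    perturbation: Sequence[str] = ("none",),
    subsample_n: int | None = None,
    seed: int | None = None,
) -> list[Trial]:
    """Select trials by type/outcome/perturbation; optionally subsample a
    balanced number per type without replacement.

    Early-lick trials are always excluded unless explicitly requested in
    ``outcomes``.  Deterministic given ``seed``.
    """
    outcomes = tuple(outcomes)
    sel = [
        t for t in session.trials
        if t.type in types and t.outcome in outcomes and t.perturbation in perturbation
        and (t.outcome != "early_lick" or "early_lick" in outcomes)
    ]
    if subsample_n is None:
        return sel
    if subsample_n == 0:
        return []
    rng = np.random.Generator(np.random.PCG64(0 if seed is None else int(seed)))
    out: list[Trial] = []
    for ty in types:
        pool = [t for t in sel if t.type == ty]
        if len(pool) < subsample_n:
            raise InsufficientTrialsError(
                f"session {session.session_id}: {len(pool)} {ty} trials < {subsample_n}"
            )
        take = rng.choice(len(pool), size=subsample_n, replace=False)
        out.extend(pool[i] for i in sorted(take))
    return out


# ---------------------------------------------------------------------------
# PSTH construction
# ---------------------------------------------------------------------------

SMOOTHERS = {
    "boxcar_centered_100ms": ("centered", 0.100),
    "boxcar_causal_5ms": ("causal", 0.005),
    "boxcar_causal_10ms": ("causal", 0.010),
    "none": (None, 0.0),
}


def _align_time(trial: Trial, align: str) -> float:
    return {"go": trial.t_go, "delay": trial.t_delay_on, "sample": trial.t_sample_on}[align]


def _boxcar_smooth(rates: np.ndarray, bin_width: float, smoothing: str) -> np.ndarray:
    """Smooth along axis 1.  Centered boxcars use edge-replicated padding;
    causal boxcars pad the past only, so bin t never sees bins > t."""
    kind, width = SMOOTHERS[smoothing]
    if kind is None:
        return rates
    k = max(1, int(round(width / bin_width)))
    if k == 1:
        return rates
    kernel = np.ones(k) / k
    out = np.empty_like(rates)
    for i in range(rates.shape[0]):
        for c in range(rates.shape[2]):
            x = rates[i, :, c]
            if kind == "centered":
                lpad = (k - 1) // 2
                rpad = k - 1 - lpad
                xp = np.concatenate([np.full(lpad, x[0]), x, np.full(rpad, x[-1])])
            else:  # causal
                xp = np.concatenate([np.full(k - 1, x[0]), x])
            out[i, :, c] = np.convolve(xp, kernel, mode="valid")
    return out


def _bin_counts(unit: Unit, trials: Sequence[Trial], align: str,
                edges: np.ndarray) -> np.ndarray:
    """Summed spike counts per bin across trials (half-open bins)."""
    counts = np.zeros(len(edges) - 1)
    for t in trials:
        rel = unit.spike_times - _align_time(t, align)
        sel = rel[(rel >= edges[0]) & (rel < edges[-1])]
        if sel.size:
            counts += np.bincount(((sel - edges[0]) // (edges[1] - edges[0])).astype(int),
                                  minlength=len(edges) - 1)[: len(edges) - 1]
    return counts


def compute_psth(
    session: SessionData,
    trials: Sequence[Trial],
    align: str = "go",
    window: tuple[float, float] = (-3.0, 1.5),
    bin_width: float = 0.01,
    smoothing: str = "boxcar_centered_100ms",
    zscore: bool = False,
    baseline_window: tuple[float, float] = (-0.1, 0.0),
    by_trial: bool = False,
    units: Sequence[Unit] | None = None,
) -> PSTHMatrix:
    """Trial-averaged PSTH per condition (or per trial with ``by_trial``).

    rate(bin) = total spikes in bin across trials / (n_trials * bin_width),
    then boxcar-smoothed.  Optional z-scoring uses the per-neuron mean/SD of
    the pre-cue baseline window; neurons with zero baseline SD are flagged in
    ``valid_neurons`` and their z-scored rates set to NaN.
    """
    if len(trials) == 0:
        raise ValueError("compute_psth requires at least one trial")
    if smoothing not in SMOOTHERS:
        raise ValueError(f"unknown smoothing {smoothing!r}")
    if zscore and not (window[0] <= baseline_window[0] and baseline_window[1] <= window[1]):
        raise ValueError("baseline_window must lie within window for z-scoring")
    unit_list = list(units) if units is not None else session.units
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    centers = edges[:-1] + bin_width / 2

    if by_trial:
        groups = [[t] for t in trials]
        labels = [f"trial_{t.trial_index}" for t in trials]
    else:
        labels = [ty for ty in TRIAL_TYPES if any(t.type == ty for t in trials)]
        groups = [[t for t in trials if t.type == ty] for ty in labels]

    rates = np.zeros((len(unit_list), n_bins, len(groups)))
    for ci, grp in enumerate(groups):
        for ui, u in enumerate(unit_list):
            rates[ui, :, ci] = _bin_counts(u, grp, align, edges) / (len(grp) * bin_width)
    rates = _boxcar_smooth(rates, bin_width, smoothing)

    baseline_stats = None
    valid = None
    if zscore:
        bmask = (centers >= baseline_window[0]) & (centers < baseline_window[1])
        base = rates[:, bmask, :].reshape(len(unit_list), -1)
        mu = base.mean(axis=1)
        sd = base.std(axis=1)
        valid = sd > 0
        baseline_stats = np.column_stack([mu, sd])
        z = np.full_like(rates, np.nan)
        z[valid] = (rates[valid] - mu[valid, None, None]) / sd[valid, None, None]
        rates = z

    return PSTHMatrix(rates=rates, time=centers, bin_width=bin_width,
                      smoothing=smoothing, alignment=align,
                      condition_labels=labels,
                      neuron_ids=[u.unit_id for u in unit_list],
                      baseline_stats=baseline_stats, valid_neurons=valid)


def trial_rate_vectors(
    session: SessionData,
    trials: Sequence[Trial],
    window: tuple[float, float],
    align: str = "go",
    units: Sequence[Unit] | None = None,
) -> np.ndarray:
    """(trials x neurons) matrix of mean spike rates in the half-open window."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must be nonempty")
    unit_list = list(units) if units is not None else session.units
    out = np.zeros((len(trials), len(unit_list)))
    dur = t1 - t0
    for ti, t in enumerate(trials):
        ref = _align_time(t, align)
        for ui, u in enumerate(unit_list):
            rel = u.spike_times - ref
            out[ti, ui] = np.count_nonzero((rel >= t0) & (rel < t1)) / dur
    return out
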