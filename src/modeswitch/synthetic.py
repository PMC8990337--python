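"""Hierarchical spike-train and kinematics simulator with planted ground truth.

Emulates a two-alternative delayed-response task: a sample epoch instructs
lick direction, a delay epoch holds the plan, and an auditory go cue releases
the movement.  Each simulated unit has a baseline rate, an optional
non-selective ramp, an optional direction-selective ramp (preparatory
activity), and a phasic cue response with a planted latency (go-up or
go-down).  A lognormal gain shared by all units within a trial couples
delay-epoch and response-epoch amplitudes, which is the trial-to-trial
structure the downstream mode-correlation analysis must detect.

Spikes are drawn from the inhomogeneous Poisson rate via 1-ms Bernoulli
thinning, so a config plus seed fixes the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .core import SessionData, Trial, Unit

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DatasetBundle",
    "rate_function",
    "ramp_profile",
    "alpha_kernel",
    "simulate_session",
    "simulate_dataset",
    "simulate_kinematics",
]

BIN_S = 0.001  # Bernoulli thinning bin; rates must stay well below 1000 sp/s


def rank2_recovery_config(seed: int = 0, **overrides) -> "SimConfig":
    """Planted rank-2 selectivity structure for mode-recovery studies.

    One 100-unit session, 40 trials per type.  Two planted selective
    patterns of comparable strength: a preparatory ramp (delay pattern) and
    a sustained, independently signed cue response (response pattern,
    tau = 80 ms so the response fills the 400 ms estimation window).  All
    cue responses are go-up so the planted linear pattern is realizable
    without rate clipping, and all trials are unperturbed correct trials.
    """
    base = dict(
        n_animals=1, sessions_per_animal=1, neurons_per_session=100,
        n_trials_per_type=40, selectivity_fraction=0.5,
        go_responsive_fraction=1.0, condition_invariant_fraction=0.2,
        go_down_fraction=0.0, go_amp_range=(20.0, 40.0),
        ramp_amplitude_range=(10.0, 30.0), baseline_rate_range=(4.0, 12.0),
        go_kernel_tau=0.08, ramp_decay_tau=0.2,
        p_no_response=0.0, p_incorrect=0.0, p_early_lick=0.0, seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset (single brain area).

    Epoch durations follow the task: 1.4 s sample, 1.2 s delay, 1.5 s
    response.  ``latency_distribution`` maps area label to (mean, sd) of the
    planted cue-response latency in ms.  ``condition_invariant_fraction`` is
    the share of the cue response that is identical across trial types; the
    remainder is direction-selective with the unit's preparatory sign.
    """

    n_animals: int = 2
    sessions_per_animal: int = 2
    neurons_per_session: int = 40
    n_trials_per_type: int = 60

    sample_dur: float = 1.4
    delay_dur: float = 1.2
    response_dur: float = 1.5
    pre_trial_dur: float = 0.8  # silent-baseline window before sample onset

    baseline_rate_range: tuple[float, float] = (2.0, 12.0)
    ramp_amplitude_range: tuple[float, float] = (4.0, 20.0)
    selectivity_fraction: float = 0.4
    ramping_fraction: float = 0.6
    go_responsive_fraction: float = 0.6
    go_amp_range: tuple[float, float] = (5.0, 30.0)
    go_down_fraction: float = 0.25
    area: str = "ALM"
    latency_distribution: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ALM": (30.0, 8.0),
            "thalamus": (22.0, 6.0),
            "midbrain": (14.0, 5.0),
        }
    )
    go_kernel_tau: float = 0.02
    ramp_decay_tau: float = 0.2  # post-cue collapse of preparatory activity
    gain_sd: float = 0.25
    condition_invariant_fraction: float = 0.7

    p_no_response: float = 0.05
    p_incorrect: float = 0.10
    p_early_lick: float = 0.05
    no_response_attenuation: float = 0.3
    n_perturbation_trials: int = 0
    n_go_omitted_trials: int = 0
    perturbation_scale: float = 1.5

    quality_fail_fraction: float = 0.0

    kinematic_onset_ms: float = 64.0
    kinematic_onset_jitter_ms: float = 15.0
    kinematic_noise_sd: float = 0.05
    kinematic_rate_hz: float = 400.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_dur", "delay_dur", "response_dur", "pre_trial_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "selectivity_fraction",
            "ramping_fraction",
            "go_responsive_fraction",
            "go_down_fraction",
            "condition_invariant_fraction",
            "p_no_response",
            "p_incorrect",
            "p_early_lick",
            "quality_fail_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_animals", "sessions_per_animal", "neurons_per_session", "n_trials_per_type"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for area, (mu, _sd) in self.latency_distribution.items():
            if mu < 0:
                raise ValueError(f"latency mean for {area} must be >= 0")
        if int(self.seed) != self.seed or self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    def to_json(self) -> str:
        d = asdict(self)
        d["latency_distribution"] = {k: list(v) for k, v in self.latency_distribution.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "latency_distribution" in d:
            d["latency_distribution"] = {k: tuple(v) for k, v in d["latency_distribution"].items()}
        for key in ("baseline_rate_range", "ramp_amplitude_range", "go_amp_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted per-unit and per-trial parameters for recovery tests."""

    units: pd.DataFrame   # one row per simulated unit
    trials: pd.DataFrame  # one row per trial (gain, planted kinematic onset)

    def unit_param(self, name: str) -> np.ndarray:
        return self.units[name].to_numpy()


@dataclass
class DatasetBundle:
    """All sessions of a simulated dataset, hierarchy labels preserved."""

    config: SimConfig
    sessions: list[SessionData]
    ground_truth: GroundTruth  # pooled, with animal_id/session_id columns

    def by_animal(self) -> dict[str, list[SessionData]]:
        out: dict[str, list[SessionData]] = {}
        for s in self.sessions:
            out.setdefault(s.animal_id, []).append(s)
        return out


def ramp_profile(t: np.ndarray, delay_dur: float, post_tau: float = 0.2) -> np.ndarray:
    """Preparatory ramp: 0 before delay onset, rising linearly to 1 at the go
    cue (t = 0), then decaying exponentially with ``post_tau`` — preparatory
    selectivity collapses after the cue (the mode switch the downstream
    analysis detects).  Time is relative to the go cue."""
    t = np.asarray(t, float)
    r = np.minimum(np.clip(1.0 + t / delay_dur, 0.0, None), 1.0)
    post = t > 0
    r = np.where(post, np.exp(-t / post_tau), r)
    return r


def alpha_kernel(x: np.ndarray, tau: float) -> np.ndarray:
    """Causal alpha function K(x) = (x/tau) e^{1 - x/tau} for x >= 0, else 0.

    Peaks at K(tau) = 1, so the planted go amplitude is the peak rate change.
    """
    x = np.asarray(x, float)
    out = np.zeros_like(x)
    pos = x >= 0
    xp = x[pos] / tau
    out[pos] = xp * np.exp(1.0 - xp)
    return out


def rate_function(
    unit_params: Mapping,
    trial: Trial,
    t: np.ndarray,
    gain: float = 1.0,
    delay_dur: float = 1.2,
    tau: float = 0.02,
    ramp_decay_tau: float = 0.2,
    no_response_attenuation: float = 0.3,
    perturbation_scale: float = 1.5,
) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) at times ``t`` relative to the go cue.

    rate = max(0, b + g*(rho + s*d)*ramp(t) + g*a*K(t - L)*(1 + c*d))

    where d = +1 for lick-right / -1 for lick-left, g is the shared trial
    gain (attenuated in no-response trials), and the cue-response kernel K is
    omitted in go-omitted trials and scaled by ``perturbation_scale`` in
    stimulation trials.  Negative drives clip at zero.
    """
    b = float(unit_params["baseline_rate"])
    rho = float(unit_params["ramp_amp"])
    s = float(unit_params["sel_ramp_amp"])
    a = float(unit_params["go_amp"])
    L = float(unit_params["go_latency_ms"]) * 1e-3 if np.isfinite(unit_params["go_latency_ms"]) else np.nan
    c = float(unit_params["go_sel"])

    d = 1.0 if trial.type == "lick_right" else -1.0
    g = gain
    if trial.outcome == "no_response":
        g = g * no_response_attenuation

    t = np.asarray(t, float)
    rate = b + g * (rho + s * d) * ramp_profile(t, delay_dur, ramp_decay_tau)
    if a != 0.0 and np.isfinite(L) and trial.perturbation != "go_omitted":
        k = alpha_kernel(t - L, tau)
        scale = perturbation_scale if trial.perturbation == "stimulation" else 1.0
        rate = rate + g * a * scale * k * (1.0 + c * d)
    return np.clip(rate, 0.0, None)


def _draw_unit_params(cfg: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    lo_b, hi_b = cfg.baseline_rate_range
    lo_r, hi_r = cfg.ramp_amplitude_range
    lo_g, hi_g = cfg.go_amp_range
    mu_lat, sd_lat = cfg.latency_distribution[cfg.area]

    baseline = rng.uniform(lo_b, hi_b, n)
    is_ramping = rng.random(n) < cfg.ramping_fraction
    ramp_amp = np.where(is_ramping, rng.uniform(lo_r, hi_r, n), 0.0)
    sel_sign = np.where(rng.random(n) < cfg.selectivity_fraction,
                        np.where(rng.random(n) < 0.5, 1.0, -1.0), 0.0)
    sel_ramp = sel_sign * rng.uniform(lo_r, hi_r, n)
    is_go = rng.random(n) < cfg.go_responsive_fraction
    go_sign = np.where(rng.random(n) < cfg.go_down_fraction, -1.0, 1.0)
    go_amp = np.where(is_go, go_sign * rng.uniform(lo_g, hi_g, n), 0.0)
    lat = np.clip(rng.normal(mu_lat, sd_lat, n), 0.0, None)
    go_latency = np.where(is_go, lat, np.nan)
    # response selectivity is signed independently of delay selectivity:
    # selectivity before and after the cue is carried by different (partially
    # overlapping) neuron combinations, so the planted structure is rank 2
    resp_sign = np.where(rng.random(n) < cfg.selectivity_fraction,
                         np.where(rng.random(n) < 0.5, 1.0, -1.0), 0.0)
    go_sel = (1.0 - cfg.condition_invariant_fraction) * resp_sign * is_go

    return pd.DataFrame(
        {
            "baseline_rate": baseline,
            "selectivity_sign": sel_sign.astype(int),
            "ramp_amp": ramp_amp,
            "sel_ramp_amp": sel_ramp,
            "go_amp": go_amp,
            "go_latency_ms": go_latency,
            "condition_invariant_amp": np.abs(go_amp) * cfg.condition_invariant_fraction,
            "go_sel": go_sel,
        }
    )


def _draw_quality_metrics(cfg: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Quality metrics drawn independently of the firing model.

    All units start at comfortably passing values; a planted fraction then
    gets exactly one criterion violated so filter tests can enumerate flags.
    """
    width_by_area = {"ALM": (0.6, 1.1), "thalamus": (0.40, 1.0), "midbrain": (0.40, 1.0)}
    wlo, whi = width_by_area.get(cfg.area, (0.6, 1.1))
    df = pd.DataFrame(
        {
            "depth_um": rng.uniform(100, 1100, n),
            "spike_width_ms": rng.uniform(wlo, whi, n),
            "amplitude_uv": rng.uniform(150, 400, n),
            "isi_violation": rng.uniform(0.0, 0.3, n),
            "amplitude_cutoff": rng.uniform(0.0, 0.05, n),
            "snr": rng.uniform(3.0, 8.0, n),
            "presence_ratio": rng.uniform(0.96, 1.0, n),
            "x_um": rng.uniform(0, 1000, n),
            "y_um": rng.uniform(0, 1000, n),
        }
    )
    fail = rng.random(n) < cfg.quality_fail_fraction
    criteria = ["amplitude_uv", "isi_violation", "amplitude_cutoff", "snr", "presence_ratio", "spike_width_ms"]
    bad_values = {
        "amplitude_uv": lambda r: r.uniform(20, 100),
        "isi_violation": lambda r: r.uniform(0.5, 1.0),
        "amplitude_cutoff": lambda r: r.uniform(0.1, 0.5),
        "snr": lambda r: r.uniform(0.5, 2.5),
        "presence_ratio": lambda r: r.uniform(0.5, 0.95),
        "spike_width_ms": lambda r: r.uniform(1.2, 2.0),
    }
    failed_criterion = np.full(n, "", dtype=object)
    for i in np.flatnonzero(fail):
        crit = criteria[rng.integers(len(criteria))]
        df.loc[i, crit] = bad_values[crit](rng)
        failed_criterion[i] = crit
    df["quality_pass"] = ~fail
    df["planted_fail_criterion"] = failed_criterion
    return df


def _make_trials(cfg: SimConfig, rng: np.random.Generator,
                 onsets_ms: np.ndarray) -> list[Trial]:
    n = 2 * cfg.n_trials_per_type + cfg.n_perturbation_trials + cfg.n_go_omitted_trials
    types = np.array(["lick_right"] * cfg.n_trials_per_type + ["lick_left"] * cfg.n_trials_per_type
                     + list(rng.choice(["lick_right", "lick_left"],
                                       cfg.n_perturbation_trials + cfg.n_go_omitted_trials)))
    perturb = np.array(["none"] * (2 * cfg.n_trials_per_type)
                       + ["stimulation"] * cfg.n_perturbation_trials
                       + ["go_omitted"] * cfg.n_go_omitted_trials)
    order = rng.permutation(n)
    types, perturb = types[order], perturb[order]

    trial_len = cfg.pre_trial_dur + cfg.sample_dur + cfg.delay_dur + cfg.response_dur
    iti = 1.0
    trials: list[Trial] = []
    for i in range(n):
        start = i * (trial_len + iti)
        t_sample = start + cfg.pre_trial_dur
        t_delay = t_sample + cfg.sample_dur
        t_go = t_delay + cfg.delay_dur
        u = rng.random()
        if u < cfg.p_early_lick:
            outcome = "early_lick"
        elif u < cfg.p_early_lick + cfg.p_no_response:
            outcome = "no_response"
        elif u < cfg.p_early_lick + cfg.p_no_response + cfg.p_incorrect:
            outcome = "incorrect"
        else:
            outcome = "correct"
        if perturb[i] == "go_omitted":
            outcome = "no_response"

        first_lick = None
        lick_dir = None
        if outcome == "early_lick":
            first_lick = t_delay + rng.uniform(0.1, cfg.delay_dur - 0.1)
            lick_dir = str(rng.choice(["lick_right", "lick_left"]))
        elif outcome in ("correct", "incorrect"):
            first_lick = t_go + onsets_ms[i] * 1e-3 + rng.exponential(0.02)
            lick_dir = types[i] if outcome == "correct" else (
                "lick_left" if types[i] == "lick_right" else "lick_right")
        trials.append(
            Trial(
                trial_index=i,
                type=str(types[i]),
                outcome=outcome,
                t_sample_on=t_sample,
                t_delay_on=t_delay,
                t_go=t_go,
                perturbation=str(perturb[i]),
                first_lick_time=first_lick,
                first_lick_direction=lick_dir,
            )
        )
    return trials


def simulate_session(
    config: SimConfig, animal_id: str, session_id: str, seed: int
) -> tuple[SessionData, GroundTruth]:
    """Simulate one recording session.

    Spikes are drawn per 1-ms bin as Bernoulli(rate * 1 ms) within each
    trial window (inter-trial gaps are silent).  Identical arguments give
    byte-identical output.
    """
    if int(seed) != seed or seed < 0:
        raise ValueError("seed must be a nonnegative integer")
    rng = np.random.Generator(np.random.PCG64(int(seed)))

    n_units = config.neurons_per_session
    params = _draw_unit_params(config, n_units, rng)
    quality = _draw_quality_metrics(config, n_units, rng)

    onset_jitter = rng.exponential(config.kinematic_onset_jitter_ms,
                                   2 * config.n_trials_per_type
                                   + config.n_perturbation_trials
                                   + config.n_go_omitted_trials)
    kin_onsets = config.kinematic_onset_ms + onset_jitter
    trials = _make_trials(config, rng, kin_onsets)
    n_trials = len(trials)
    gains = rng.lognormal(0.0, config.gain_sd, n_trials) if config.gain_sd > 0 else np.ones(n_trials)

    # per-trial time grid relative to go cue, 1-ms bins
    t0 = -(config.pre_trial_dur + config.sample_dur + config.delay_dur)
    t1 = config.response_dur
    edges = np.arange(t0, t1 + BIN_S / 2, BIN_S)
    centers = edges[:-1] + BIN_S / 2

    spikes_per_unit: list[list[np.ndarray]] = [[] for _ in range(n_units)]
    for ti, trial in enumerate(trials):
        for ui in range(n_units):
            rate = rate_function(
                params.iloc[ui],
                trial,
                centers,
                gain=gains[ti],
                delay_dur=config.delay_dur,
                tau=config.go_kernel_tau,
                ramp_decay_tau=config.ramp_decay_tau,
                no_response_attenuation=config.no_response_attenuation,
                perturbation_scale=config.perturbation_scale,
            )
            p = np.minimum(rate * BIN_S, 1.0)
            hits = rng.random(len(p)) < p
            if hits.any():
                spikes_per_unit[ui].append(trial.t_go + centers[hits])

    units = []
    for ui in range(n_units):
        st = (np.sort(np.concatenate(spikes_per_unit[ui]))
              if spikes_per_unit[ui] else np.empty(0))
        q = quality.iloc[ui]
        units.append(
            Unit(
                unit_id=f"{session_id}_u{ui:03d}",
                spike_times=st,
                area_label=config.area,
                depth_um=float(q["depth_um"]),
                spike_width_ms=float(q["spike_width_ms"]),
                amplitude_uv=float(q["amplitude_uv"]),
                isi_violation=float(q["isi_violation"]),
                amplitude_cutoff=float(q["amplitude_cutoff"]),
                snr=float(q["snr"]),
                presence_ratio=float(q["presence_ratio"]),
                coordinates_um=(float(q["x_um"]), float(q["y_um"])),
            )
        )

    gt_units = pd.concat([params, quality], axis=1)
    gt_units.insert(0, "unit_id", [u.unit_id for u in units])
    gt_units.insert(0, "session_id", session_id)
    gt_units.insert(0, "animal_id", animal_id)
    gt_trials = pd.DataFrame(
        {
            "animal_id": animal_id,
            "session_id": session_id,
            "trial_index": [t.trial_index for t in trials],
            "gain": gains,
            "kinematic_onset_ms": kin_onsets,
        }
    )
    session = SessionData(animal_id=animal_id, session_id=session_id, units=units, trials=trials)
    return session, GroundTruth(units=gt_units, trials=gt_trials)


def simulate_dataset(config: SimConfig) -> DatasetBundle:
    """Simulate the full animal -> session hierarchy.

    Per-session seeds are spawned deterministically from the master seed, so
    sessions differ from each other but the whole dataset is reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    n_sessions = config.n_animals * config.sessions_per_animal
    child_seeds = [int(s.generate_state(1, np.uint32)[0]) for s in ss.spawn(n_sessions)]

    sessions: list[SessionData] = []
    gt_units, gt_trials = [], []
    k = 0
    for a in range(config.n_animals):
        for s in range(config.sessions_per_animal):
            animal_id = f"animal{a:02d}"
            session_id = f"{animal_id}_s{s:02d}"
            sess, gt = simulate_session(config, animal_id, session_id, child_seeds[k])
            sessions.append(sess)
            gt_units.append(gt.units)
            gt_trials.append(gt.trials)
            k += 1
    ground_truth = GroundTruth(
        units=pd.concat(gt_units, ignore_index=True),
        trials=pd.concat(gt_trials, ignore_index=True),
    )
    return DatasetBundle(config=config, sessions=sessions, ground_truth=ground_truth)


def simulate_kinematics(
    config: SimConfig,
    trials: Sequence[Trial],
    planted_onsets_ms: np.ndarray,
    seed: int,
    window: tuple[float, float] = (-0.5, 1.0),
) -> dict:
    """Jaw/nose traces and tongue detection times for a list of trials.

    Traces (sampled at ``kinematic_rate_hz``) are Gaussian noise plus a slow
    linear drift; on movement trials a sigmoidal displacement starts at the
    planted onset after the go cue.  Tongue detection time is the planted
    onset plus exponential jitter on lick trials, NaN otherwise.

    Returns dict with keys ``time`` (s, relative to go cue), ``jaw``,
    ``nose`` ((n_trials, n_samples) arrays), ``tongue_times`` (s, NaN if no
    lick).
    """
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    dt = 1.0 / config.kinematic_rate_hz
    time = np.arange(window[0], window[1], dt)
    n = len(trials)
    out = {}
    moved = np.array([t.outcome in ("correct", "incorrect") for t in trials])
    for key, amp in (("jaw", 1.0), ("nose", 0.6)):
        traces = rng.normal(0.0, config.kinematic_noise_sd, (n, len(time)))
        drift = rng.normal(0.0, 0.02, n)
        traces += drift[:, None] * (time[None, :] - time[0])
        for i in range(n):
            if moved[i]:
                onset = planted_onsets_ms[i] * 1e-3
                x = (time - onset) / 0.03
                traces[i] += amp / (1.0 + np.exp(-x)) * (time >= onset)
        out[key] = traces
    tongue = np.full(n, np.nan)
    lick = np.array([t.first_lick_time is not None and t.outcome != "early_lick" for t in trials])
    jit = rng.exponential(config.kinematic_onset_jitter_ms * 1e-3, n)
    tongue[lick] = planted_onsets_ms[lick] * 1e-3 + jit[lick]
    out["time"] = time
    out["tongue_times"] = tongue
    return out
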