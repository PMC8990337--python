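"""End-to-end orchestration: simulate/load -> filter -> modes -> projections
-> latencies -> statistics -> report.

The pipeline is a pure function of (input data, RunConfig): rerunning with
the same config writes byte-identical artifacts.  Every excluded unit,
session, or trial is logged with the rule that triggered the exclusion,
because the exclusion cascade is the main reproducibility hazard in this
kind of analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core, latency as lat, modes as md, stats as st, synthetic as syn

__all__ = ["RunConfig", "ReportBundle", "run_analysis", "recovery_report", "planted_modes"]

LOW_RATE_THRESHOLD = 2.0      # spikes/s; session-mean over analyzed trials, strict <
MIN_CELLS_PER_SESSION = 5
PRE_CUE_SEL_WINDOW = 0.1      # s, eligibility rank-sum window
PERI_CUE_WINDOW = (-0.2, 0.2)  # selectivity/activity explained report window


@dataclass
class RunConfig:
    sim: syn.SimConfig | None = None
    session_dirs: list[str] = field(default_factory=list)
    out_dir: str = "modeswitch_out"
    filter_profile: str = "alm_pyramidal"
    split_seed: int = 0
    split_fraction: float = 0.5
    bin_width: float = 0.01
    psth_window: tuple[float, float] = (-3.4, 1.0)
    psth_smoothing: str = "boxcar_centered_100ms"
    cd_delay_window: tuple[float, float] = (-0.6, 0.0)
    cd_response_window: tuple[float, float] = (0.0, 0.4)
    mode_order: tuple[str, ...] = ("CD_delay", "CD_response", "D_go", "D_ramp")
    n_boot: int = 1000
    boot_seed: int = 0
    latency_search_ms: float = 200.0

    def to_json(self) -> str:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = json.loads(self.sim.to_json())
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim"):
            d["sim"] = syn.SimConfig.from_dict(d["sim"])
        for key in ("psth_window", "cd_delay_window", "cd_response_window", "mode_order"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ReportBundle:
    config: RunConfig
    out_dir: Path
    session_results: list[dict]
    summary: dict
    exclusions: list[dict]
    ground_truth: syn.GroundTruth | None = None


def _session_eligibility(session, units, trials_by_type, seed) -> tuple[bool, str]:
    """A session is eligible when it has >= 5 analyzed cells and at least one
    cell with significant pre-cue (100 ms) selectivity (rank-sum p < 0.05)."""
    if len(units) < MIN_CELLS_PER_SESSION:
        return False, f"fewer than {MIN_CELLS_PER_SESSION} analyzed cells"
    win = (-PRE_CUE_SEL_WINDOW, 0.0)
    right, left = trials_by_type
    any_selective = False
    for u in units:
        cr = _counts_in_window(u, right, win)
        cl = _counts_in_window(u, left, win)
        if cr.std() == 0 and cl.std() == 0 and cr.mean() == cl.mean():
            continue
        from scipy.stats import mannwhitneyu
        p = mannwhitneyu(cr, cl, alternative="two-sided", method="auto").pvalue
        if p < 0.05:
            any_selective = True
            break
    if not any_selective:
        return False, "no significant pre-cue selectivity"
    return True, ""


def _counts_in_window(unit, trials, window) -> np.ndarray:
    out = np.empty(len(trials))
    for i, t in enumerate(trials):
        rel = unit.spike_times - t.t_go
        out[i] = np.count_nonzero((rel >= window[0]) & (rel < window[1]))
    return out


def _analyze_session(session, cfg: RunConfig, exclusions: list[dict],
                     sim_cfg: syn.SimConfig | None) -> dict | None:
    sid = session.session_id
    kept, rejlog = core.filter_units(session.units, cfg.filter_profile)
    for rec in rejlog:
        exclusions.append({"level": "unit", "session": sid, "id": rec["unit_id"],
                           "rule": "quality_filter", "detail": rec["failed"]})

    correct = core.select_trials(session, outcomes=("correct",), perturbation=("none",))
    right = [t for t in correct if t.type == "lick_right"]
    left = [t for t in correct if t.type == "lick_left"]
    if len(right) < 4 or len(left) < 4:
        exclusions.append({"level": "session", "session": sid,
                           "rule": "insufficient_correct_trials",
                           "detail": [len(right), len(left)]})
        return None

    # low-rate exclusion: session-mean rate over analyzed trials < 2 sp/s
    dur = cfg.psth_window[1] - cfg.psth_window[0]
    analyzed = []
    for u in kept:
        rate = np.mean([_counts_in_window(u, correct, cfg.psth_window).mean()]) / dur
        if rate < LOW_RATE_THRESHOLD:
            exclusions.append({"level": "unit", "session": sid, "id": u.unit_id,
                               "rule": "low_rate", "detail": float(rate)})
        else:
            analyzed.append(u)

    ok, reason = _session_eligibility(session, analyzed, (right, left), cfg.split_seed)
    if not ok:
        exclusions.append({"level": "session", "session": sid,
                           "rule": "eligibility", "detail": reason})
        return None

    train, test = md.split_train_test(correct, cfg.split_fraction, cfg.split_seed)
    psth_kw = dict(align="go", window=cfg.psth_window, bin_width=cfg.bin_width,
                   smoothing=cfg.psth_smoothing, units=analyzed)
    psth_train = core.compute_psth(session, train, **psth_kw)
    psth_test = core.compute_psth(session, test, **psth_kw)

    sample_rel = -(sim_cfg.delay_dur + sim_cfg.sample_dur) if sim_cfg else cfg.psth_window[0] + 0.6
    cd_delay = md.compute_cd_delay(psth_train, cfg.cd_delay_window)
    cd_resp = md.compute_cd_response(psth_train, cfg.cd_response_window, cd_delay=cd_delay)
    d_go = md.compute_d_go(psth_train)
    d_ramp = md.compute_d_ramp(psth_train, (sample_rel - 0.6, sample_rel))
    mode_set = md.orthogonalize_set([cd_delay, cd_resp, d_go, d_ramp], cfg.mode_order)
    by_kind = {m.kind: m for m in mode_set}

    projections, norms = {}, {}
    for kind in ("CD_delay", "CD_response", "D_go"):
        tr_train = md.project(psth_train, by_kind[kind])
        tr_test = md.project(psth_test, by_kind[kind])
        norm = md.fit_normalization(tr_train, kind)
        projections[kind] = {"raw": tr_test, "normalized": norm.apply(tr_test)}
        norms[kind] = norm

    sel = md.selectivity_explained(psth_test, [by_kind["CD_delay"], by_kind["CD_response"]],
                                   PERI_CUE_WINDOW)
    act = md.activity_explained(psth_test, mode_set,
                                baseline_window=(sample_rel - 0.6, sample_rel),
                                window=PERI_CUE_WINDOW)
    act_cum = np.mean([np.nanmean(act["per_condition"][lbl]["cumulative"])
                       for lbl in act["per_condition"]])

    # projection latencies on fine-binned test PSTHs (1-ms bins, raw rates)
    fine = core.compute_psth(session, test, align="go",
                             window=(-0.2, min(0.4, cfg.psth_window[1])),
                             bin_width=0.001, smoothing="none", units=analyzed)
    dgo_tr = md.project(fine, by_kind["D_go"])
    dgo_lat = lat.projection_latency(dgo_tr.values.mean(axis=1), fine.time,
                                     search_window=(0.0, cfg.latency_search_ms * 1e-3))
    w = md.selectivity_vector(fine)
    cdr_lat = lat.projection_latency(by_kind["CD_response"].weights @ w, fine.time,
                                     search_window=(0.0, cfg.latency_search_ms * 1e-3))

    # trial-by-trial mode coupling on held-out trials (100-ms bins), within
    # trial type so across-type selectivity does not masquerade as coupling
    pre_bins = [(-0.6 + 0.1 * i, -0.5 + 0.1 * i) for i in range(6)]
    post_bins = [(0.1 * i, 0.1 * (i + 1)) for i in range(4)]
    corr_vals, shuf_vals = [], []
    for ty in ("lick_right", "lick_left"):
        sub = [t for t in test if t.type == ty]
        if len(sub) < 4:
            continue
        pd_mat = np.column_stack([
            md.project(core.trial_rate_vectors(session, sub, wdw, units=analyzed),
                       by_kind["CD_delay"]).values for wdw in pre_bins])
        pr_mat = np.column_stack([
            md.project(core.trial_rate_vectors(session, sub, wdw, units=analyzed),
                       by_kind["CD_response"]).values for wdw in post_bins])
        corr_vals.append(np.nanmean(st.trial_mode_correlation(pd_mat, pr_mat)))
        shuf_vals.append(np.nanmean(st.trial_mode_correlation(
            pd_mat, pr_mat, shuffle_control=True, seed=cfg.boot_seed)))
    corr = float(np.mean(corr_vals)) if corr_vals else np.nan
    corr_shuf = float(np.mean(shuf_vals)) if shuf_vals else np.nan

    # decoding lick direction from held-out CD_delay projections, pre-cue
    labels = np.array([t.type == "lick_right" for t in test])
    auc = st.roc_decode(md.project(
        core.trial_rate_vectors(session, test, (-0.5, 0.0), units=analyzed),
        by_kind["CD_delay"]).values[:, None], labels)[0]

    # single-neuron go latencies (40-trial subsample per type when available)
    unit_lat = []
    try:
        lat_trials = core.select_trials(session, outcomes=("correct",),
                                        perturbation=("none",), subsample_n=40,
                                        seed=cfg.split_seed)
    except core.InsufficientTrialsError:
        lat_trials = correct
    go_times = [t.t_go for t in lat_trials]
    for u in analyzed:
        times_ms, counts = lat.pooled_counts(
            u.spike_times, go_times, (-0.1, cfg.latency_search_ms * 1e-3))
        unit_lat.append((u.unit_id, lat.neuron_go_latency(
            counts, times_ms, len(go_times),
            search_window_ms=(0.0, cfg.latency_search_ms))))

    return {
        "session_id": sid,
        "animal_id": session.animal_id,
        "n_units_analyzed": len(analyzed),
        "neuron_ids": [u.unit_id for u in analyzed],
        "modes": by_kind,
        "normalizations": norms,
        "projections": projections,
        "selectivity_explained": float(np.nanmean(sel["cumulative"])),
        "activity_explained": float(act_cum),
        "d_go_latency_ms": dgo_lat,
        "cd_response_latency_ms": cdr_lat,
        "trial_mode_corr": corr,
        "trial_mode_corr_shuffled": corr_shuf,
        "n_test_trials": len(test),
        "auc_cd_delay": float(auc),
        "unit_latencies": unit_lat,
        "test_trials": test,
    }


def run_analysis(cfg: RunConfig) -> ReportBundle:
    """Execute the full pipeline and write artifacts to ``cfg.out_dir``."""
    gt = None
    if cfg.sim is not None:
        bundle = syn.simulate_dataset(cfg.sim)
        sessions = bundle.sessions
        gt = bundle.ground_truth
    elif cfg.session_dirs:
        sessions = [core.read_session(p) for p in cfg.session_dirs]
    else:
        raise ValueError("RunConfig needs either sim or session_dirs")

    exclusions: list[dict] = []
    results = []
    for session in sessions:
        res = _analyze_session(session, cfg, exclusions, cfg.sim)
        if res is not None:
            results.append(res)
    if not results:
        raise RuntimeError("analysis: no eligible sessions")

    def grand(key):
        vals = [r[key] for r in results if r[key] is not None]
        return float(np.median(vals)) if vals else None

    # area latency over pooled analyzed units
    all_lat = [lr for r in results for (_uid, lr) in r["unit_latencies"]]
    area = lat.area_latency(all_lat, fraction=0.01, n_boot=cfg.n_boot, seed=cfg.boot_seed)

    summary = {
        "n_sessions_analyzed": len(results),
        "n_sessions_excluded": sum(1 for e in exclusions if e["level"] == "session"),
        "n_units_excluded": sum(1 for e in exclusions if e["level"] == "unit"),
        "selectivity_explained_pct": 100.0 * float(np.median(
            [r["selectivity_explained"] for r in results])),
        "activity_explained_pct": 100.0 * float(np.median(
            [r["activity_explained"] for r in results])),
        "d_go_latency_ms": grand("d_go_latency_ms"),
        "cd_response_latency_ms": grand("cd_response_latency_ms"),
        "area_latency_ms": area["latency_ms"],
        "area_latency_sem_ms": area["sem"],
        "trial_mode_corr": grand("trial_mode_corr"),
        "trial_mode_corr_shuffled": grand("trial_mode_corr_shuffled"),
        "auc_cd_delay": grand("auc_cd_delay"),
    }

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(cfg.to_json() + "\n")
    with open(out_dir / "exclusions.jsonl", "w") as f:
        for rec in exclusions:
            f.write(json.dumps(rec, sort_keys=True) + "\n")

    mode_rows = []
    for r in results:
        for kind, m in r["modes"].items():
            for uid, wgt in zip(m.neuron_ids, m.weights):
                mode_rows.append({"session_id": r["session_id"], "mode": kind,
                                  "unit_id": uid, "weight": wgt})
    pd.DataFrame(mode_rows).to_csv(out_dir / "modes.csv", index=False)

    lat_rows = []
    for r in results:
        for uid, lr in r["unit_latencies"]:
            lat_rows.append({"session_id": r["session_id"], "unit_id": uid,
                             "latency_ms": lr.latency_ms, "direction": lr.direction,
                             "t_p001_ms": lr.t_p001_ms,
                             "baseline_rate": lr.baseline_rate})
    pd.DataFrame(lat_rows).to_csv(out_dir / "unit_latencies.csv", index=False)

    proj_rows = []
    for r in results:
        for kind, pr in r["projections"].items():
            tr = pr["normalized"]
            for ci, lbl in enumerate(tr.condition_labels):
                for t, v in zip(tr.time, tr.values[:, ci]):
                    proj_rows.append({"session_id": r["session_id"], "mode": kind,
                                      "condition": lbl, "time_s": t, "value": v})
    pd.DataFrame(proj_rows).to_csv(out_dir / "projections.csv", index=False)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return ReportBundle(config=cfg, out_dir=out_dir, session_results=results,
                        summary=summary, exclusions=exclusions, ground_truth=gt)


# ---------------------------------------------------------------------------
# Ground-truth comparison
# ---------------------------------------------------------------------------

def planted_modes(gt_units: pd.DataFrame, sim_cfg: syn.SimConfig,
                  neuron_ids: Sequence[str]) -> dict:
    """Planted mode directions implied by the generator's rate law, for the
    analyzed subset of units.

    CD_delay is proportional to the selective ramp amplitude; D_go to the
    expected cue-response window-mean; CD_response to the selective part of
    the cue response, orthogonalized against the planted CD_delay.
    """
    sub = gt_units.set_index("unit_id").loc[list(neuron_ids)]
    s = sub["sel_ramp_amp"].to_numpy()
    a = sub["go_amp"].to_numpy()
    c = sub["go_sel"].to_numpy()
    L = np.nan_to_num(sub["go_latency_ms"].to_numpy() * 1e-3)

    tgrid = np.arange(0.0005, 0.4, 0.001)
    kmean = np.array([syn.alpha_kernel(tgrid - Li, sim_cfg.go_kernel_tau).mean() for Li in L])
    tgrid_go = np.arange(0.0005, 0.1, 0.001)
    kmean_go = np.array([syn.alpha_kernel(tgrid_go - Li, sim_cfg.go_kernel_tau).mean() for Li in L])

    def unitize(v):
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v

    cd_delay = unitize(2.0 * s)
    decay_mean = float(np.exp(-tgrid / sim_cfg.ramp_decay_tau).mean())
    # selectivity in the response window: decaying preparatory part + cue part
    resp_sel = 2.0 * s * decay_mean + 2.0 * a * c * kmean
    cd_resp = resp_sel - (resp_sel @ cd_delay) * cd_delay
    return {
        "CD_delay": cd_delay,
        "CD_response": unitize(cd_resp),
        "D_go": unitize(a * kmean_go),
        "D_ramp": unitize(sub["ramp_amp"].to_numpy()),
    }


def recovery_report(bundle: ReportBundle) -> pd.DataFrame:
    """Compare estimated modes/latencies to planted ground truth.

    One row per session with mode cosine similarities, the correlation of
    detected unit latencies with planted ones, and the trial-coupling
    statistics.  Requires a simulated run.
    """
    if bundle.ground_truth is None or bundle.config.sim is None:
        raise ValueError("recovery_report requires a simulated run")
    gt = bundle.ground_truth
    rows = []
    for r in bundle.session_results:
        planted = planted_modes(gt.units, bundle.config.sim, r["neuron_ids"])
        row = {"session_id": r["session_id"]}
        for kind in ("CD_delay", "CD_response", "D_go", "D_ramp"):
            est = r["modes"][kind].weights
            row[f"cos_{kind}"] = float(abs(est @ planted[kind]))
        det = {uid: lr for uid, lr in r["unit_latencies"]}
        gsub = gt.units.set_index("unit_id")
        pairs = [
            (gsub.loc[uid, "go_latency_ms"], det[uid].latency_ms)
            for uid in r["neuron_ids"]
            if uid in det and det[uid].latency_ms is not None
            and np.isfinite(gsub.loc[uid, "go_latency_ms"])
            and det[uid].direction == ("up" if gsub.loc[uid, "go_amp"] > 0 else "down")
        ]
        if pairs:
            planted_l, est_l = map(np.array, zip(*pairs))
            row["latency_mae_ms"] = float(np.median(np.abs(est_l - planted_l)))
            row["n_latency_pairs"] = len(pairs)
        else:
            row["latency_mae_ms"] = np.nan
            row["n_latency_pairs"] = 0
        row["trial_mode_corr"] = r["trial_mode_corr"]
        row["selectivity_explained"] = r["selectivity_explained"]
        rows.append(row)
    return pd.DataFrame(rows)
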