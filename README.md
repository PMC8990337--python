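# modeswitch

Activity-mode decomposition of trial-aligned neural population recordings
from delayed-response tasks, with latency estimation, decoding, and
hierarchical-bootstrap inference — exercised end-to-end on a synthetic spike
simulator with planted ground truth.

## The scientific problem

In a delayed-response task an instruction tells the animal which movement to
make (e.g. lick left or lick right), a delay epoch holds the plan, and an
auditory go cue releases it.  With *n* recorded neurons, population activity
is a trajectory in *n*-dimensional state space.  Around movement initiation
that trajectory reorganizes rapidly: the slowly varying, direction-selective
*preparatory* pattern collapses and two new patterns appear — a
condition-invariant cue response and a direction-selective movement command.
This package implements the subtraction-defined directions that isolate
those patterns, plus the latency and inference machinery needed to time and
compare them:

* **w**_t = **r**_right,t − **r**_left,t, the population selectivity vector;
* **CD**_delay = mean of **w**_t over the last 600 ms of the delay,
  normalized — the preparatory (plan) direction;
* **CD**_response = mean of **w**_t over the first 400 ms after the cue,
  Gram–Schmidt-orthogonalized to **CD**_delay — the movement-command
  direction;
* **D**_go = post-cue minus pre-cue mean of the trial-type-averaged activity
  (100 ms windows) — the condition-invariant cue response;
* **D**_ramp = pre-cue minus pre-trial mean — non-selective ramping;
* **D**_stim = stimulation minus cue-omitted post-stimulus mean.

Directions are estimated on a random half of unperturbed correct trials and
applied to the held-out half; projections are normalized so lick-left and
lick-right training means map to 0 and 1 (unit pre/post change for
**D**_go).  Mode quality is quantified as *selectivity explained*,
Σ_modes(**w**_tᵀ·mode)² / ‖**w**_t‖² per time bin.

Latencies are estimated at three levels: single neurons by a two-step
Poisson test on pooled 1-ms spike counts (first bin significant at
α = 0.001, pulled back through the contiguous α = 0.05 run); population
projections by the analogous 5σ/2σ rule on the baseline-standardized trace;
and brain areas as the earliest time at which 1% of analyzed cells have
responded.  Kinematic movement onsets use a 3σ threshold on the detrended
mean trace (jaw/nose) and a 0.05 cumulative-distribution difference against
cue-omitted trials (tongue).  All resampling inference uses a three-level
hierarchical bootstrap: animals, then sessions within animal, then trials
within session, each with replacement.

Because real recordings of this kind are large and external, the package
ships a first-class synthetic generator (`modeswitch.synthetic`) that plants
the relevant structure — delay-selective ramps, go-up/go-down cue responses
with per-area latency distributions, a condition-invariant component, a
lognormal trial gain shared across the population (which couples delay- and
response-epoch amplitudes trial by trial), no-response and perturbation
trials, and kinematic traces — and returns the planted parameters for
recovery tests.

## Worked example

Simulate the default study (2 animals × 2 sessions × 40 units, 60 trials per
lick direction) and run the full pipeline:

```python
import json
import modeswitch as ms
from modeswitch.pipeline import RunConfig, run_analysis

cfg = RunConfig(sim=ms.SimConfig(seed=42), out_dir="out", n_boot=1000)
bundle = run_analysis(cfg)
print(json.dumps(bundle.summary, indent=2, sort_keys=True))
```

prints

```json
{
  "activity_explained_pct": 91.76534446967335,
  "area_latency_ms": 17.0,
  "area_latency_sem_ms": 10.352828405802926,
  "auc_cd_delay": 1.0,
  "cd_response_latency_ms": 33.499999999999986,
  "d_go_latency_ms": 30.5,
  "n_sessions_analyzed": 4,
  "n_sessions_excluded": 0,
  "n_units_excluded": 0,
  "selectivity_explained_pct": 90.09012595575022,
  "trial_mode_corr": -0.0035974552338365095,
  "trial_mode_corr_shuffled": 0.04821800148477822
}
```

Reading the output: the two coding directions capture ~90% of the
population selectivity around the cue (`selectivity_explained_pct`), and
four orthogonalized modes capture ~92% of baseline-subtracted activity
(`activity_explained_pct`).  Held-out pre-cue **CD**_delay projections
decode lick direction perfectly (`auc_cd_delay` = 1.0).  The
condition-invariant mode turns on ~30 ms after the cue and the
movement-command mode a few milliseconds later (`d_go_latency_ms`,
`cd_response_latency_ms`), while 1% of single units have responded by 17 ms
(`area_latency_ms`).  Trial-by-trial coupling between delay and response
modes (`trial_mode_corr`) is indistinguishable from its shuffle control at
these small per-session sizes; the dedicated coupling study in
`scripts/acceptance.py` (100 held-out trials per type, 100 units) detects
the planted shared gain at r ≈ 0.6.

The same pipeline runs from a shell:

```bash
modeswitch simulate --out data/            # sessions + ground-truth CSVs
modeswitch analyze  --session-dir data/animal00_s00 --out out/
modeswitch recover  --out out/             # simulate, analyze, compare to truth
```

Each analysis writes `summary.json`, tidy `modes.csv` /
`unit_latencies.csv` / `projections.csv` tables, the resolved
`config.json`, and an `exclusions.jsonl` log with one record per excluded
unit/session and the rule that triggered it.

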