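# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `modeswitch`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Time is in seconds with t = 0 at go-cue onset for peri-cue analyses; all
time bins are half-open [t, t + Δ), so each spike belongs to exactly one
bin.  A session holds units (spike times on the session clock plus quality
metadata) and trials (sample/delay/go event times, trial type, outcome,
perturbation label, first-lick time).  The on-disk session format is a
directory of plain CSVs (`units.csv`, `spikes.csv`, `trials.csv`,
`session.csv`) written with 17-significant-digit floats and read with
round-trip parsing, so write∘read is the identity.  An NWB-layout HDF5
reader (`read_nwb_session`) maps the standard `units` ragged spike-times
table and `intervals/trials` columns onto the same model via h5py.

Unit quality filtering applies the published post-hoc thresholds, all
strict: amplitude > 100 µV, ISI violation < 0.5, amplitude cutoff < 0.1,
SNR > 2.5, spike width < 1.2 ms, presence ratio > 0.95; profile-specific
width cuts select putative pyramidal cells in cortex (> 0.5 ms), thalamic
units (> 0.35 ms), or narrow-spiking nigral units (< 0.35 ms).  A missing
metric is an error, never a silent pass.  Units with session-mean rate
below 2 spikes/s over the analyzed trials are excluded before mode
estimation (boundary kept: exactly 2.0 is retained); the threshold is
evaluated before trial subsetting.  Sessions need at least 5 analyzed cells
and at least one cell with significant pre-cue selectivity (rank-sum on a
100-ms window, p < 0.05) to enter session-based analyses.

## The synthetic generator

Each simulated unit's instantaneous rate is

    rate(t) = max(0, b + g·(ρ + s·d)·ramp(t) + g·a·K(t − L)·(1 + c·d))

with baseline b, non-selective ramp amplitude ρ, signed selective ramp
amplitude s, trial-type sign d (+1 lick-right, −1 lick-left), cue-response
amplitude a (negative for go-down cells) with planted latency L drawn from
a per-area normal distribution, and causal alpha kernel
K(x) = (x/τ)·e^(1−x/τ) peaking at K(τ) = 1 so that a is the peak rate
change.  The ramp rises linearly from 0 at delay onset to 1 at the cue and
then decays exponentially (default τ_decay = 0.2 s): preparatory
selectivity collapses after the cue, which is the reorganization the mode
analysis is built to detect.  The cue-response selectivity factor c is
(1 − condition_invariant_fraction) with a sign drawn independently of the
delay sign, because delay-epoch and response-epoch selectivity are carried
by partially different neuron combinations; this makes the planted
selectivity genuinely rank-2 (a delay pattern and a response pattern).

A lognormal trial gain g ~ exp(N(0, gain_sd)) is shared by every unit in a
trial and multiplies both the ramp and the cue response, inducing the
trial-by-trial coupling between delay- and response-epoch activity that the
trial-correlation analysis must detect; in no-response trials g is
attenuated (default ×0.3), in stimulation trials the kernel term is scaled
by `perturbation_scale`, and in go-omitted trials it is absent.  Spikes are
drawn by 1-ms Bernoulli thinning of the rate (valid for rates ≪ 1000
spikes/s), which makes a config-plus-seed bit-reproducible; inter-trial
gaps are silent.  Per-session seeds are spawned deterministically from the
master seed.  Quality metrics are drawn independently of the firing model
so filter logic can be tested in isolation; a configurable fraction of
units gets exactly one criterion violated.

Default study conditions: 2 animals × 2 sessions × 40 units, 60 trials per
type; baselines U(2, 12) spikes/s, ramp amplitudes U(4, 20) on 60% of
units, selective ramps on 40%, cue responses U(5, 30) on 60% (25%
go-down), kernel τ = 20 ms, planted latencies N(30, 8)/N(22, 6)/N(14, 5) ms
for the cortical/thalamic/midbrain area labels, gain_sd = 0.25, 70%
condition-invariant cue response, 5%/10%/5% no-response/incorrect/early-lick
outcomes.  These values are chosen to resemble strongly modulated frontal
cortex units; they are calibration knobs of the simulator, not estimates of
any real dataset.

The kinematics module emits 400-Hz jaw/nose traces (Gaussian noise + slow
linear drift + a sigmoidal displacement starting at the planted onset on
movement trials) and tongue first-detection times (planted onset +
exponential jitter on lick trials, absent otherwise).

What the generator does **not** emulate: realistic spike-train
autocorrelation (refractoriness, bursting), cross-neuron noise correlations
beyond the shared scalar gain, drift or non-stationarity across a session,
behaviorally conditioned dynamics (the rate law is the same on incorrect
trials, with d following the instruction), or video artifacts.  Passing
recovery tests therefore demonstrates estimator correctness under the
planted model, not robustness to every pathology of real recordings.

## Mode estimation

Modes are the subtraction-defined unit vectors described in the README.
Estimation uses a 10-ms-bin PSTH smoothed with a 100-ms centered boxcar
(causal 5/10-ms boxcars are used for peri-cue views; the assignment is a
config default, overridable).  A defining vector is degenerate when its
norm is below 1e−9·√n (scale-free); degeneracy raises an explicit error
naming the mode.  Full-set orthogonalization is sequential Gram–Schmidt in
the order CD_delay → CD_response → D_go → D_ramp by default; the order of
D_go and D_ramp is genuinely open and exposed as config.  The train/test
split is a type-balanced random half of unperturbed correct trials;
normalization anchors are fitted on training condition means and applied
unchanged to held-out trials (they are recomputed per resampling iteration
by default; a caller can freeze them by reusing the `Normalization`
object).  Pseudopopulations pool cells across sessions with replacement,
drawing disjoint train/test trial sets per cell; cells with fewer than
2 × trials_per_type correct trials per direction are excluded and logged.

## Latency estimation

The per-neuron test pools spike counts in 1-ms bins across the (up to 40
subsampled) trials and tests each post-cue bin two-sided against
Poisson(baseline_rate × n_trials × bin width), with the baseline from the
100-ms pre-cue window.  Exact Poisson tails are used (the bin width and
test statistic are our documented choices; pooled exact counts were chosen
for reproducibility).  T_p=0.001 is the first bin with p < 0.001; the
reported latency is the earliest bin of the contiguous p < 0.05 run
containing T_p=0.001.  The alternative literal reading — the latest
above→below 0.05 crossing before T_p=0.001 — is implemented behind
`rule="last_crossing"` and compared in tests; the two agree except on
p-paths with multiple significant runs.  The search window is capped at
200 ms post-cue (configurable).  A down-going response on a zero baseline
is declared undetectable rather than extrapolated.  Under a homogeneous
Poisson null the false-positive rate of the default settings is ≤ 5% in the
200-ms window (measured over 1000 simulated units in the acceptance suite).

Area latency is the earliest time by which 1% of analyzed cells (default:
all cells passing the quality filter, responders and non-responders alike)
show an up-going latency, with SEM from 1000 cell-level bootstrap
resamples.  Projection latency standardizes the trace by the pre-cue 100-ms
baseline, smooths with a 10-ms causal boxcar, and applies the 5σ/2σ
two-threshold rule with the same contiguous-run pull-back.

Kinematic onsets: per bootstrap draw the mean trace is linearly detrended
on the late-delay window, and the onset is the first post-cue sample whose
absolute excursion exceeds 3× the pre-cue baseline SD; a numerically flat
baseline yields "absent".  The tongue onset is the first time the
first-detection c.d.f. of the condition of interest exceeds the
cue-omitted c.d.f. by 0.05 (undetected trials stay in the denominator).

## Statistics

The hierarchical bootstrap resamples animals, then sessions within each
sampled animal, then trials within each sampled session, all with
replacement, 1000 iterations by default.  One-sided p-values are reported
as max(fraction, 1/n_iter) so a p of literally zero is never printed.  A
draw on which the statistic fails is rejected and logged, capped at 5% of
iterations.  With one animal and one session the procedure reduces to a
flat trial bootstrap (verified distributionally in tests); CI coverage for
a three-level Gaussian mean at 10 animals × 4 sessions × 25 trials is
measured in the acceptance suite.

Rank-sum selectivity tests use scipy's Mann–Whitney implementation
(exact/asymptotic-with-tie-correction chosen automatically by sample size
and ties), on 40-trial subsamples per direction.  ROC decoding is the
rank-based AUC (sklearn), computed per 50-ms bin in the pipeline.  The
logistic regression of lick outcome on per-trial mode activity (200-ms
windows) is a maximum-likelihood binomial fit via statsmodels, with
complete separation flagged when the fit predicts perfectly and either
fails to converge or produces |coefficient| > 10; confidence intervals come
from the hierarchical bootstrap.  The density map smooths flagged and total
neuron counts with a Gaussian of 250-µm half-width-at-half-maximum
(σ = HWHM/√(2 ln 2)) on a 10-µm grid and reports flagged/(total + 0.05);
the 0.05 regularizer keeps sparsely sampled pixels bounded.  Sinusoidal
modulation is the Fourier coefficient of the mean rate at the
photostimulus frequency over an integer number of cycles.  Fisher LDA uses
the pooled-covariance solution (sklearn), cross-checked against the
scatter-matrix formula in tests.

## Pipeline

`run_analysis` is a pure function of (input data, config): stages run in a
fixed order, every exclusion is logged with its rule, and repeated runs are
byte-identical (verified).  Trial-by-trial mode coupling is computed within
trial type, because across-type selectivity differences would otherwise
masquerade as coupling.  The recovery report compares estimated modes to
the planted directions implied by the rate law: CD_delay ∝ s, D_go ∝ a
weighted by each unit's expected kernel window-mean, CD_response ∝ the
response-window selectivity (decayed ramp + selective kernel term)
orthogonalized against the planted delay direction.

## Problem sizes and study designs

The test and acceptance workloads use: 100-unit, 40-trial-per-type sessions
for mode recovery (the `rank2_recovery_config` plants two balanced
selective patterns — ramp U(10, 30) on half the units, sustained go-up cue
response U(20, 40) with τ = 80 ms and 80% selective share — with all-go-up
responses so the planted linear pattern is realizable without rate
clipping); 200 step-response units at three planted latencies and 1000 null
units for the latency study; 300 units per area for area-latency ordering;
10 × 4 × 25 three-level Gaussian datasets, 200 replications, for bootstrap
calibration; 300 trials for kinematic onsets; and a 500-unit session for
population projection latencies, where the 5σ rule on the selective
component needs several hundred cells.

## Known limitations

* The planted-direction comparison ignores rate clipping at zero, so mode
  cosines are only meaningful for configurations (like the recovery config)
  where clipping is negligible; with strong go-down cells the planted
  linear pattern is not exactly realizable.
* Session eligibility implements "significant pre-cue selectivity" as at
  least one significantly selective cell; other population-level readings
  are possible.
* The Poisson latency test assumes independent bins; bursty or refractory
  spike trains would miscalibrate the per-bin test.
* Hierarchical-bootstrap coverage is approximate for small numbers of
  animals; the calibration test documents the regime in which it holds.
* The logit covariate set is configurable; no claim is made that the
  default matches any particular published figure's exact covariates.
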