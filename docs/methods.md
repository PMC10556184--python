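# Methods

This note documents the models, algorithms, defaults and known limitations
behind `pupilkit`, in the order of the workflow.

## Data model and conventions

Time is milliseconds everywhere; sample indices are 0-based; windows and
index ranges are half-open. Sample *i* of a trace covers
`[t0 + i·dt, t0 + (i+1)·dt)` with `dt = 1000/rate_hz`; a time window maps to
the set of samples whose intervals overlap it (never empty — a
non-overlapping window is an error). Missing data is NaN; the raw-stream
convention of coding missing pupil size as 0 is undone at parse time.
Ragged epochs (e.g. variable cue–target intervals) are right-padded with
NaN to the longest epoch, and the unpadded length of every trial is stored
in the bundle metadata; statistics ignore missing cells. Padding at the end
is a choice: nothing in the rectangular trials-by-samples layout dictates
where shorter epochs should leave their gap, and end-padding keeps epoch
onsets aligned, which is what event-locked analyses need.

## Raw-log dialect

The parser reads a plain-text, EyeLink-ASC-inspired dialect (the vendor's
binary format is proprietary): sample lines `<timestamp> <x> <y> <pupil>`
and message lines `MSG <timestamp> <payload>`, with payloads
`start_trial`/`end_trial`, `start_phase <name>`/`end_phase <name>`, and
`var <name> <value>`. All marker strings can be overridden through a
protocol file, which is also the recipe for ingesting other single-file
dialects. The sampling rate is inferred as the modal inter-sample interval,
rounded to integer Hz; recorder-dropped samples are filled with NaN so the
time axis stays uniform. Monocular input is assumed; binocular files must
be reduced to one eye upstream. `var` values that are fully numeric are
parsed as numbers, others stay text.

## Blink reconstruction

Blinks contaminate the recorded pupil size with a sharp drop (eyelid
closing), a missing plateau, and a sharp rise (eyelid reopening). The
reconstruction is recursive:

1. smooth a working copy with a moving average (`smooth_winlen_ms`, default
   21 ms) and differentiate to a velocity in units/ms; the smoother
   propagates NaN only within its window, so data away from gaps is
   unaffected;
2. the earliest sample with velocity below `-vt_start` (default 10
   units/ms) opens a blink; the blink closes at the first sample where
   velocity falls back below `vt_end` (default 5 units/ms) after the rapid
   rise; `blink_margin_ms` (10 ms) is added on both sides;
3. extents up to `maxdur_ms` (500 ms) are replaced by a cubic spline
   through four anchors at `onset−d, onset, offset, offset+d` where `d` is
   the blink extent — anchor spacing proportional to the gap uses an
   appropriate amount of context; if an outer anchor falls outside the
   trace or on missing data, the two inner anchors are joined linearly; if
   an inner anchor is unavailable (blink at a trace edge), the extent stays
   missing. Longer extents are never interpolated: pupil size is not
   predictable over them;
4. repeat from (1) until no blink is found (interpolated stretches are
   smooth, so they are never re-detected; termination is guaranteed and the
   earliest-first search order makes the result deterministic);
5. mark samples deviating more than `std_thresh` (3) SDs from the
   post-interpolation trace mean (single pass, mean/SD ignore missing), or
   moving faster than `vt_start`, as missing;
6. widen every missing run by `gap_margin_ms` (20 ms).

Valid samples outside blink extents keep their exact input values. The
velocity thresholds are absolute, in the tracker's native units, sized for
1000 Hz recordings on an EyeLink-like arbitrary-unit scale (pupil ≈
1000–3000 units): a blink ramp moves at ≈ 100 units/ms while physiological
pupil change stays below ≈ 1 unit/ms, so the defaults separate the two by
two orders of magnitude. An amplitude-relative threshold (scaled to the
trace SD) was considered and rejected: within-trace SDs of realistic traces
put such thresholds within a factor ~2 of the velocity noise floor, causing
spurious detections. Other unit scales need rescaled thresholds — all of
them are exposed in `BlinkParams`.

Detection requires the drop/rise ramps to be present in the recording;
gaps without ramps (tracking loss) are not "blinks" and are handled by
steps 5–6 only. Reconstruction must run at the original sampling rate,
before downsampling — the ramps live at millisecond scale.

## Downsampling

Block means over `factor` consecutive samples, ignoring missing values
(an all-missing block is missing); the trailing partial block is dropped
and the rate divides by the factor. Block-averaging is itself a box
low-pass, so no separate anti-alias filter is applied; at the target rates
used for pupillometry (≥ 20 Hz, effects < a few Hz) the difference is
negligible and the missing-data semantics stay simple.

## Unit conversion

Many trackers report pupil size in arbitrary units. The calibration table
of `(true diameter mm, recorded units)` pairs — obtained e.g. by recording
printed circles of known size — is fitted by least squares with a
two-parameter power law `mm = a·units^b` by default (calibration curves are
monotone but visibly nonlinear; the power law is invertible and fits such
curves well), with a linear alternative. The fit must be monotonically
increasing over the observed range, at least 3 pairs are required, and
predictions below the fitted range are produced with an extrapolation
warning. Missing values pass through unchanged.

## Baseline correction and trial exclusion

Per trial, the baseline is the mean pupil size over a short window (default
the first 50 ms of the epoch) ignoring missing samples; subtractive
correction (default, recommended) subtracts it, divisive correction divides
by it. An all-missing window, or a zero divisive baseline, voids the whole
trial. Corrected traces start at exactly 0 (subtractive) or 1 (divisive)
over the baseline window — a property the tests assert to machine
precision.

Note that baseline correction introduces regression-to-the-mean
contingencies: trials with large baselines tend to show more negative
corrected responses purely by chance. Correlations between baseline pupil
size and corrected task-evoked responses must therefore be interpreted with
care; the package documents, and does not model, this artifact.

Trials are excluded when the per-participant z-score of their baseline
exceeds ±2 (sample SD, n−1 denominator, so results are exactly
reproducible), or when the baseline is missing. A participant with zero
baseline variance keeps all trials, with a warning. On standard-normal
baselines the rule removes the two-tailed Gaussian mass beyond 2
(≈ 4.55%) — a calibration the acceptance suite verifies at n = 100,000.

## Quality metrics

The four checks mirror the standard visual diagnostics, computed per
participant and collapsed across conditions (so data quality cannot be
judged by whether the hypothesized effect is visible):

* **spike trials** — a trial is flagged when any sample lies more than
  `k = 5` cross-trial SDs *below* the cross-trial mean trace (unreconstructed
  blinks spike downward); an optional single-step velocity bound exists but
  is off by default since no fixed default transfers across unit scales.
  A fraction above 5% raises an advisory flag;
* **missing fraction** per participant;
* **blink counts** per trial by condition — from recorded blink events when
  available, else maximal missing runs of ≥ 50 ms (shorter runs are
  usually isolated dropped samples, not blinks) in the pre-reconstruction
  trace;
* **gaze deviation** — condition-wise mean |x−cx|, |y−cy| traces in
  degrees.

Condition-imbalance flags (blink counts, gaze deviation) use a heuristic
screen — max pairwise condition difference above 25% of the grand mean —
and are advisory only, never inferential; no participant is excluded
automatically.

## Mixed-model contract

All tests build on a linear mixed-effects model with by-participant random
intercepts (optionally random slopes for the final models). p values come
from the normal approximation on the Wald z; no degrees-of-freedom
correction is applied, consistent with reporting z statistics. Final models
are estimated by REML with `statsmodels.MixedLM`; non-convergence is
flagged on the result, never raised. Rows with missing dependents are
dropped and the n used is reported.

The per-sample fits inside cross-validation localization and permutation
testing would need 10³–10⁶ mixed-model optimizations; a general-purpose
optimizer is orders of magnitude too slow. `pupilkit._gls` instead profiles
β and σ² out of the REML criterion of the random-intercept model and
maximises over the variance ratio λ = σ²ᵤ/σ² on a dense grid (λ = 0 plus 49
log-spaced points over 10⁻⁴–10⁴), using the closed Woodbury form of V⁻¹ to
reduce everything to per-group sums; many samples sharing one design are
solved simultaneously. Agreement with `MixedLM` (|Δz| < 0.1) is asserted in
the test suite, keeping the two routes independent.

## Window test

The per-trial mean over a predetermined window (missing-aware) becomes the
dependent variable of a single mixed model. No multiple-comparison
correction is needed; the cost is having to know the window in advance.

## Cluster-based permutation test

Per-sample tests over the epoch; maximal runs of contiguous samples with
`p < α` and constant z sign form clusters. Each permutation shuffles the
primary effect's values across trials *within participant* (preserving the
participant structure under the null; the shuffling granularity is a
documented choice) and records the *maximum* cluster size, giving
family-wise control; per-cluster `p = (1 + #{null max ≥ size})/(1 +
n_permutations)` (add-one rule, so p never falls below `1/(n_perm+1)`).
An all-clusters null is available by flag
(`ClusterPermResult.null_max_sizes` stores the max-statistic null). With a
fixed seed the whole result is bit-reproducible.

## Cross-validation test

Rows are split by the deterministic interleaved rule (row *i* tests in fold
`i mod k`, k = 4 by default; each fold trains on exactly 75% of rows, and
the split ignores how conditions are distributed). Per fold, per-sample
random-intercept fits on the training rows select the sample with the
largest |z| for the focal effect — |z| rather than signed z so
negative-going effects are localizable, with ties broken toward the lowest
index for determinism. Each held-out trial contributes its value at its
fold's chosen sample, and one final mixed model (with the full random
structure of the specification) is fitted to the assembled values; the
procedure repeats per main effect and interaction, and contains no
randomness at all.

### Known limitation: false-alarm rate under weak autocorrelation

The procedure's selection step leaks: training sets of different folds
overlap by two thirds, so the folds' chosen samples coincide or couple, and
the final pooled test partially reuses rows that drove the selection. An
independent brute-force simulation of the procedure (ordinary least
squares, iid Gaussian samples, no package code) puts the false-alarm rate
at α = .05 near **0.11** with 50 independent candidate samples, ~0.12 at
lag-1 autocorrelation 0.9, falling to ~0.06 only at 0.99. The package's
own null simulations reproduce this (≈ 0.07–0.12 depending on the noise
realization). In the intended regime — densely sampled pupil data whose
residuals are dominated by slow physiological fluctuations, leaving few
effectively-independent candidates per epoch — the inflation is mild, but
users should know the test is anticonservative, increasingly so the more
independent time points the analysis window contains. The cluster-based
permutation test, which is exactly calibrated by exchangeability, is the
conservative alternative when this matters.

## Synthetic data

The generator exists so every operation above is testable against ground
truth without external recordings. Per trial the pupil trace is

```
intercept_p + baseline_t + drift(t) − plr·k_plr(t)
            + (effect_c + code_c·slope_p)·k(t)·1[t ∈ effect window]
            + slow(t) + jitter(t)
```

* `k` — Erlang-shaped unit-peak kernel, shape 10.1, time-to-peak 1000 ms
  (task-evoked dilations peak around a second after their trigger);
* `k_plr` — the same family for the condition-independent stimulus-evoked
  constriction: latency 200 ms, peak ≈ 750 ms, amplitude 100 units —
  onset-locked constrictions in real data are far larger than cognitive
  effects, and including one keeps the traces' dynamic range realistic;
* `intercept_p ~ N(1800, 100²)` units — an EyeLink-like arbitrary-unit
  scale for a ≈ 3.5 mm pupil (cosmetic, configurable);
* `drift` — a sinusoid (amplitude 100 units, period 4 s, random phase per
  trial) emulating the slow waxing and waning of arousal;
  `baseline_t ~ N(0, 30²)` adds trial-to-trial level shifts;
* `slow` — white noise smoothed over 1 s and rescaled to SD 10: pupillary
  unrest is band-limited below ~1 Hz, so modelling measurement noise as
  white at 1000 Hz would be physically wrong (and would make any smooth
  interpolation "wrong" by construction); `jitter` — white camera noise,
  SD 1 unit;
* condition effects: peak dilation per condition label (default
  ctrl = 0 / exp = 50 units — together with noise SD 10 and 20×40 trials
  this is the default "detectable" regime), by-participant random slope
  SD 10;
* blinks: Poisson counts (rate 0.5/trial), durations uniform 100–400 ms,
  20 ms linear ramps to/from the missing plateau (a flag generates > 500 ms
  gaps to exercise the non-interpolation path); gaze: white noise of SD
  0.3° around the display center at 35 px/°.

Each participant's block is generated from an independent random stream
keyed by `(seed, participant index)`, so datasets are bit-reproducible and
participant blocks do not depend on how many participants are generated.
The ground-truth record retains the pre-blink traces (the blink oracle),
the true effect-window sample range (the localization oracle), and the
blink extents.

What the simulator does **not** emulate: pupil-foreshortening error,
post-saccadic/post-blink constrictions, luminance-driven responses beyond
the single onset-locked kernel, non-Gaussian heavy-tailed artifacts, and
session-scale fatigue trends. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical structure, not
robustness to every failure mode of real recordings.

### Null-calibration conditions

Type-I simulations use a reduced 50-sample grid realised as 2500 ms at
20 Hz — a post-downsampling grid with realistic within-trial
autocorrelation (50 ms at 1000 Hz would make every sample nearly
independent of the analysis question; 50 identical samples would make
cluster sizes degenerate) — with 10 participants × 20 trials, both
condition effects 0 *and* random-slope SD 0: a true null has no condition
effect of any kind, and leaving participant-varying effects in place would
test model misspecification, not calibration.

## Numerical choices

* Modal inter-sample interval (rounded to integer Hz) defines the rate;
  per-sample grid slots are `round((t − t₀)/dt)`.
* Window→sample mapping uses exact half-open interval overlap with a 10⁻⁹
  tolerance against floating-point boundary error.
* The λ grid of the fast solver bounds the variance ratio to 10⁻⁴–10⁴;
  z varies slowly in λ, so grid resolution contributes < 1% error in z.
* Argmax ties (localization) break toward the lowest sample index;
  cluster boundaries break at sign changes of z.
* Degenerate noise-free fits (residual variance 0) report z = ±inf, p = 0
  rather than NaN.
* Pipeline artifacts contain no timestamps, so identical inputs and config
  reproduce byte-identical outputs.

## Problem sizes

The test suite and the acceptance script run all simulations at desk scale,
chosen as the smallest sizes at which the verified properties are
statistically meaningful: 200 trials for the blink oracle, 10⁵ draws for
the exclusion calibration, 200–300 datasets for null-rate calibration
(binomial 95% bands), 200 permutations per cluster test, 40–50 seeds for
localization and power.
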