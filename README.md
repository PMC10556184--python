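# pupilkit

Preprocessing, quality control and time-series statistics for trial-based
**cognitive pupillometry** — experiments in which the measure of interest is
the task-evoked pupil response to a stimulus, recorded by an eye tracker as
one pupil-size trace per trial.

`pupilkit` is for researchers who have raw eye-tracker recordings (or want to
simulate them) and need the full path from raw samples to an inferential
statistic: parsing, blink reconstruction, downsampling, unit conversion,
baseline correction, trial exclusion, data-quality checks, and statistical
tests that handle the multiple-comparison problem of testing an
autocorrelated time series.

## The data model

Trials are rows of a `TrialTable`: scalar columns (participant, condition,
response time, ...) coexist with *series* columns — `n_trials x n_samples`
arrays holding one epoch of pupil or gaze samples per trial, sharing one
sampling rate and epoch-zero time per column. Time is in milliseconds,
windows are half-open `[start, end)`, and missing data is NaN (raw streams
that code missing pupil size as 0 are recoded on ingest). Tables serialize
to plain-text bundle directories (`scalars.csv`, one `series_<name>.csv` per
series column, `meta.json` with rate, epoch zero and ragged-epoch padding).

## Preprocessing

The chain runs in a fixed order (enforced programmatically):

1. **Blink reconstruction** — blinks appear as a sharp drop, a missing
   plateau, and a sharp rise. Onsets/offsets are detected by velocity
   thresholds on a smoothed copy; blinks up to 500 ms are replaced by a
   cubic spline through four anchor points (two per side, spaced by the
   blink extent), falling back to linear interpolation at trace edges;
   longer gaps are left missing. Remaining samples beyond ±3 SD of the
   trace mean, or moving impossibly fast, are removed, and 20 ms margins
   around missing runs are discarded.
2. **Downsampling** — block means (e.g. 1000 Hz → 100 Hz by factor 10),
   missing-aware.
3. **Unit conversion** — a fitted monotone calibration curve (default power
   law `mm = a·units^b`) maps arbitrary tracker units to mm of diameter.
4. **Baseline correction** — subtract (recommended) or divide by the mean
   pupil size in a short baseline window (default: first 50 ms), so every
   trial starts from 0 (or 1).
5. **Trial exclusion** — baselines are z-scored per participant; trials
   with |z| > 2 are excluded.

## Statistics

All three procedures share a linear mixed-effects contract: for trial *i* of
participant *p*,

```
y_ip = β₀ + β₁·x_ip + u_p + ε_ip ,   u_p ~ N(0, σ²_u),  ε_ip ~ N(0, σ²)
```

with Wald `z = β̂/SE` and two-tailed normal-approximation p values
(optionally with by-participant random slopes).

* **Predetermined window** (`window_test`) — one mixed model on the mean
  pupil size over an a-priori window. No multiple comparisons, but the
  window must be known in advance.
* **Cluster-based permutation** (`cluster_permutation_test`) — per-sample
  tests, maximal runs of contiguous `p < α` samples with constant sign, and
  a null distribution of maximum cluster sizes from shuffling condition
  labels within participant; cluster `p = (1 + #{null ≥ size})/(1 + n_perm)`.
* **Cross-validation** (`crossval_test`) — deterministic interleaved
  four-fold split; each fold's training rows localize the sample with the
  largest |z|, the held-out trials contribute their value at that sample,
  and a single final mixed model on the assembled values gives z and p.

The per-sample engine inside localization and permutations is a vectorised
profiled-REML random-intercept solver (`pupilkit._gls`), cross-checked
against `statsmodels.MixedLM`, which remains the engine for all final
models. See `docs/methods.md` for an important caveat about the
cross-validation procedure's false-alarm rate.

## Worked example

Everything below is computed from the package's own simulator (20
participants × 40 trials at 1000 Hz, a 50-unit peak condition effect
confined to 750–3000 ms after cue onset, blinks at 0.5 per trial):

```python
import pupilkit as pk

table, truth = pk.simulate_dataset(pk.SyntheticSpec(seed=1))
table, reports = pk.reconstruct_blinks_table(table, "pupil_cue")
table = pk.downsample_table(table, 10)                 # 1000 Hz -> 100 Hz
table, baselines = pk.baseline_correct_table(table, "pupil_cue")
table, excluded, _ = pk.exclude_baseline_outliers(table, baselines)

spec = pk.ModelSpec("pupil_cue", ["condition"],
                    coding={"condition": {"ctrl": -0.5, "exp": 0.5}})
print(pk.window_test(table, pk.TimeWindow(750, 3000), spec).summary())
print(pk.crossval_test(table, spec, window=pk.TimeWindow(750, 3000)).summary())
```

prints (blinks reconstructed: 402; trials excluded: 10 = 1.25%):

```
Predetermined-window test, window [750, 3000) ms (samples [75, 300)); 0 trial(s) dropped
Mixed-effects fit (MixedLM); n = 790; converged = True
term                     estimate           SE        z         p
Intercept              -6.254e-17          nan      nan       nan
condition                  27.806       7.6893     3.62 0.0002989
4-fold interleaved cross-validation test
condition: z = 9.88, p = 5.194e-23 (tested at samples [92]; 0 trial(s) dropped)
```

The `condition` estimate (27.8 arbitrary units) is the mean pupil-size
difference between conditions over the window — smaller than the 50-unit
peak because the kernel-shaped effect averages out over 750–3000 ms. The
cross-validation test localizes the effect at sample 92 (920 ms, near the
kernel peak at 1000 ms) and tests the held-out trials there, hence the much
larger z. The intercept of baseline-corrected data is indistinguishable
from 0 and its SE is undefined at the boundary of the between-participant
variance, which statsmodels reports as NaN.

The same workflow is available from the shell:

```bash
pupilkit simulate -o data --seed 1 --ascii   # also writes an ASCII log
pupilkit parse data/recording.asc -o parsed
pupilkit preprocess parsed -o prep
pupilkit test prep --method crossval --dv pupil_cue \
    --fixed condition --coding "ctrl=-0.5,exp=0.5" --window 750:3000
pupilkit run data -o out --config config.yaml   # end-to-end, one command
```

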