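"""Ground-truth generator of trial-epoched pupillometry datasets.

Simulates the statistical structure that the preprocessing and inference
modules assume: per-participant random intercepts and slopes, a slow
sinusoidal arousal drift, a stimulus-evoked constriction, a condition effect
carried by a single-peaked response kernel restricted to an effect window,
band-limited measurement noise, blink artifacts (sharp drop, missing plateau,
sharp rise), and gaze jitter around a nominal fixation center.

Every dataset comes with a :class:`GroundTruth` record (pre-blink traces,
blink extents, the true effect window) so oracle errors can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import SeriesMeta, TimeWindow, TrialTable, window_to_samples

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "response_kernel",
    "simulate_dataset",
    "inject_blink",
    "inject_spikes",
]


@dataclass
class SyntheticSpec:
    """Ground-truth description of a simulated pupillometry experiment.

    Amplitudes are in the tracker's arbitrary units (the default scale is
    centered near 1800 units, echoing an EyeLink-like recording of a ~3.5 mm
    pupil). Effect sizes are peak dilations in the same units. The default
    condition effect (50 units), measurement-noise SD (10 units) and the
    20 participants x 40 trials layout define the generator's "detectable"
    regime. Measurement noise is band-limited: a slow fluctuation process
    (white noise smoothed over ``noise_smooth_ms``, rescaled to ``noise_sd``)
    plus white camera jitter of SD ``jitter_sd``.
    """

    n_participants: int = 20
    trials_per_participant: int = 40
    rate_hz: float = 1000.0
    epoch_ms: float = 3000.0
    phase: str = "cue"
    # condition label -> peak dilation (arbitrary units)
    conditions: dict = field(default_factory=lambda: {"ctrl": 0.0, "exp": 50.0})
    effect_window_ms: tuple = (750.0, 3000.0)
    # task-evoked dilation kernel
    kernel_shape: float = 10.1
    kernel_peak_ms: float = 1000.0
    # stimulus-evoked constriction, condition-independent
    plr_amplitude: float = 100.0
    plr_latency_ms: float = 200.0
    plr_peak_ms: float = 750.0
    # slow state fluctuations
    drift_amplitude: float = 100.0
    drift_period_ms: float = 4000.0
    baseline_sd: float = 30.0
    # participant random effects
    intercept_mean: float = 1800.0
    intercept_sd: float = 100.0
    slope_sd: float = 10.0
    # measurement noise
    noise_sd: float = 10.0
    noise_smooth_ms: float = 1000.0
    jitter_sd: float = 1.0
    # blink artifacts
    blink_rate: float = 0.5
    blink_dur_range_ms: tuple = (100.0, 400.0)
    blink_ramp_ms: float = 20.0
    long_blink_prob: float = 0.0
    long_blink_dur_range_ms: tuple = (600.0, 900.0)
    # gaze
    gaze_center_px: tuple = (512.0, 384.0)
    px_per_degree: float = 35.0
    gaze_noise_sd_deg: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_sd", "intercept_sd", "slope_sd", "noise_sd", "jitter_sd",
            "gaze_noise_sd_deg", "drift_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rate_hz <= 0 or self.epoch_ms <= 0:
            raise ValueError("rate_hz and epoch_ms must be > 0")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        a, b = self.effect_window_ms
        if not (0 <= a < b <= self.epoch_ms):
            raise ValueError("effect window must lie within the epoch")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_ms * self.rate_hz / 1000.0))

    def condition_codes(self) -> dict:
        """Centered numeric codes for the condition labels, in insertion
        order (two conditions -> -0.5/+0.5; three -> -1/0/1)."""
        labels = list(self.conditions)
        k = len(labels)
        codes = np.arange(k, dtype=float) - (k - 1) / 2.0
        if k == 3:
            codes = np.array([-1.0, 0.0, 1.0])
        return dict(zip(labels, codes))


@dataclass
class GroundTruth:
    """Oracle record for a simulated dataset."""

    spec: SyntheticSpec
    clean_pupil: np.ndarray          # pre-blink-injection traces
    blink_extents: list              # per trial: list of (start, end) sample idx
    effect_window_samples: tuple     # half-open sample range of the true effect
    kernel: np.ndarray               # unit-peak dilation kernel over the grid
    condition_codes: dict


def response_kernel(
    n_samples: int,
    rate_hz: float,
    t_peak_ms: float = 1000.0,
    shape: float = 10.1,
) -> np.ndarray:
    """Unit-peak, single-peaked (Erlang-shaped) pupil response kernel.

    ``k(t) = (t / t_peak)^shape * exp(shape * (1 - t / t_peak))`` evaluated on
    the epoch grid; nonnegative, exactly 1 at ``t = t_peak``.
    """
    if n_samples < 1 or rate_hz <= 0:
        raise ValueError("n_samples and rate_hz must be positive")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    epoch_ms = n_samples * 1000.0 / rate_hz
    if not 0 < t_peak_ms < epoch_ms:
        raise ValueError("time-to-peak must lie inside the epoch")
    t = np.arange(n_samples) * 1000.0 / rate_hz
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = t / t_peak_ms
        k = np.where(rel > 0, rel ** shape * np.exp(shape * (1.0 - rel)), 0.0)
    k[~np.isfinite(k)] = 0.0
    return k / k.max()


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, win: int) -> np.ndarray:
    """Band-limited Gaussian noise: moving-average-filtered white noise,
    rescaled to standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    win = max(1, win)
    white = rng.standard_normal(n + win - 1)
    kern = np.ones(win) / win
    slow = np.convolve(white, kern, mode="valid")
    return slow * sd * np.sqrt(win)


def inject_blink(
    values: np.ndarray,
    start: int,
    duration: int,
    ramp: int,
) -> tuple[int, int]:
    """Inject a blink artifact in place: a linear ramp to 0 over ``ramp``
    samples, a missing (NaN) plateau, and a linear ramp back up. Returns the
    half-open sample extent that was modified."""
    n = values.size
    end = min(n, start + duration)
    start = max(0, start)
    if end - start < 2 * ramp + 1:
        ramp = max(1, (end - start) // 3)
    v0 = values[start]
    v1 = values[end - 1] if end < n else values[n - 1]
    down = np.linspace(v0, 0.0, ramp + 1)[1:]
    up = np.linspace(0.0, v1, ramp + 1)[:-1]
    values[start:start + ramp] = down
    values[end - ramp:end] = up
    values[start + ramp:end - ramp] = np.nan
    # a recorded value of exactly 0 is the raw stream's missing code, so the
    # ramp endpoints that reach 0 belong to the missing plateau
    values[start + ramp - 1] = np.nan
    values[end - ramp] = np.nan
    return start, end


def _participant_rng(seed: int, pid: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(pid)])


def simulate_dataset(spec: SyntheticSpec) -> tuple[TrialTable, GroundTruth]:
    """Simulate a trial-epoched dataset and its ground-truth record.

    Per trial the pupil trace is

    ``intercept_p + baseline_t + drift(t) - plr * k_plr(t)
    + (effect_c + code_c * slope_p) * k(t) * 1[t in effect window]
    + slow noise + jitter``

    with blinks injected afterwards (the pre-injection trace is retained in
    the ground truth). Each participant has an independent random stream
    derived from ``(seed, participant index)``, so participant blocks do not
    depend on how many participants are generated.
    """
    n_samp = spec.n_samples
    rate = spec.rate_hz
    t = np.arange(n_samp) * 1000.0 / rate
    kernel = response_kernel(n_samp, rate, spec.kernel_peak_ms, spec.kernel_shape)
    win = TimeWindow(*spec.effect_window_ms)
    w0, w1 = window_to_samples(rate, 0.0, win, n_samp)
    mask = np.zeros(n_samp)
    mask[w0:w1] = 1.0
    kern_masked = kernel * mask

    # condition-independent constriction kernel (latency-shifted)
    plr = np.zeros(n_samp)
    if spec.plr_amplitude != 0:
        lat = spec.plr_latency_ms
        tp = spec.plr_peak_ms - lat
        if tp <= 0:
            raise ValueError("plr_peak_ms must exceed plr_latency_ms")
        rel = np.clip(t - lat, 0.0, None) / tp
        plr = np.where(rel > 0, rel ** spec.kernel_shape
                       * np.exp(spec.kernel_shape * (1.0 - rel)), 0.0)
        plr = plr / max(plr.max(), 1e-12)

    codes = spec.condition_codes()
    labels = list(spec.conditions)
    noise_win = int(round(spec.noise_smooth_ms * rate / 1000.0))
    ramp = max(1, int(round(spec.blink_ramp_ms * rate / 1000.0)))

    rows = []
    pupil_rows, x_rows, y_rows = [], [], []
    clean_rows, blink_extents = [], []
    for pid in range(spec.n_participants):
        rng = _participant_rng(spec.seed, pid)
        intercept = spec.intercept_mean + rng.normal(0.0, spec.intercept_sd)
        slope_dev = rng.normal(0.0, spec.slope_sd)
        # balanced condition labels, shuffled deterministically
        reps = int(np.ceil(spec.trials_per_participant / len(labels)))
        cond_seq = np.tile(labels, reps)[: spec.trials_per_participant]
        cond_seq = cond_seq[rng.permutation(spec.trials_per_participant)]
        for tr in range(spec.trials_per_participant):
            cond = cond_seq[tr]
            effect = spec.conditions[cond] + codes[cond] * slope_dev
            base = rng.normal(0.0, spec.baseline_sd)
            phase0 = rng.uniform(0.0, 2 * np.pi)
            drift = spec.drift_amplitude * np.sin(
                2 * np.pi * t / spec.drift_period_ms + phase0)
            slow = _smooth_noise(rng, n_samp, spec.noise_sd, noise_win)
            jitter = rng.normal(0.0, spec.jitter_sd, n_samp) if spec.jitter_sd else 0.0
            trace = (intercept + base + drift - spec.plr_amplitude * plr
                     + effect * kern_masked + slow + jitter)
            clean = trace.copy()
            extents = []
            n_blinks = rng.poisson(spec.blink_rate)
            for _ in range(n_blinks):
                if spec.long_blink_prob > 0 and rng.random() < spec.long_blink_prob:
                    dur_ms = rng.uniform(*spec.long_blink_dur_range_ms)
                else:
                    dur_ms = rng.uniform(*spec.blink_dur_range_ms)
                dur = int(round(dur_ms * rate / 1000.0))
                lo = int(0.05 * n_samp)
                hi = n_samp - dur - int(0.05 * n_samp)
                placed = False
                for _attempt in range(20):
                    start = int(rng.integers(lo, max(lo + 1, hi)))
                    gap = int(0.1 * rate)  # 100 ms separation between blinks
                    if all(start + dur + gap < a or start > b + gap
                           for a, b in extents):
                        placed = True
                        break
                if not placed:
                    continue
                extents.append(inject_blink(trace, start, dur, ramp))
            ppd = spec.px_per_degree
            gx = spec.gaze_center_px[0] + rng.normal(
                0.0, spec.gaze_noise_sd_deg * ppd, n_samp)
            gy = spec.gaze_center_px[1] + rng.normal(
                0.0, spec.gaze_noise_sd_deg * ppd, n_samp)
            rows.append({
                "participant": pid,
                "trial": tr,
                "condition": cond,
                "cond_code": codes[cond],
                "n_blinks": len(extents),
            })
            pupil_rows.append(trace)
            x_rows.append(gx)
            y_rows.append(gy)
            clean_rows.append(clean)
            blink_extents.append(extents)

    scalars = pd.DataFrame(rows)
    table = TrialTable(scalars, history=["parse"])
    meta = SeriesMeta(rate, 0.0)
    ph = spec.phase
    table.add_series(f"pupil_{ph}", np.asarray(pupil_rows), meta)
    table.add_series(f"x_{ph}", np.asarray(x_rows), meta)
    table.add_series(f"y_{ph}", np.asarray(y_rows), meta)
    truth = GroundTruth(
        spec=spec,
        clean_pupil=np.asarray(clean_rows),
        blink_extents=blink_extents,
        effect_window_samples=(w0, w1),
        kernel=kernel,
        condition_codes=codes,
    )
    return table, truth


def inject_spikes(
    table: TrialTable,
    fraction: float,
    magnitude: float,
    column: str | None = None,
    width: int = 3,
    seed: int = 0,
) -> tuple[TrialTable, np.ndarray]:
    """Inject one downward spike into ``round(fraction * n_trials)`` trials.

    Returns a modified copy of the table and the affected trial indices.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    out = table.copy()
    if column is None:
        column = next(c for c in out.series if c.startswith("pupil"))
    arr = out.series[column]
    n = out.n_trials
    n_spike = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_spike, replace=False) if n_spike else np.array([], int)
    n_samp = arr.shape[1]
    for i in idx:
        pos = int(rng.integers(n_samp // 4, 3 * n_samp // 4))
        arr[i, pos:pos + width] -= magnitude
    return out, np.sort(idx)
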