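"""The ordered preprocessing chain for pupil-size data.

Stages, in the order in which they must be performed:

1. blink reconstruction (:func:`reconstruct_blinks`)
2. downsampling (:func:`downsample`)
3. unit conversion from arbitrary units to mm (:func:`fit_calibration`,
   :func:`apply_calibration`)
4. baseline correction (:func:`baseline_correct`)
5. trial exclusion on z-scored baselines (:func:`exclude_baseline_outliers`)

The table-level wrappers (``*_table``) enforce this order through the
table's stage history and raise :class:`~pupilkit.core.PipelineOrderError`
when called out of order.

Blink reconstruction
--------------------
Blinks appear as a sharp drop in recorded pupil size (eyelid closing),
a period of missing data (eyelid closed), and a sharp rise (eyelid
reopening). The recursive reconstruction procedure detects the drop and the
post-rise stabilization with velocity thresholds, and replaces the blink
extent with a cubic-spline interpolation through four anchor points (two on
each side, spaced by the blink extent), falling back to linear interpolation
when the outer anchors are unavailable, and to plain removal when the
blink-like period is too long for pupil size to be predictable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit

from .core import (
    PipelineOrderError,
    PupilTrace,
    SeriesMeta,
    TimeWindow,
    TrialTable,
    window_to_samples,
)

__all__ = [
    "BlinkParams",
    "BlinkReport",
    "CalibrationModel",
    "BaselineSpec",
    "reconstruct_blinks",
    "reconstruct_blinks_table",
    "downsample",
    "downsample_table",
    "fit_calibration",
    "apply_calibration",
    "convert_units_table",
    "baseline_correct",
    "baseline_correct_table",
    "exclude_baseline_outliers",
]


@dataclass
class BlinkParams:
    """Tunables of the blink-reconstruction algorithm.

    Velocity thresholds are in signal units per ms on the smoothed trace:
    a blink onset is a negative velocity excursion past ``-vt_start``; the
    blink ends when velocity falls back below ``vt_end`` after the rapid
    rise. The defaults suit 1000 Hz recordings in EyeLink-like arbitrary
    units (pupil ~ 1000-3000 units); other scales need rescaled thresholds.
    """

    vt_start: float = 10.0        # onset threshold, units/ms (negative-going)
    vt_end: float = 5.0           # offset stabilization threshold, units/ms
    maxdur_ms: float = 500.0      # longest reconstructable blink
    blink_margin_ms: float = 10.0  # margin marked missing around each blink
    smooth_winlen_ms: float = 21.0  # moving-average width before velocity
    std_thresh: float = 3.0       # outlier cut in SDs of the trace mean
    gap_margin_ms: float = 20.0   # margin around remaining missing periods

    def __post_init__(self) -> None:
        for name in ("vt_start", "vt_end", "maxdur_ms", "blink_margin_ms",
                     "smooth_winlen_ms", "gap_margin_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.std_thresh <= 0:
            raise ValueError("std_thresh must be > 0")
        if self.maxdur_ms <= 2 * self.blink_margin_ms:
            raise ValueError("maxdur_ms must exceed 2 * blink_margin_ms")


@dataclass
class BlinkReport:
    """Per-trace reconstruction report."""

    n_blinks: int = 0
    n_cubic_samples: int = 0
    n_linear_samples: int = 0
    n_marked_missing: int = 0
    all_missing: bool = False
    blink_extents: list = field(default_factory=list)


def _smooth(values: np.ndarray, win: int) -> np.ndarray:
    # NaN-propagating moving average: any window touching missing data is
    # NaN, but (unlike running-sum filters) samples farther than the window
    # from a gap are unaffected; edges replicate the boundary value
    if win <= 1:
        return values.copy()
    half = win // 2
    padded = np.pad(values, (half, win - 1 - half), mode="edge")
    return np.convolve(padded, np.ones(win) / win, mode="valid")


def _nan_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Half-open extents of the NaN runs in ``values``."""
    isnan = np.isnan(values)
    if not isnan.any():
        return []
    d = np.diff(isnan.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if isnan[0]:
        starts.insert(0, 0)
    if isnan[-1]:
        ends.append(values.size)
    return list(zip(starts, ends))


def _find_blink(vel: np.ndarray, vt_start: float, vt_end: float,
                from_idx: int = 0) -> tuple[int, int | None] | None:
    """Earliest (onset, offset) velocity excursion past the thresholds.

    ``offset`` is None when the trace ends before pupil size stabilizes
    (rise not found or not completed). NaN velocities never match, so fully
    missing gaps without recorded ramps are not treated as blinks.
    """
    with np.errstate(invalid="ignore"):
        onset_hits = np.where(vel[from_idx:] < -vt_start)[0]
    if onset_hits.size == 0:
        return None
    onset = from_idx + int(onset_hits[0])
    with np.errstate(invalid="ignore"):
        rise_hits = np.where(vel[onset + 1:] > vt_end)[0]
    if rise_hits.size == 0:
        return onset, None
    rise = onset + 1 + int(rise_hits[0])
    with np.errstate(invalid="ignore"):
        stab_hits = np.where(vel[rise + 1:] < vt_end)[0]
    if stab_hits.size == 0:
        return onset, None
    return onset, rise + 1 + int(stab_hits[0])


def reconstruct_blinks(
    trace: PupilTrace,
    params: BlinkParams | None = None,
) -> tuple[PupilTrace, BlinkReport]:
    """Reconstruct blinks in a single trace; returns (trace, report).

    Recursive procedure: (1) smooth a working copy and compute velocity;
    (2) find the earliest blink (negative excursion past ``vt_start``,
    recovery, stabilization below ``vt_end``), extended by
    ``blink_margin_ms`` on both sides; (3) reconstruct it by cubic-spline
    interpolation through four anchors (spacing equal to the blink extent),
    by linear interpolation when the outer anchors are unavailable, or mark
    it missing when longer than ``maxdur_ms``; (4) repeat until no blink is
    found; (5) mark samples deviating more than ``std_thresh`` SDs from the
    trace mean, or moving faster than ``vt_start``, as missing; (6) widen
    every missing run by ``gap_margin_ms``.

    Valid samples outside blink extents keep their exact input values. Runs
    at the original (pre-downsampling) sampling rate.
    """
    params = params or BlinkParams()
    values = trace.values.copy()
    n = values.size
    report = BlinkReport()
    if np.all(np.isnan(values)):
        report.all_missing = True
        warnings.warn("trace is entirely missing; returned unchanged")
        return PupilTrace(values, trace.rate_hz, trace.t0_ms), report

    rate = trace.rate_hz
    win = max(1, int(round(params.smooth_winlen_ms * rate / 1000.0)))
    if n < win:
        raise ValueError(
            f"trace ({n} samples) is shorter than the smoothing window ({win})"
        )
    margin = max(1, int(round(params.blink_margin_ms * rate / 1000.0)))
    maxdur = int(round(params.maxdur_ms * rate / 1000.0))
    ms_per_sample = 1000.0 / rate

    for _ in range(100):  # safety bound; recursion terminates well before
        sm = _smooth(values, win)
        vel = np.diff(sm) / ms_per_sample
        hit = _find_blink(vel, params.vt_start, params.vt_end)
        if hit is None:
            break
        onset, offset = hit
        start = max(0, onset - margin)
        if offset is None:
            # blink runs into the end of the trace: unrecoverable
            values[start:n] = np.nan
            report.n_marked_missing += n - start
            report.blink_extents.append((start, n))
            report.n_blinks += 1
            continue
        end = min(n, offset + 1 + margin)
        report.n_blinks += 1
        report.blink_extents.append((start, end))
        dur = end - start
        if dur > maxdur:
            values[start:end] = np.nan
            report.n_marked_missing += dur
            continue
        o, f = start - 1, end  # inner anchors: last/first valid neighbors
        a1, a4 = o - dur, f + dur
        inner_ok = (o >= 0 and f < n
                    and np.isfinite(values[o]) and np.isfinite(values[f]))
        outer_ok = (inner_ok and a1 >= 0 and a4 < n
                    and np.isfinite(values[a1]) and np.isfinite(values[a4]))
        if outer_ok:
            spline = CubicSpline([a1, o, f, a4],
                                 values[[a1, o, f, a4]])
            values[start:end] = spline(np.arange(start, end))
            report.n_cubic_samples += dur
        elif inner_ok:
            values[start:end] = np.interp(
                np.arange(start, end), [o, f], values[[o, f]])
            report.n_linear_samples += dur
        else:
            # no valid anchor on one side (e.g., blink at trace edge):
            # the extent stays missing
            values[start:end] = np.nan
            report.n_marked_missing += dur

    # (5) remaining invalid data: deviation and velocity outliers
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        m = np.nanmean(values)
        sd = np.nanstd(values)
    with np.errstate(invalid="ignore"):
        dev_out = np.abs(values - m) > params.std_thresh * sd
    sm = _smooth(values, win)
    vel = np.diff(sm) / ms_per_sample
    vel_out = np.zeros(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        fast = np.abs(vel) > params.vt_start
    vel_out[:-1] |= fast
    vel_out[1:] |= fast
    newly = (dev_out | vel_out) & ~np.isnan(values)
    values[newly] = np.nan
    report.n_marked_missing += int(newly.sum())

    # (6) widen every missing run
    gap = max(1, int(round(params.gap_margin_ms * rate / 1000.0)))
    marked = 0
    for s, e in _nan_runs(values):
        lo, hi = max(0, s - gap), min(n, e + gap)
        marked += int(np.sum(~np.isnan(values[lo:s]))) \
            + int(np.sum(~np.isnan(values[e:hi])))
        values[lo:s] = np.nan
        values[e:hi] = np.nan
    report.n_marked_missing += marked

    return PupilTrace(values, rate, trace.t0_ms), report


def reconstruct_blinks_table(
    table: TrialTable,
    column: str,
    params: BlinkParams | None = None,
) -> tuple[TrialTable, list[BlinkReport]]:
    """Apply blink reconstruction to every trial of a series column."""
    table.check_stage_order("reconstruct")
    out = table.copy()
    reports = []
    arr = out.series[column]
    meta = out.series_meta[column]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        for i in range(out.n_trials):
            stop = arr.shape[1] if meta.valid_lengths is None \
                else int(meta.valid_lengths[i])
            tr = PupilTrace(arr[i, :stop].copy(), meta.rate_hz, meta.t0_ms)
            rec, rep = reconstruct_blinks(tr, params)
            arr[i, :stop] = rec.values
            reports.append(rep)
    out.record_stage("reconstruct")
    return out, reports


def downsample(obj, factor: int):
    """Downsample a trace, 1-D array, or 2-D series column by block means.

    Output length is ``floor(n / factor)``; each output sample is the mean of
    ``factor`` consecutive input samples ignoring missing values (all-missing
    blocks yield NaN); the trailing partial block is dropped. For
    :class:`PupilTrace` input, ``rate_hz`` is divided by ``factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if isinstance(obj, PupilTrace):
        if obj.n_samples < factor:
            raise ValueError("trace shorter than the downsampling factor")
        return PupilTrace(downsample(obj.values, factor),
                          obj.rate_hz / factor, obj.t0_ms)
    arr = np.asarray(obj, dtype=float)
    if factor == 1:
        return arr.copy()
    if arr.ndim == 1:
        n_out = arr.size // factor
        if n_out == 0:
            raise ValueError("input shorter than the downsampling factor")
        blocks = arr[: n_out * factor].reshape(n_out, factor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(blocks, axis=1)
    if arr.ndim == 2:
        n_out = arr.shape[1] // factor
        if n_out == 0:
            raise ValueError("input shorter than the downsampling factor")
        blocks = arr[:, : n_out * factor].reshape(arr.shape[0], n_out, factor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(blocks, axis=2)
    raise ValueError("expected a PupilTrace, 1-D or 2-D array")


def downsample_table(table: TrialTable, factor: int) -> TrialTable:
    """Downsample every series column of a table."""
    table.check_stage_order("downsample")
    out = TrialTable(table.scalars.copy(), history=list(table.history))
    for name, arr in table.series.items():
        m = table.series_meta[name]
        vl = None if m.valid_lengths is None else m.valid_lengths // int(factor)
        out.add_series(name, downsample(arr, factor),
                       SeriesMeta(m.rate_hz / factor, m.t0_ms, vl))
    out.record_stage("downsample")
    return out


# ---------------------------------------------------------------------------
# unit conversion


@dataclass
class CalibrationModel:
    """Fitted conversion from recorded arbitrary units to mm of diameter.

    ``form`` is ``"power"`` (mm = a * units**b, the default; pupil-size
    calibration curves are monotone but visibly nonlinear) or ``"linear"``
    (mm = a + b * units).
    """

    form: str
    params: tuple
    rmse: float
    max_abs_residual: float
    fit_range: tuple  # (min units, max units) seen during fitting

    def predict(self, units):
        units = np.asarray(units, dtype=float)
        a, b = self.params
        if self.form == "power":
            with np.errstate(invalid="ignore"):
                return a * units ** b
        return a + b * units

    def inverse(self, mm):
        mm = np.asarray(mm, dtype=float)
        a, b = self.params
        if self.form == "power":
            with np.errstate(invalid="ignore"):
                return (mm / a) ** (1.0 / b)
        return (mm - a) / b


def fit_calibration(pairs, form: str = "power") -> CalibrationModel:
    """Least-squares fit of a conversion formula from (mm, units) pairs.

    ``pairs`` is a sequence of ``(true_diameter_mm, recorded_units)``; at
    least 3 pairs with strictly positive recorded units are required. The
    fitted prediction must be monotonically increasing over the observed
    range of recorded units.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (mm, units) pairs")
    mm, units = arr[:, 0], arr[:, 1]
    if np.any(units <= 0):
        raise ValueError("recorded units must be strictly positive")
    if np.ptp(units) == 0 or np.ptp(mm) == 0:
        raise ValueError("degenerate calibration pairs (zero variance)")
    if form == "power":
        # log-log least squares as initialization, refined on the raw scale
        if np.any(mm <= 0):
            raise ValueError("power-law form requires positive diameters")
        b0, loga0 = np.polyfit(np.log(units), np.log(mm), 1)
        p0 = (float(np.exp(loga0)), float(b0))
        popt, _ = curve_fit(lambda u, a, b: a * u ** b, units, mm,
                            p0=p0, maxfev=10000)
        params = (float(popt[0]), float(popt[1]))
        monotone = params[0] > 0 and params[1] > 0
    elif form == "linear":
        b, a = np.polyfit(units, mm, 1)
        params = (float(a), float(b))
        monotone = params[1] > 0
    else:
        raise ValueError(f"unknown calibration form {form!r}")
    model = CalibrationModel(form, params, 0.0, 0.0,
                             (float(units.min()), float(units.max())))
    resid = model.predict(units) - mm
    model.rmse = float(np.sqrt(np.mean(resid ** 2)))
    model.max_abs_residual = float(np.max(np.abs(resid)))
    if not monotone:
        raise ValueError(
            "fitted conversion is not monotonically increasing over the "
            "observed range; check the calibration pairs"
        )
    return model


def apply_calibration(model: CalibrationModel, column):
    """Convert a series column (or array) from arbitrary units to mm.

    Missing values pass through as missing. Values below the model's fitted
    range are converted anyway, with a warning (extrapolation).
    """
    arr = np.asarray(column, dtype=float)
    finite = np.isfinite(arr)
    if np.any(arr[finite] < model.fit_range[0]):
        warnings.warn(
            "input contains values below the calibration's fitted range; "
            "extrapolating"
        )
    return model.predict(arr)


def convert_units_table(
    table: TrialTable, model: CalibrationModel, columns=None
) -> TrialTable:
    """Apply unit conversion to pupil series columns of a table."""
    table.check_stage_order("convert")
    out = table.copy()
    if columns is None:
        columns = [c for c in out.series if c.startswith("pupil")]
    for c in columns:
        out.series[c] = apply_calibration(model, out.series[c])
    out.record_stage("convert")
    return out


# ---------------------------------------------------------------------------
# baseline correction and exclusion


@dataclass
class BaselineSpec:
    """Baseline-correction settings: window and mode.

    Subtractive correction (recommended) subtracts the per-trial mean pupil
    size over the baseline window, so every corrected trial starts from 0
    during the baseline; divisive correction divides by it (starts from 1).
    """

    window: TimeWindow = field(default_factory=lambda: TimeWindow(0.0, 50.0))
    mode: str = "subtractive"

    def __post_init__(self) -> None:
        if self.mode not in ("subtractive", "divisive"):
            raise ValueError("mode must be 'subtractive' or 'divisive'")


def baseline_correct(
    column: np.ndarray,
    rate_hz: float,
    t0_ms: float,
    spec: BaselineSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-correct a series column; returns (corrected, baselines).

    The per-trial baseline is the mean over the window ignoring missing; an
    all-missing window makes the whole corrected trial missing (baseline
    NaN). Divisive mode with a zero baseline likewise yields a missing trial,
    with a warning.
    """
    spec = spec or BaselineSpec()
    arr = np.asarray(column, dtype=float)
    s, e = window_to_samples(rate_hz, t0_ms, spec.window, arr.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        baselines = np.nanmean(arr[:, s:e], axis=1)
    corrected = arr.copy()
    if spec.mode == "divisive":
        zero = baselines == 0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} trial(s) have a zero baseline; their "
                "divisively corrected traces are missing"
            )
            baselines = baselines.copy()
            baselines[zero] = np.nan
        corrected = corrected / baselines[:, None]
    else:
        corrected = corrected - baselines[:, None]
    corrected[np.isnan(baselines)] = np.nan
    return corrected, baselines


def baseline_correct_table(
    table: TrialTable,
    column: str,
    spec: BaselineSpec | None = None,
) -> tuple[TrialTable, np.ndarray]:
    """Baseline-correct a table's series column in place of the original;
    the per-trial baselines are stored as scalar column ``baseline_<name>``.
    """
    table.check_stage_order("baseline")
    out = table.copy()
    m = out.series_meta[column]
    corrected, baselines = baseline_correct(
        out.series[column], m.rate_hz, m.t0_ms, spec)
    out.series[column] = corrected
    out.scalars[f"baseline_{column}"] = baselines
    out.record_stage("baseline")
    return out, baselines


def exclude_baseline_outliers(
    table: TrialTable,
    baselines: np.ndarray,
    z_thresh: float = 2.0,
) -> tuple[TrialTable, np.ndarray, pd.DataFrame]:
    """Exclude trials whose z-scored baseline exceeds ``z_thresh``.

    z-scores are computed separately per participant (sample SD, n-1
    denominator); trials with |z| > z_thresh or a missing baseline are
    excluded. Returns (filtered table, exclusion mask, per-participant
    counts). A participant with zero baseline variance keeps all trials
    (z defined as 0) with a warning.
    """
    table.check_stage_order("exclude")
    baselines = np.asarray(baselines, dtype=float)
    if baselines.shape != (table.n_trials,):
        raise ValueError("baselines must align with the table rows")
    part = table.scalars["participant"].to_numpy()
    excluded = np.zeros(table.n_trials, dtype=bool)
    rows = []
    for p in table.participants:
        sel = part == p
        b = baselines[sel]
        valid = np.isfinite(b)
        if valid.sum() < 2:
            raise ValueError(
                f"participant {p!r} has fewer than 2 non-missing baselines"
            )
        mu = b[valid].mean()
        sd = b[valid].std(ddof=1)
        z = np.zeros_like(b)
        if sd == 0:
            warnings.warn(
                f"participant {p!r} has zero baseline variance; no trials "
                "excluded"
            )
        else:
            z[valid] = (b[valid] - mu) / sd
        out = (~valid) | (np.abs(z) > z_thresh)
        excluded[sel] = out
        rows.append({"participant": p, "n_trials": int(sel.sum()),
                     "n_excluded": int(out.sum())})
    filtered = table.subset(~excluded)
    filtered.record_stage("exclude")
    return filtered, excluded, pd.DataFrame(rows)
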