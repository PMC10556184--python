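"""Quantitative data-quality metrics for trial-epoched pupil data.

Four checks a pupillometrist should make before testing anything:

1. spike trials — traces that shoot downward out of the tangle of lines
   (blinks or artifacts the reconstruction missed); as a rule of thumb no
   more than 5% of trials should show such spikes;
2. the distribution of baseline pupil sizes per participant;
3. blink counts per trial, by condition and participant — blink rate must
   not differ systematically between conditions;
4. gaze deviation from the display center over time, by condition.

The condition-imbalance flags are an advisory screen (max pairwise condition
difference above 25% of the grand mean), never an inferential test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TrialTable, nanmean_series

__all__ = [
    "QCReport",
    "spike_trials",
    "blink_counts",
    "gaze_deviation",
    "qc_report",
]


def spike_trials(
    column: np.ndarray,
    k: float = 5.0,
    velocity_bound: float | None = None,
) -> tuple[np.ndarray, float]:
    """Flag trials with downward spikes; returns (per-trial mask, fraction).

    A trial is a spike trial if any sample lies more than ``k`` cross-trial
    SDs below the cross-trial mean trace, or (when ``velocity_bound`` is
    set, in signal units per sample) if any single-step change exceeds the
    bound. Operates on baseline-corrected data. Requires at least 3 trials
    for a stable mean trace.
    """
    arr = np.asarray(column, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need a series column with at least 3 trials")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_trace = np.nanmean(arr, axis=0)
        sd_trace = np.nanstd(arr, axis=0)
    with np.errstate(invalid="ignore"):
        below = arr < mean_trace - k * sd_trace
    mask = np.any(np.where(np.isnan(arr), False, below), axis=1)
    if velocity_bound is not None:
        step = np.abs(np.diff(arr, axis=1))
        with np.errstate(invalid="ignore"):
            fast = step > velocity_bound
        mask |= np.any(np.where(np.isnan(step), False, fast), axis=1)
    return mask, float(mask.mean())


def _missing_runs_per_trial(arr: np.ndarray, min_len: int) -> np.ndarray:
    """Number of maximal missing runs of at least ``min_len`` samples."""
    counts = np.zeros(arr.shape[0], dtype=int)
    isnan = np.isnan(arr)
    for i in range(arr.shape[0]):
        row = isnan[i]
        if not row.any():
            continue
        padded = np.concatenate([[0], row.astype(int), [0]])
        d = np.diff(padded)
        starts = np.where(d == 1)[0]
        ends = np.where(d == -1)[0]
        counts[i] = int(np.sum((ends - starts) >= min_len))
    return counts


def _imbalance(by_condition: pd.Series) -> bool:
    grand = by_condition.mean()
    if not np.isfinite(grand) or grand <= 0 or len(by_condition) < 2:
        return False
    return bool(by_condition.max() - by_condition.min() > 0.25 * grand)


def blink_counts(
    table: TrialTable,
    by: str,
    events: np.ndarray | None = None,
    column: str | None = None,
    min_dur_ms: float = 50.0,
) -> tuple[pd.DataFrame, bool]:
    """Mean blinks per trial by participant and condition.

    Counts come from recorded per-trial blink events when ``events`` is
    given (e.g. the tracker's own blink detection, or the simulator's
    ``n_blinks`` column); otherwise maximal missing runs of at least
    ``min_dur_ms`` in a pre-reconstruction series column serve as an easy
    proxy. Returns the per-participant x condition table of means and an
    advisory condition-imbalance flag.
    """
    if by not in table.scalars.columns:
        raise ValueError(f"condition column {by!r} not found")
    if events is not None:
        counts = np.asarray(events, dtype=float)
    else:
        if column is None:
            column = next(c for c in table.series if c.startswith("pupil"))
        meta = table.series_meta[column]
        min_len = max(1, int(round(min_dur_ms * meta.rate_hz / 1000.0)))
        counts = _missing_runs_per_trial(table.series[column], min_len)
    df = pd.DataFrame({
        "participant": table.scalars["participant"],
        "condition": table.scalars[by],
        "blinks": counts,
    })
    means = df.pivot_table(index="participant", columns="condition",
                           values="blinks", aggfunc="mean")
    flag = _imbalance(df.groupby("condition")["blinks"].mean())
    return means, flag


def gaze_deviation(
    table: TrialTable,
    x_column: str,
    y_column: str,
    center_px: tuple,
    px_per_degree: float,
    by: str | None = None,
) -> dict:
    """Condition-wise mean absolute gaze deviation traces, in degrees.

    Returns ``{condition: (horizontal trace, vertical trace)}``; with
    ``by=None`` a single entry keyed ``"all"``.
    """
    if px_per_degree <= 0:
        raise ValueError("px_per_degree must be > 0")
    dx = np.abs(table.series[x_column] - center_px[0]) / px_per_degree
    dy = np.abs(table.series[y_column] - center_px[1]) / px_per_degree
    out = {}
    if by is None:
        out["all"] = (nanmean_series(dx), nanmean_series(dy))
        return out
    cond = table.scalars[by].to_numpy()
    for c in pd.unique(cond):
        sel = cond == c
        out[c] = (nanmean_series(dx[sel]), nanmean_series(dy[sel]))
    return out


@dataclass
class QCReport:
    """Per-participant quality metrics with advisory flags."""

    participants: list
    spike_fraction: dict          # participant -> fraction
    missing_fraction: dict        # participant -> fraction of missing samples
    baseline_summary: dict        # participant -> {mean, sd, skew, hist, edges}
    blink_means: pd.DataFrame     # participant x condition mean blink counts
    gaze: dict                    # condition -> (horiz, vert) degree traces
    spike_flags: dict             # participant -> fraction > threshold
    blink_imbalance: bool
    gaze_imbalance: bool
    spike_threshold: float = 0.05

    @property
    def any_flag(self) -> bool:
        return (any(self.spike_flags.values()) or self.blink_imbalance
                or self.gaze_imbalance)

    def to_dict(self) -> dict:
        return {
            "participants": [str(p) for p in self.participants],
            "spike_fraction": {str(k): v for k, v in self.spike_fraction.items()},
            "missing_fraction": {str(k): v for k, v in self.missing_fraction.items()},
            "baseline_summary": {
                str(k): {kk: (vv if not isinstance(vv, np.ndarray) else vv.tolist())
                         for kk, vv in v.items()}
                for k, v in self.baseline_summary.items()},
            "blink_means": {str(k): dict(v.dropna()) for k, v in
                            self.blink_means.iterrows()},
            "spike_flags": {str(k): bool(v) for k, v in self.spike_flags.items()},
            "blink_imbalance": self.blink_imbalance,
            "gaze_imbalance": self.gaze_imbalance,
            "spike_threshold": self.spike_threshold,
        }


def qc_report(
    table: TrialTable,
    corrected_column: str,
    baselines: np.ndarray,
    raw_column: str | None = None,
    condition: str | None = None,
    x_column: str | None = None,
    y_column: str | None = None,
    center_px: tuple = (512.0, 384.0),
    px_per_degree: float = 35.0,
    spike_k: float = 5.0,
    spike_threshold: float = 0.05,
    blink_min_dur_ms: float = 50.0,
    blink_events: np.ndarray | None = None,
) -> QCReport:
    """Aggregate the quality metrics into one per-participant report.

    ``corrected_column`` is the baseline-corrected series used for spike
    detection (collapsed across conditions, so the assessment cannot be
    biased by the hypothesized effect); ``raw_column`` is the
    pre-reconstruction series used for the blink proxy.
    """
    part = table.scalars["participant"].to_numpy()
    baselines = np.asarray(baselines, dtype=float)
    spike_fraction, missing_fraction, baseline_summary, flags = {}, {}, {}, {}
    for p in table.participants:
        sel = part == p
        arr = table.series[corrected_column][sel]
        if sel.sum() >= 3:
            _, frac = spike_trials(arr, k=spike_k)
        else:
            frac = 0.0
        spike_fraction[p] = frac
        flags[p] = frac > spike_threshold
        missing_fraction[p] = float(np.mean(np.isnan(arr)))
        b = baselines[sel]
        b = b[np.isfinite(b)]
        if b.size:
            hist, edges = np.histogram(b, bins=20)
            sd = b.std(ddof=1) if b.size > 1 else 0.0
            skew = (float(np.mean(((b - b.mean()) / sd) ** 3))
                    if sd > 0 else 0.0)
            baseline_summary[p] = {"mean": float(b.mean()), "sd": float(sd),
                                   "skew": skew, "hist": hist, "edges": edges}
        else:
            baseline_summary[p] = {"mean": np.nan, "sd": np.nan, "skew": np.nan,
                                   "hist": np.zeros(0), "edges": np.zeros(0)}

    cond_col = condition if condition is not None else None
    if cond_col is not None:
        blink_means, blink_flag = blink_counts(
            table, cond_col, events=blink_events,
            column=raw_column or corrected_column, min_dur_ms=blink_min_dur_ms)
    else:
        blink_means, blink_flag = pd.DataFrame(), False

    gaze = {}
    gaze_flag = False
    if x_column and y_column:
        gaze = gaze_deviation(table, x_column, y_column, center_px,
                              px_per_degree, by=cond_col)
        if len(gaze) > 1:
            means = pd.Series({c: np.nanmean(np.concatenate(tr))
                               for c, tr in gaze.items()})
            gaze_flag = _imbalance(means)
    return QCReport(
        participants=table.participants,
        spike_fraction=spike_fraction,
        missing_fraction=missing_fraction,
        baseline_summary=baseline_summary,
        blink_means=blink_means,
        gaze=gaze,
        spike_flags=flags,
        blink_imbalance=blink_flag,
        gaze_imbalance=gaze_flag,
        spike_threshold=spike_threshold,
    )
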