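"""Figure helpers for quality checks and trace plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core import TrialTable, nanmean_series  # noqa: E402

__all__ = [
    "plot_traces",
    "plot_baseline_histogram",
    "plot_blink_counts",
    "plot_gaze_deviation",
    "plot_condition_traces",
]


def _times(table: TrialTable, column: str) -> np.ndarray:
    m = table.series_meta[column]
    n = table.series[column].shape[1]
    return m.t0_ms + np.arange(n) * 1000.0 / m.rate_hz


def plot_traces(table: TrialTable, column: str, ax=None, alpha: float = 0.1):
    """All trials of a series column as semitransparent lines (one panel,
    collapsed across conditions)."""
    ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
    t = _times(table, column)
    for row in table.series[column]:
        ax.plot(t, row, color="steelblue", alpha=alpha, lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("pupil size")
    return ax


def plot_baseline_histogram(baselines, z_thresh: float = 2.0, ax=None):
    """Histogram of baseline pupil sizes with the exclusion bounds marked."""
    ax = ax or plt.figure(figsize=(5, 4)).add_subplot()
    b = np.asarray(baselines, dtype=float)
    b = b[np.isfinite(b)]
    ax.hist(b, bins=30, color="steelblue")
    if b.size > 1:
        mu, sd = b.mean(), b.std(ddof=1)
        for bound in (mu - z_thresh * sd, mu + z_thresh * sd):
            ax.axvline(bound, color="firebrick", ls="--", lw=1)
    ax.set_xlabel("baseline pupil size")
    ax.set_ylabel("count")
    return ax


def plot_blink_counts(blink_means, ax=None):
    """Mean blinks per trial by participant and condition."""
    ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
    blink_means.plot(kind="bar", ax=ax)
    ax.set_ylabel("mean blinks per trial")
    return ax


def plot_gaze_deviation(gaze: dict, times: np.ndarray, axes=None):
    """Horizontal and vertical gaze-deviation traces per condition."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for cond, (hx, hy) in gaze.items():
        axes[0].plot(times, hx, label=str(cond))
        axes[1].plot(times, hy, label=str(cond))
    axes[0].set_title("horizontal")
    axes[1].set_title("vertical")
    for ax in axes:
        ax.set_xlabel("time (ms)")
    axes[0].set_ylabel("deviation (deg)")
    axes[0].legend()
    return axes


def plot_condition_traces(table: TrialTable, column: str, by: str,
                          marker_sample: float | None = None, ax=None):
    """Mean pupil trace per condition, with an optional vertical line at the
    (mean) tested sample of a cross-validation result."""
    ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
    t = _times(table, column)
    cond = table.scalars[by].to_numpy()
    for c in dict.fromkeys(cond):
        sel = cond == c
        ax.plot(t, nanmean_series(table.series[column][sel]), label=str(c))
    if marker_sample is not None:
        m = table.series_meta[column]
        ax.axvline(m.t0_ms + marker_sample * 1000.0 / m.rate_hz,
                   color="black", lw=1)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("pupil size")
    ax.legend(title=by)
    return ax
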