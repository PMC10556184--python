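"""Trial-epoched data model shared by all pupillometry modules.

Conventions
-----------
* Time is in milliseconds everywhere; sample indices are 0-based.
* All time windows and index ranges are half-open ``[start, end)``.
* Sample ``i`` of a trace covers ``[t0_ms + i*dt, t0_ms + (i+1)*dt)`` with
  ``dt = 1000 / rate_hz``.
* Missing data is represented by ``numpy.nan``; raw streams that code missing
  pupil size as 0 are recoded at parse time.
* Ragged epochs are right-padded with NaN to the longest epoch; the original
  (unpadded) length of every trial is recorded per series column.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PupilTrace",
    "TimeWindow",
    "TrialTable",
    "window_to_samples",
    "nanmean_series",
]


@dataclass
class PupilTrace:
    """One epoch's pupil samples.

    Parameters
    ----------
    values
        Pupil-size measurements (arbitrary units or mm). Missing samples are
        NaN; any other non-finite value is invalid.
    rate_hz
        Sampling rate in Hz.
    t0_ms
        Time of sample 0 relative to epoch onset, in ms.
    """

    values: np.ndarray
    rate_hz: float
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a 1-D array with length >= 1")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be > 0")
        if np.any(np.isinf(self.values)):
            raise ValueError("trace contains non-finite, non-NaN values")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def n_samples(self) -> int:
        return self.values.size

    def times(self) -> np.ndarray:
        """Start time (ms) of every sample."""
        return self.t0_ms + np.arange(self.n_samples) * self.dt_ms

    def copy(self) -> "PupilTrace":
        return PupilTrace(self.values.copy(), self.rate_hz, self.t0_ms)


@dataclass(frozen=True)
class TimeWindow:
    """Half-open epoch-relative time window ``[start_ms, end_ms)``."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(
                f"start_ms ({self.start_ms}) must be < end_ms ({self.end_ms})"
            )

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def window_to_samples(
    rate_hz: float,
    t0_ms: float,
    window: TimeWindow,
    n_samples: int,
) -> tuple[int, int]:
    """Map a time window to the half-open sample-index range covering it.

    Sample ``i`` covers ``[t0 + i*dt, t0 + (i+1)*dt)``; every sample whose
    interval overlaps the window is included. Raises if the window does not
    overlap the epoch at all.
    """
    if not rate_hz > 0:
        raise ValueError("rate_hz must be > 0")
    dt = 1000.0 / rate_hz
    # overlap condition: i*dt + dt > start - t0  and  i*dt < end - t0
    lo = (window.start_ms - t0_ms) / dt
    hi = (window.end_ms - t0_ms) / dt
    start = max(0, int(math.floor(lo + 1e-9)))
    end = min(n_samples, int(math.ceil(hi - 1e-9)))
    if start >= end:
        extent = (t0_ms, t0_ms + n_samples * dt)
        raise ValueError(
            f"window [{window.start_ms}, {window.end_ms}) does not overlap the "
            f"epoch extent [{extent[0]}, {extent[1]}) ms"
        )
    return start, end


def nanmean_series(column: np.ndarray, axis: str = "trials") -> np.ndarray:
    """Mean of a series column ignoring missing values.

    Parameters
    ----------
    column
        ``n_trials x n_samples`` array.
    axis
        ``"trials"`` averages over trials (returns one value per sample);
        ``"time"`` averages over samples (returns one value per trial).
    All-missing slices yield NaN.
    """
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ValueError("column is empty")
    if axis not in ("trials", "time"):
        raise ValueError("axis must be 'trials' or 'time'")
    ax = 0 if axis == "trials" else 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(column, axis=ax)


@dataclass
class SeriesMeta:
    """Per-series-column metadata: sampling and ragged-epoch padding record."""

    rate_hz: float
    t0_ms: float = 0.0
    # unpadded length per trial; None means all trials are full-width
    valid_lengths: np.ndarray | None = None


class TrialTable:
    """Trials as rows: scalar columns coexisting with series columns.

    Scalar columns hold one value per trial (participant id, condition label,
    response time, ...). Series columns are ``n_trials x n_samples`` float
    arrays sharing one sampling rate and epoch-zero time per column. Row order
    is the chronological trial order within participant, participants
    concatenated; the cross-validation split depends on this order.
    """

    STAGES = ("parse", "reconstruct", "downsample", "convert", "baseline", "exclude")

    def __init__(
        self,
        scalars: pd.DataFrame,
        series: dict[str, np.ndarray] | None = None,
        series_meta: dict[str, SeriesMeta] | None = None,
        history: list[str] | None = None,
    ):
        scalars = pd.DataFrame(scalars).reset_index(drop=True)
        if "participant" not in scalars.columns:
            raise ValueError("a 'participant' scalar column is required")
        self.scalars = scalars
        self.series: dict[str, np.ndarray] = {}
        self.series_meta: dict[str, SeriesMeta] = {}
        self.history: list[str] = list(history or [])
        series = series or {}
        series_meta = series_meta or {}
        for name, arr in series.items():
            meta = series_meta.get(name)
            if meta is None:
                raise ValueError(f"series column {name!r} has no SeriesMeta")
            self.add_series(name, arr, meta)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.scalars)

    @property
    def participants(self) -> list:
        seen: list = []
        for p in self.scalars["participant"]:
            if p not in seen:
                seen.append(p)
        return seen

    def add_series(self, name: str, arr: np.ndarray, meta: SeriesMeta) -> None:
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"series column {name!r} must be 2-D")
        if arr.shape[0] != self.n_trials:
            raise ValueError(
                f"series column {name!r} has {arr.shape[0]} rows, "
                f"expected {self.n_trials}"
            )
        if not meta.rate_hz > 0:
            raise ValueError("rate_hz must be > 0")
        self.series[name] = arr
        vl = meta.valid_lengths
        if vl is not None:
            vl = np.asarray(vl, dtype=int)
            if vl.shape != (arr.shape[0],):
                raise ValueError("valid_lengths must have one entry per trial")
        self.series_meta[name] = SeriesMeta(meta.rate_hz, meta.t0_ms, vl)

    def trace(self, name: str, i: int) -> PupilTrace:
        """Trial ``i`` of series column ``name`` as a :class:`PupilTrace`."""
        m = self.series_meta[name]
        return PupilTrace(self.series[name][i].copy(), m.rate_hz, m.t0_ms)

    def subset(self, mask: np.ndarray) -> "TrialTable":
        """Row subset (boolean mask or index array), preserving order."""
        mask = np.asarray(mask)
        scalars = self.scalars.loc[mask].reset_index(drop=True) if mask.dtype == bool \
            else self.scalars.iloc[mask].reset_index(drop=True)
        out = TrialTable(scalars, history=list(self.history))
        for name, arr in self.series.items():
            m = self.series_meta[name]
            vl = None if m.valid_lengths is None else m.valid_lengths[mask]
            out.add_series(name, arr[mask], SeriesMeta(m.rate_hz, m.t0_ms, vl))
        return out

    def copy(self) -> "TrialTable":
        out = TrialTable(self.scalars.copy(), history=list(self.history))
        for name, arr in self.series.items():
            m = self.series_meta[name]
            vl = None if m.valid_lengths is None else m.valid_lengths.copy()
            out.add_series(name, arr.copy(), SeriesMeta(m.rate_hz, m.t0_ms, vl))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        if not self.scalars.equals(other.scalars):
            return False
        if set(self.series) != set(other.series):
            return False
        for name in self.series:
            a, b = self.series[name], other.series[name]
            if a.shape != b.shape or not np.array_equal(a, b, equal_nan=True):
                return False
            ma, mb = self.series_meta[name], other.series_meta[name]
            if ma.rate_hz != mb.rate_hz or ma.t0_ms != mb.t0_ms:
                return False
            va = ma.valid_lengths
            vb = mb.valid_lengths
            if (va is None) != (vb is None):
                return False
            if va is not None and not np.array_equal(va, vb):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"TrialTable(n_trials={self.n_trials}, "
            f"scalars={list(self.scalars.columns)}, "
            f"series={list(self.series)})"
        )

    # -- bundle serialization ---------------------------------------------
    # A bundle directory holds scalars.csv, series_<name>.csv (one row per
    # trial, NaN written as 'nan') and meta.json (rate_hz, t0_ms, padding
    # record and stage history).

    def to_bundle(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scalars.to_csv(directory / "scalars.csv", index=False)
        meta: dict = {"history": self.history, "series": {}}
        for name, arr in self.series.items():
            m = self.series_meta[name]
            np.savetxt(directory / f"series_{name}.csv", arr, delimiter=",", fmt="%.10g")
            meta["series"][name] = {
                "rate_hz": m.rate_hz,
                "t0_ms": m.t0_ms,
                "valid_lengths": None if m.valid_lengths is None
                else [int(v) for v in m.valid_lengths],
            }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def from_bundle(cls, directory: str | Path) -> "TrialTable":
        directory = Path(directory)
        scalars = pd.read_csv(directory / "scalars.csv")
        meta = json.loads((directory / "meta.json").read_text())
        table = cls(scalars, history=meta.get("history", []))
        for name, m in meta["series"].items():
            arr = np.loadtxt(directory / f"series_{name}.csv", delimiter=",", ndmin=2)
            vl = m.get("valid_lengths")
            table.add_series(
                name,
                arr,
                SeriesMeta(m["rate_hz"], m["t0_ms"], None if vl is None else np.asarray(vl)),
            )
        return table

    # -- preprocessing-stage bookkeeping -----------------------------------
    def record_stage(self, stage: str) -> None:
        if stage not in self.STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.check_stage_order(stage)
        self.history.append(stage)

    def check_stage_order(self, stage: str) -> None:
        """Raise if running ``stage`` now would violate the pipeline order.

        Stages must run in the fixed order parse -> reconstruct -> downsample
        -> convert -> baseline -> exclude; stages may be skipped or repeated,
        but never run before an already-completed later stage.
        """
        idx = self.STAGES.index(stage)
        done = [self.STAGES.index(s) for s in self.history if s in self.STAGES]
        if done and idx < max(done):
            raise PipelineOrderError(
                f"stage {stage!r} cannot run after "
                f"{self.STAGES[max(done)]!r}; required order is "
                + " -> ".join(self.STAGES)
            )


class PipelineOrderError(RuntimeError):
    """Raised when preprocessing stages are invoked out of order."""
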