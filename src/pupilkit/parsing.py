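"""Parsers for raw eye-tracker ASCII logs and long-format sample tables.

ASCII dialect
-------------
The reader understands an EyeLink-ASC-inspired plain-text dialect (the
vendor's binary format is proprietary and out of scope):

* sample lines: ``<timestamp> <x> <y> <pupil>``, whitespace-delimited,
  timestamps in ms;
* message lines: ``MSG <timestamp> <payload>`` where the payload is one of
  the protocol markers: ``start_trial`` / ``end_trial``,
  ``start_phase <name>`` / ``end_phase <name>``, or ``var <name> <value>``.

Samples outside a phase are ignored. A pupil value of 0 codes missing data
and is recoded to NaN on ingest. The sampling rate is inferred as the modal
inter-sample interval; dropped samples (gaps in the timestamps) are filled
with missing samples so the time axis stays uniform. Epoch time 0 is the
first sample of each phase.

Binocular recordings are out of scope: the parser assumes monocular sample
lines (for binocular files, pre-select one eye's columns).
"""

from __future__ import annotations

import io
import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SeriesMeta, TrialTable

logger = logging.getLogger(__name__)

__all__ = [
    "MessageProtocol",
    "parse_ascii_log",
    "parse_long_table",
    "write_ascii_log",
]

_SIGNALS = ("pupil", "x", "y")


@dataclass
class MessageProtocol:
    """Marker strings of the message protocol embedded in a recording."""

    trial_start: str = "start_trial"
    trial_end: str = "end_trial"
    phase_start: str = "start_phase"
    phase_end: str = "end_phase"
    var: str = "var"

    @classmethod
    def from_dict(cls, d: dict) -> "MessageProtocol":
        known = {f: d[f] for f in
                 ("trial_start", "trial_end", "phase_start", "phase_end", "var")
                 if f in d}
        return cls(**known)


def _coerce(value: str):
    """Parse a var value as a number when fully numeric, else keep text."""
    try:
        f = float(value)
    except ValueError:
        return value
    if f.is_integer() and "." not in value and "e" not in value.lower():
        return int(f)
    return f


def _iter_lines(source):
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, io.TextIOBase):
        yield from source
    else:
        yield from source


def parse_ascii_log(
    source,
    protocol: MessageProtocol | None = None,
) -> TrialTable:
    """Parse an ASCII eye-tracker log into a :class:`TrialTable`.

    ``source`` is a path, an open text file, or an iterable of lines.
    One row per complete trial; one series column per phase per signal
    (``pupil_<phase>``, ``x_<phase>``, ``y_<phase>``); one scalar column per
    distinct ``var`` name. Unterminated trials are dropped with a warning;
    unparseable sample lines are skipped with a warning; non-monotonic
    timestamps within a trial raise.
    """
    protocol = protocol or MessageProtocol()
    trials: list[dict] = []
    cur: dict | None = None
    cur_phase: str | None = None
    last_ts: float | None = None
    n_bad_lines = 0

    for raw in _iter_lines(source):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if tokens[0] == "MSG":
            if len(tokens) < 3:
                n_bad_lines += 1
                continue
            payload = tokens[2:]
            if payload[0] == protocol.trial_start:
                if cur is not None:
                    warnings.warn("unterminated trial dropped")
                cur = {"phases": {}, "vars": {}, "order": []}
                cur_phase = None
                last_ts = None
            elif payload[0] == protocol.trial_end:
                if cur is not None:
                    trials.append(cur)
                cur = None
                cur_phase = None
            elif cur is None:
                continue
            elif payload[0] == protocol.phase_start and len(payload) >= 2:
                cur_phase = payload[1]
                if cur_phase not in cur["phases"]:
                    cur["phases"][cur_phase] = []
                    cur["order"].append(cur_phase)
            elif payload[0] == protocol.phase_end:
                cur_phase = None
            elif payload[0] == protocol.var and len(payload) >= 3:
                cur["vars"][payload[1]] = _coerce(" ".join(payload[2:]))
            continue
        # sample line
        if cur is None or cur_phase is None:
            continue
        if len(tokens) != 4:
            n_bad_lines += 1
            continue
        try:
            ts, gx, gy, pupil = (float(t) for t in tokens)
        except ValueError:
            n_bad_lines += 1
            continue
        if last_ts is not None and ts <= last_ts:
            raise ValueError(
                f"non-monotonic timestamp {ts} within a trial"
            )
        last_ts = ts
        cur["phases"][cur_phase].append((ts, gx, gy, pupil))

    if cur is not None:
        warnings.warn("unterminated trial at end of stream dropped")
    if n_bad_lines:
        warnings.warn(f"skipped {n_bad_lines} unparseable line(s)")
    if not trials:
        raise ValueError("no trials found")

    # modal inter-sample interval over the whole file
    diffs = Counter()
    for tr in trials:
        for samples in tr["phases"].values():
            ts = np.array([s[0] for s in samples])
            if ts.size > 1:
                d = np.diff(ts)
                diffs.update(np.round(d, 6).tolist())
    if diffs:
        dt = float(diffs.most_common(1)[0][0])
    else:
        dt = 1.0
    rate_hz = round(1000.0 / dt)
    dt = 1000.0 / rate_hz

    # assemble per-phase series on a uniform grid
    phase_names: list[str] = []
    for tr in trials:
        for ph in tr["order"]:
            if ph not in phase_names:
                phase_names.append(ph)

    rows = []
    for i, tr in enumerate(trials):
        row = dict(tr["vars"])
        rows.append(row)
    scalars = pd.DataFrame(rows)
    if "participant" not in scalars.columns:
        scalars["participant"] = 0
    table = TrialTable(scalars, history=["parse"])

    for ph in phase_names:
        per_trial = []
        for tr in trials:
            samples = tr["phases"].get(ph, [])
            if not samples:
                per_trial.append(np.full((0, 3), np.nan))
                continue
            ts0 = samples[0][0]
            idx = [int(round((s[0] - ts0) / dt)) for s in samples]
            width = idx[-1] + 1
            grid = np.full((width, 3), np.nan)
            for k, s in zip(idx, samples):
                grid[k] = s[1:]
            per_trial.append(grid)
        width = max(g.shape[0] for g in per_trial)
        if width == 0:
            continue
        valid_lengths = np.array([g.shape[0] for g in per_trial])
        # sample tuples are (x, y, pupil) in columns 0, 1, 2
        for sig, col in (("x", 0), ("y", 1), ("pupil", 2)):
            arr = np.full((len(trials), width), np.nan)
            for i, g in enumerate(per_trial):
                arr[i, : g.shape[0]] = g[:, col]
            if sig == "pupil":
                arr[arr == 0] = np.nan  # 0-coded missing recoded on ingest
            pad = None if np.all(valid_lengths == width) else valid_lengths
            table.add_series(f"{sig}_{ph}", arr,
                             SeriesMeta(rate_hz, 0.0, pad))
    return table


def write_ascii_log(
    table: TrialTable,
    protocol: MessageProtocol | None = None,
) -> str:
    """Serialize a table back to the ASCII dialect (round-trip writer).

    Missing samples are written with pupil value 0 (the raw stream's missing
    code); padding cells beyond a trial's recorded length are not written.
    ``parse_ascii_log(write_ascii_log(t))`` reproduces ``t`` up to padding.
    """
    protocol = protocol or MessageProtocol()
    # group series columns by phase: names are <signal>_<phase>
    phases: dict[str, dict[str, str]] = {}
    for name in table.series:
        for sig in _SIGNALS:
            if name.startswith(sig + "_"):
                phases.setdefault(name[len(sig) + 1:], {})[sig] = name
                break
    out = io.StringIO()
    ts = 1000
    for i in range(table.n_trials):
        out.write(f"MSG {ts} {protocol.trial_start}\n")
        ts += 1
        for ph, cols in phases.items():
            ref = next(iter(cols.values()))
            meta = table.series_meta[ref]
            dt = 1000.0 / meta.rate_hz
            width = table.series[ref].shape[1]
            stop = width if meta.valid_lengths is None \
                else int(meta.valid_lengths[i])
            out.write(f"MSG {ts} {protocol.phase_start} {ph}\n")
            ts += 1
            t0 = ts
            for k in range(stop):
                vals = {}
                for sig in _SIGNALS:
                    col = cols.get(sig)
                    v = table.series[col][i, k] if col is not None else 0.0
                    vals[sig] = 0.0 if np.isnan(v) else v
                stamp = t0 + int(round(k * dt))
                out.write(f"{stamp} {vals['x']:.6g} {vals['y']:.6g} "
                          f"{vals['pupil']:.10g}\n")
            ts = t0 + int(round(stop * dt))
            out.write(f"MSG {ts} {protocol.phase_end} {ph}\n")
            ts += 1
        for name in table.scalars.columns:
            v = table.scalars[name].iloc[i]
            out.write(f"MSG {ts} {protocol.var} {name} {v}\n")
            ts += 1
        out.write(f"MSG {ts} {protocol.trial_end}\n")
        ts += 10
    return out.getvalue()


def parse_long_table(source, sep: str = ",") -> TrialTable:
    """Parse a long-format delimited sample table into a :class:`TrialTable`.

    Required columns: ``trial``, ``participant``, ``phase``, ``t_ms``,
    ``pupil``; optional gaze columns ``x`` and ``y``; any other column is a
    per-trial scalar and must be constant within a trial (a conflict raises,
    naming the trial and column). Rows are grouped by participant in order
    of first appearance, chronological (first-appearance trial order) within
    participant. A pupil value of 0 is recoded to missing.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=sep)
    required = ["trial", "participant", "phase", "t_ms", "pupil"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    gaze = [c for c in ("x", "y") if c in df.columns]
    scalar_cols = [c for c in df.columns
                   if c not in required + gaze]

    # infer sampling rate from the modal within-phase interval
    diffs = Counter()
    grouped = df.groupby(["participant", "trial", "phase"], sort=False)
    for _, g in grouped:
        t = np.sort(g["t_ms"].to_numpy(dtype=float))
        if t.size > 1:
            diffs.update(np.round(np.diff(t), 6).tolist())
    dt = float(diffs.most_common(1)[0][0]) if diffs else 1.0
    rate_hz = round(1000.0 / dt)
    dt = 1000.0 / rate_hz

    # row order: participants by first appearance, trials likewise
    order: list[tuple] = []
    for p, tr in zip(df["participant"], df["trial"]):
        if (p, tr) not in order:
            order.append((p, tr))
    parts_seen: list = []
    for p, _ in order:
        if p not in parts_seen:
            parts_seen.append(p)
    appearance = {k: i for i, k in enumerate(order)}
    order.sort(key=lambda k: (parts_seen.index(k[0]), appearance[k]))

    rows = []
    per_phase: dict[str, list] = {}
    phase_names = list(dict.fromkeys(df["phase"]))
    for p, tr in order:
        g = df[(df["participant"] == p) & (df["trial"] == tr)]
        row = {"participant": p, "trial": tr}
        for c in scalar_cols:
            vals = g[c].drop_duplicates()
            if len(vals) > 1:
                raise ValueError(
                    f"conflicting values for scalar column {c!r} in trial "
                    f"{tr!r} of participant {p!r}"
                )
            row[c] = vals.iloc[0]
        rows.append(row)
        for ph in phase_names:
            gp = g[g["phase"] == ph].sort_values("t_ms")
            t = gp["t_ms"].to_numpy(dtype=float)
            if t.size == 0:
                per_phase.setdefault(ph, []).append(
                    {s: np.empty(0) for s in ["pupil"] + gaze})
                continue
            idx = np.round((t - t[0]) / dt).astype(int)
            width = int(idx[-1]) + 1
            rec = {}
            for s in ["pupil"] + gaze:
                grid = np.full(width, np.nan)
                grid[idx] = gp[s].to_numpy(dtype=float)
                rec[s] = grid
            per_phase.setdefault(ph, []).append(rec)

    scalars = pd.DataFrame(rows)
    table = TrialTable(scalars, history=["parse"])
    for ph in phase_names:
        recs = per_phase[ph]
        width = max(r["pupil"].size for r in recs)
        if width == 0:
            continue
        valid = np.array([r["pupil"].size for r in recs])
        pad = None if np.all(valid == width) else valid
        for s in ["pupil"] + gaze:
            arr = np.full((len(recs), width), np.nan)
            for i, r in enumerate(recs):
                arr[i, : r[s].size] = r[s]
            if s == "pupil":
                arr[arr == 0] = np.nan
            table.add_series(f"{s}_{ph}", arr, SeriesMeta(rate_hz, 0.0, pad))
    return table
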