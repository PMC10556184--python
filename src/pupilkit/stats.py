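"""Inference procedures for pupil time series.

Three ways to answer "does my manipulation affect pupil size at all?" for an
autocorrelated signal sampled many times per trial:

* :class:`WindowModel` — a single linear mixed-effects test on the mean
  pupil size over a predetermined time window (no multiple-comparison
  problem, but requires knowing the window in advance);
* :class:`ClusterPermutationModel` — per-sample tests, clusters of
  contiguous significant samples, and a permutation null distribution of
  maximum cluster sizes obtained by shuffling condition labels;
* :class:`CrossValidationModel` — k-fold (default four-fold) interleaved
  cross-validation: each fold's training set localizes the sample with the
  largest |z|, the held-out trials are tested at that sample, and one final
  mixed model on the assembled per-trial values gives the z and p values.
  Fully deterministic.

All procedures share the mixed-effects model contract: Wald z per fixed
effect with two-tailed normal-approximation p values. Final models are
estimated with statsmodels ``MixedLM``; the per-sample engine inside
localization and permutations is the vectorised random-intercept solver in
:mod:`pupilkit._gls` (full mixed-model optimisation per sample per
permutation is computationally prohibitive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from ._gls import RandomInterceptGLS
from .core import TimeWindow, TrialTable, window_to_samples

__all__ = [
    "ModelSpec",
    "FitResult",
    "ClusterPermResult",
    "CVTestResult",
    "WindowModel",
    "ClusterPermutationModel",
    "CrossValidationModel",
    "fit_lmm",
    "window_test",
    "persample_tests",
    "find_clusters",
    "cluster_permutation_test",
    "interleaved_split",
    "crossval_test",
]


@dataclass
class ModelSpec:
    """Model specification shared by all test procedures.

    ``dependent`` names a series column; ``fixed`` lists scalar predictors
    (``"a"``) and interactions (``"a:b"``); ``coding`` optionally maps a
    column's labels to numbers (e.g. near/medium/far -> -1/0/1); ``random``
    is ``"intercept"`` (by-participant random intercept) or ``"slopes"``
    (intercept plus by-participant random slopes for the fixed effects).
    """

    dependent: str
    fixed: list
    coding: dict = field(default_factory=dict)
    random: str = "intercept"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.fixed:
            raise ValueError("at least one fixed effect is required")
        if self.random not in ("intercept", "slopes"):
            raise ValueError("random must be 'intercept' or 'slopes'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _column_values(scalars: pd.DataFrame, col: str, coding: dict) -> np.ndarray:
    if col not in scalars.columns:
        raise ValueError(f"predictor {col!r} not found in the table")
    v = scalars[col]
    if col in coding:
        mapped = v.map(coding[col])
        if mapped.isna().any() and not v.isna().any():
            bad = sorted(set(v[mapped.isna()]))
            raise ValueError(f"no code for level(s) {bad} of {col!r}")
        return mapped.to_numpy(dtype=float)
    arr = pd.to_numeric(v, errors="coerce").to_numpy(dtype=float)
    if np.isnan(arr).any() and not v.isna().any():
        raise ValueError(
            f"predictor {col!r} is not numeric; provide a coding for it"
        )
    return arr


def build_design(scalars: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list]:
    """Fixed-effects design matrix (with intercept) and term names."""
    cols = [np.ones(len(scalars))]
    names = ["Intercept"]
    for term in spec.fixed:
        parts = term.split(":")
        v = _column_values(scalars, parts[0], spec.coding)
        for p in parts[1:]:
            v = v * _column_values(scalars, p, spec.coding)
        cols.append(v)
        names.append(term)
    return np.column_stack(cols), names


@dataclass
class FitResult:
    """Coefficient table of one mixed-effects fit.

    Per fixed effect: estimate, standard error, Wald z = estimate / SE, and
    the two-tailed normal-approximation p value.
    """

    names: list
    estimates: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    nobs: int
    method: str = "MixedLM"

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimates, "se": self.se,
             "z": self.z, "p": self.p},
            index=self.names,
        )

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {"estimate": self.estimates[i], "se": self.se[i],
                "z": self.z[i], "p": self.p[i]}

    def summary(self) -> str:
        lines = [f"Mixed-effects fit ({self.method}); n = {self.nobs}; "
                 f"converged = {self.converged}"]
        lines.append(f"{'term':<20}{'estimate':>13}{'SE':>13}{'z':>9}{'p':>10}")
        for i, name in enumerate(self.names):
            lines.append(
                f"{name:<20}{self.estimates[i]:>13.5g}{self.se[i]:>13.5g}"
                f"{self.z[i]:>9.2f}{self.p[i]:>10.4g}"
            )
        return "\n".join(lines)


def fit_lmm(data: pd.DataFrame, y: np.ndarray, spec: ModelSpec) -> FitResult:
    """Fit a linear mixed-effects model with participant random effects.

    Rows with a missing dependent value are dropped. Non-convergence is
    flagged on the result, never raised. Requires at least 2 participants.
    """
    y = np.asarray(y, dtype=float)
    X, names = build_design(data, spec)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if keep.sum() == 0:
        raise ValueError("no rows with a non-missing dependent value")
    groups = data["participant"].to_numpy()[keep]
    if np.unique(groups).size < 2:
        raise ValueError(
            "at least 2 participants are required (random effect undefined)"
        )
    Xk, yk = X[keep], y[keep]
    exog_re = Xk if spec.random == "slopes" else np.ones((keep.sum(), 1))
    k = len(names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(yk, Xk, groups=groups, exog_re=exog_re)
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=500)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            try:
                res = model.fit(reml=True, method="powell", maxiter=500)
                converged = False
            except Exception:
                nan = np.full(k, np.nan)
                return FitResult(names, nan, nan.copy(), nan.copy(),
                                 nan.copy(), False, int(keep.sum()))
        est = np.asarray(res.fe_params, dtype=float)
        se = np.asarray(res.bse_fe, dtype=float)
    # degenerate noise-free fit: residual variance 0 makes the Wald SE
    # undefined; the effect is then exact (z -> inf, p -> 0)
    scale = float(getattr(res, "scale", np.nan))
    degenerate = (np.isfinite(scale)
                  and scale <= 1e-12 * max(float(np.var(yk)), 1e-12))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    if degenerate:
        # exact fit: the effect is recovered without residual error
        converged = True
        with np.errstate(invalid="ignore"):
            z = np.where(est == 0, 0.0, np.sign(est) * np.inf)
        se = np.where(np.isfinite(se), se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    return FitResult(names, est, se, z, p, converged, int(keep.sum()))


# ---------------------------------------------------------------------------
# predetermined-window test


@dataclass
class WindowResult(FitResult):
    window: TimeWindow | None = None
    sample_range: tuple = (0, 0)
    n_dropped: int = 0

    def summary(self) -> str:
        head = (f"Predetermined-window test, window "
                f"[{self.window.start_ms:g}, {self.window.end_ms:g}) ms "
                f"(samples [{self.sample_range[0]}, {self.sample_range[1]})); "
                f"{self.n_dropped} trial(s) dropped\n")
        return head + super().summary()


class WindowModel:
    """Single mixed-effects test on mean pupil size over a time window."""

    def __init__(self, table: TrialTable, spec: ModelSpec, window: TimeWindow):
        self.table = table
        self.spec = spec
        self.window = window

    def fit(self) -> WindowResult:
        col = self.table.series[self.spec.dependent]
        meta = self.table.series_meta[self.spec.dependent]
        s, e = window_to_samples(meta.rate_hz, meta.t0_ms, self.window,
                                 col.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            y = np.nanmean(col[:, s:e], axis=1)
        res = fit_lmm(self.table.scalars, y, self.spec)
        return WindowResult(res.names, res.estimates, res.se, res.z, res.p,
                            res.converged, res.nobs, res.method,
                            window=self.window, sample_range=(s, e),
                            n_dropped=self.table.n_trials - res.nobs)


def window_test(table: TrialTable, window: TimeWindow,
                spec: ModelSpec) -> WindowResult:
    return WindowModel(table, spec, window).fit()


# ---------------------------------------------------------------------------
# per-sample tests and clusters


@dataclass
class PerSampleResult:
    names: list
    z: np.ndarray  # (n_terms, n_samples)
    p: np.ndarray

    def for_term(self, term: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.names.index(term)
        return self.z[i], self.p[i]


def persample_tests(table: TrialTable, spec: ModelSpec,
                    engine: str = "gls",
                    sample_range: tuple | None = None,
                    rows: np.ndarray | None = None) -> PerSampleResult:
    """One mixed-model fit per sample of the dependent series column.

    ``engine="gls"`` uses the fast random-intercept solver (vectorised when
    the column has no missing data); ``engine="lmm"`` runs a full
    statsmodels fit per sample. Samples where the fit fails yield NaN.
    """
    col = table.series[spec.dependent]
    scalars = table.scalars
    if rows is not None:
        col = col[rows]
        scalars = scalars.iloc[rows].reset_index(drop=True)
    n_samples = col.shape[1]
    s0, s1 = sample_range if sample_range is not None else (0, n_samples)
    X, names = build_design(scalars, spec)
    k = len(names)
    z = np.full((k, n_samples), np.nan)
    p = np.full((k, n_samples), np.nan)
    groups = scalars["participant"].to_numpy()
    block = col[:, s0:s1]
    if engine == "gls" and not np.isnan(block).any():
        gls = RandomInterceptGLS(X, groups)
        out = gls.fit_many(block)
        z[:, s0:s1] = out["z"]
        p[:, s0:s1] = out["p"]
        return PerSampleResult(names, z, p)
    if engine not in ("gls", "lmm"):
        raise ValueError("engine must be 'gls' or 'lmm'")
    for s in range(s0, s1):
        y = col[:, s]
        keep = np.isfinite(y)
        if keep.sum() < X.shape[1] + 2 or np.unique(groups[keep]).size < 2:
            continue
        try:
            if engine == "gls":
                gls = RandomInterceptGLS(X[keep], groups[keep])
                out = gls.fit_one(y[keep])
                z[:, s], p[:, s] = out["z"], out["p"]
            else:
                res = fit_lmm(scalars, y, spec)
                z[:, s], p[:, s] = res.z, res.p
        except Exception:
            continue
    return PerSampleResult(names, z, p)


@dataclass(frozen=True)
class Cluster:
    start: int  # first sample (inclusive)
    end: int    # past-the-end sample
    size: int


def find_clusters(p: np.ndarray, z: np.ndarray, alpha: float) -> list[Cluster]:
    """Maximal runs of contiguous samples with p < alpha and constant z sign."""
    p = np.asarray(p, dtype=float)
    z = np.asarray(z, dtype=float)
    if p.shape != z.shape:
        raise ValueError("p and z must have the same length")
    with np.errstate(invalid="ignore"):
        sig = (p < alpha) & np.isfinite(z)
    clusters: list[Cluster] = []
    i = 0
    n = p.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        sign = np.sign(z[i])
        j = i
        while j < n and sig[j] and np.sign(z[j]) == sign:
            j += 1
        clusters.append(Cluster(i, j, j - i))
        i = j
    return clusters


@dataclass
class ClusterPermResult:
    """Observed clusters and their permutation p values."""

    effect: str
    z: np.ndarray
    p: np.ndarray
    clusters: list
    cluster_p: list
    null_max_sizes: np.ndarray
    n_permutations: int
    seed: int | None
    alpha: float

    @property
    def p_value(self) -> float:
        """Smallest cluster p value; 1 when no cluster was observed."""
        return min(self.cluster_p) if self.cluster_p else 1.0

    def summary(self) -> str:
        lines = [
            f"Cluster-based permutation test for {self.effect!r} "
            f"({self.n_permutations} permutations, alpha {self.alpha:g}, "
            f"seed {self.seed})"
        ]
        if not self.clusters:
            lines.append("no cluster of significant samples observed (p = 1)")
        for cl, pv in zip(self.clusters, self.cluster_p):
            lines.append(
                f"cluster samples [{cl.start}, {cl.end}): size {cl.size}, "
                f"p = {pv:.4g}"
            )
        return "\n".join(lines)


class ClusterPermutationModel:
    """Cluster-based permutation test with within-participant label shuffles.

    The observed per-sample z/p arrays come from the per-sample engine; each
    permutation shuffles the primary effect's values across trials within
    participant, re-runs the per-sample tests and records the maximum
    cluster size. Per-cluster p uses the add-one rule
    ``(1 + #{null max >= observed size}) / (1 + n_permutations)`` and can
    therefore never drop below ``1 / (n_permutations + 1)``.
    """

    def __init__(self, table: TrialTable, spec: ModelSpec,
                 effect: str | None = None, n_permutations: int = 1000,
                 seed: int | None = None, window: TimeWindow | None = None,
                 engine: str = "gls"):
        if n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        self.table = table
        self.spec = spec
        self.effect = effect or spec.fixed[0]
        if ":" in self.effect:
            raise ValueError(
                f"effect {self.effect!r} is an interaction and cannot be "
                "shuffled on a trial basis; designate a plain column"
            )
        if self.effect not in table.scalars.columns:
            raise ValueError(f"effect column {self.effect!r} not found")
        self.n_permutations = n_permutations
        self.seed = seed
        self.window = window
        self.engine = engine

    def fit(self) -> ClusterPermResult:
        table, spec, effect = self.table, self.spec, self.effect
        meta = table.series_meta[spec.dependent]
        n_samples = table.series[spec.dependent].shape[1]
        srange = None
        if self.window is not None:
            srange = window_to_samples(meta.rate_hz, meta.t0_ms, self.window,
                                       n_samples)
        observed = persample_tests(table, spec, engine=self.engine,
                                   sample_range=srange)
        z, p = observed.for_term(effect)
        clusters = find_clusters(p, z, spec.alpha)

        rng = np.random.default_rng(self.seed)
        scalars = table.scalars
        part = scalars["participant"].to_numpy()
        # permute positions within participant; reuse across derived terms
        part_slices = [np.flatnonzero(part == g) for g in table.participants]
        perm_scalars = scalars.copy()
        null_max = np.zeros(self.n_permutations, dtype=int)
        base = scalars[effect].to_numpy()
        for it in range(self.n_permutations):
            shuffled = base.copy()
            for sl in part_slices:
                shuffled[sl] = base[sl][rng.permutation(sl.size)]
            perm_scalars[effect] = shuffled
            perm_table = TrialTable(perm_scalars,
                                    history=list(table.history))
            perm_table.series = table.series
            perm_table.series_meta = table.series_meta
            res = persample_tests(perm_table, spec, engine=self.engine,
                                  sample_range=srange)
            pz, pp = res.for_term(effect)
            found = find_clusters(pp, pz, spec.alpha)
            null_max[it] = max((c.size for c in found), default=0)
        cluster_p = [
            (1 + int(np.sum(null_max >= c.size))) / (1 + self.n_permutations)
            for c in clusters
        ]
        return ClusterPermResult(effect, z, p, clusters, cluster_p, null_max,
                                 self.n_permutations, self.seed, spec.alpha)


def cluster_permutation_test(table: TrialTable, spec: ModelSpec,
                             effect: str | None = None,
                             n_permutations: int = 1000,
                             seed: int | None = None,
                             window: TimeWindow | None = None,
                             engine: str = "gls") -> ClusterPermResult:
    return ClusterPermutationModel(table, spec, effect, n_permutations, seed,
                                   window, engine).fit()


# ---------------------------------------------------------------------------
# cross-validation test


def interleaved_split(n_rows: int, n_folds: int = 4) -> np.ndarray:
    """Deterministic interleaved fold assignment: row ``i`` is in the test
    set of fold ``i mod n_folds``; the folds' test sets partition the rows
    and each fold trains on the remaining ``(n_folds - 1) / n_folds`` of the
    data. Splitting ignores how conditions are distributed across rows."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_rows < n_folds:
        raise ValueError("need at least as many rows as folds")
    return np.arange(n_rows) % n_folds


@dataclass
class EffectCV:
    """Cross-validation record for one effect."""

    chosen_samples: list       # tested sample index per fold
    result: FitResult          # final model on the assembled values
    n_dropped: int             # trials missing at their tested sample


@dataclass
class CVTestResult:
    """Result of the k-fold cross-validation test (deterministic)."""

    effects: dict              # term -> EffectCV
    folds: np.ndarray
    n_folds: int
    alpha: float

    def summary(self) -> str:
        lines = [f"{self.n_folds}-fold interleaved cross-validation test"]
        for term, eff in self.effects.items():
            r = eff.result[term]
            lines.append(
                f"{term}: z = {r['z']:.2f}, p = {r['p']:.4g} "
                f"(tested at samples {sorted(set(eff.chosen_samples))}; "
                f"{eff.n_dropped} trial(s) dropped)"
            )
        return "\n".join(lines)


class CrossValidationModel:
    """Four-fold cross-validation test for time-series mixed models.

    For every fold, per-sample random-intercept models on the training rows
    localize the sample with the highest |z| for the focal effect (ties
    break toward the lowest index); the fold's held-out trials contribute
    their value at that sample. A final mixed model with the spec's full
    random structure is fitted to the assembled per-trial values, so the
    dependent variable mixes sample indices across trials. The procedure is
    repeated per main effect and interaction, and contains no randomness.
    """

    def __init__(self, table: TrialTable, spec: ModelSpec, n_folds: int = 4,
                 window: TimeWindow | None = None):
        self.table = table
        self.spec = spec
        self.n_folds = n_folds
        self.window = window

    def fit(self) -> CVTestResult:
        table, spec = self.table, self.spec
        col = table.series[spec.dependent]
        meta = table.series_meta[spec.dependent]
        n_rows, n_samples = col.shape
        folds = interleaved_split(n_rows, self.n_folds)
        srange = (0, n_samples)
        if self.window is not None:
            srange = window_to_samples(meta.rate_hz, meta.t0_ms, self.window,
                                       n_samples)
        effects = {}
        for term in spec.fixed:
            y_final = np.full(n_rows, np.nan)
            chosen = []
            for k in range(self.n_folds):
                train = np.flatnonzero(folds != k)
                self._check_trainable(train, term)
                loc_spec = ModelSpec(spec.dependent, list(spec.fixed),
                                     dict(spec.coding), "intercept",
                                     spec.alpha)
                res = persample_tests(table, loc_spec, engine="gls",
                                      sample_range=srange, rows=train)
                z, _ = res.for_term(term)
                absz = np.abs(z)
                if not np.isfinite(absz[srange[0]:srange[1]]).any():
                    raise ValueError(
                        f"no sample could be localized for {term!r} in fold {k}"
                    )
                absz = np.where(np.isfinite(absz), absz, -np.inf)
                best = int(np.argmax(absz))  # first max -> lowest index tie-break
                chosen.append(best)
                test = np.flatnonzero(folds == k)
                y_final[test] = col[test, best]
            n_dropped = int(np.sum(np.isnan(y_final)))
            final = fit_lmm(table.scalars, y_final, spec)
            effects[term] = EffectCV(chosen, final, n_dropped)
        return CVTestResult(effects, folds, self.n_folds, spec.alpha)

    def _check_trainable(self, train: np.ndarray, term: str) -> None:
        scalars = self.table.scalars.iloc[train]
        if scalars["participant"].nunique() < 2:
            raise ValueError(
                "a fold's training set has fewer than 2 participants"
            )
        for col in term.split(":"):
            if scalars[col].nunique() < 2:
                raise ValueError(
                    f"a fold's training set has no variation in {col!r}"
                )


def crossval_test(table: TrialTable, spec: ModelSpec, n_folds: int = 4,
                  window: TimeWindow | None = None) -> CVTestResult:
    return CrossValidationModel(table, spec, n_folds, window).fit()
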