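"""Spatial and temporal noise statistics for abundance measurements.

Quantifies cell-to-cell variability within rows of cells at the same
anterior-posterior position (spatial noise, expressed as a percentage of
the fitted gradient magnitude), temporal fluctuation strength of repeated
single-cell measurements (coefficient of variation), the dominant
fluctuation period via moving-window autocorrelation, and group
comparisons of variability (Levene's test and a one-way ANOVA of
coefficients of variation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from ranoise.gradient_fit import FitResult, GradientProfile, fit_gradient

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalTrace",
    "AutocorrResult",
    "NoiseSummary",
    "VarianceComparison",
    "spatial_noise",
    "temporal_cv",
    "movwin_autocorr",
    "dominant_period",
    "levene_cv_comparison",
    "mean_centered_expression",
]


@dataclass(frozen=True)
class TemporalTrace:
    """Uniformly sampled single-cell abundance time series.

    The default experimental cadence is one frame every 12 s.
    """

    t: np.ndarray
    value: np.ndarray
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("t and value must be equal-length 1-D arrays, >= 2 points")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling interval must be constant")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class NoiseSummary:
    """Per-group noise summary: CV, mean, and deviations from the mean."""

    label: str
    cv: float
    mean: float
    deviations: np.ndarray

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass(frozen=True)
class AutocorrResult:
    """Per-lag moving-window autocorrelation with significance calls."""

    lags: np.ndarray
    corr: np.ndarray
    p: np.ndarray
    significant_lags: tuple
    period: float | None
    dt: float
    window: int
    alpha: float


# --------------------------------------------------------------------------
# spatial noise
# --------------------------------------------------------------------------

def _best_fit(
    profile: GradientProfile, model: str, candidates: Sequence[str]
) -> FitResult:
    if model != "auto":
        return fit_gradient(profile, model)
    best: FitResult | None = None
    for name in candidates:
        try:
            fit = fit_gradient(profile, name)
        except ValueError:
            continue
        if best is None or fit.adj_r2 > best.adj_r2:
            best = fit
    if best is None:
        raise ValueError("no candidate gradient model could be fit")
    return best


def spatial_noise(
    rows: Sequence[GradientProfile],
    model: str = "auto",
    candidates: Sequence[str] = ("linear", "exponential", "quadratic"),
) -> float:
    """Within-row variability as a percentage of the gradient magnitude.

    For each row the residuals from that row's best-fit gradient curve
    are computed; the statistic is the maximum over rows of the residual
    range (max - min) divided by the amplitude of the globally fitted
    gradient (max - min of the pooled best-fit curve over the common
    position range), times 100.

    Raises
    ------
    ValueError
        If fewer than 2 rows, a row has < 5 points, the rows share no
        position range, or the fitted gradient amplitude is zero.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    for r in rows:
        if len(r) < 5:
            raise ValueError("each row needs at least 5 points")
    lo = max(r.position.min() for r in rows)
    hi = min(r.position.max() for r in rows)
    if hi <= lo:
        raise ValueError("rows do not span a common position range")

    pooled_pos = np.concatenate([r.position for r in rows])
    pooled_ab = np.concatenate([r.abundance for r in rows])
    order = np.argsort(pooled_pos, kind="stable")
    # pooled profile may contain duplicate positions across rows; jitter-free
    # OLS does not require strict monotonicity, so bypass the row validator
    pooled = GradientProfile.__new__(GradientProfile)
    object.__setattr__(pooled, "position", pooled_pos[order])
    object.__setattr__(pooled, "abundance", pooled_ab[order])
    object.__setattr__(pooled, "row_id", -1)
    object.__setattr__(pooled, "embryo_id", "pooled")
    global_fit = _best_fit(pooled, model, candidates)
    grid = np.linspace(lo, hi, 512)
    curve = global_fit.predict(grid)
    amplitude = float(curve.max() - curve.min())
    if amplitude <= 1e-12:
        raise ValueError("fitted gradient amplitude is zero; noise percentage undefined")

    worst = 0.0
    for r in rows:
        fit = _best_fit(r, model, candidates)
        resid = r.abundance - fit.predict(r.position)
        worst = max(worst, float(resid.max() - resid.min()))
    return 100.0 * worst / amplitude


# --------------------------------------------------------------------------
# temporal noise
# --------------------------------------------------------------------------

def temporal_cv(trace: TemporalTrace) -> NoiseSummary:
    """Coefficient of variation (sample std / mean) of a temporal trace."""
    if len(trace) < 2:
        raise ValueError("need at least 2 time points")
    mean = float(trace.value.mean())
    if mean <= 0:
        raise ValueError("trace mean must be positive for a CV")
    std = float(trace.value.std(ddof=1))
    return NoiseSummary(
        label=trace.cell_id or trace.condition,
        cv=std / mean,
        mean=mean,
        deviations=trace.value - mean,
    )


def _windowed_autocorr(
    values: np.ndarray, window: int, step: int, max_lag: int, detrend: bool
) -> np.ndarray:
    """Sample autocorrelation per (window, lag); shape (n_windows, max_lag+1)."""
    wins = sliding_window_view(values, window)[::step].astype(float)
    if detrend:
        x = np.arange(window) - (window - 1) / 2.0
        slope = (wins * x).sum(axis=1) / (x * x).sum()
        wins = wins - wins.mean(axis=1, keepdims=True) - slope[:, None] * x
    else:
        wins = wins - wins.mean(axis=1, keepdims=True)
    denom = (wins * wins).sum(axis=1)
    if (denom <= 0).any():
        raise ValueError("constant window encountered; autocorrelation undefined")
    out = np.empty((wins.shape[0], max_lag + 1))
    out[:, 0] = 1.0
    for k in range(1, max_lag + 1):
        out[:, k] = (wins[:, :-k] * wins[:, k:]).sum(axis=1) / denom
    return out


def _recurrent_lobe(mean_corr: np.ndarray) -> np.ndarray:
    """Lags of the first positive lobe after the autocorrelation first dips.

    The short-lag positive run contiguous with lag 0 reflects smoothness,
    not periodicity; a periodic signal reappears as a second positive lobe
    near its period.
    """
    pos = mean_corr > 0
    k = 1
    n = mean_corr.size - 1
    while k <= n and pos[k]:  # skip the leading smoothness lobe
        k += 1
    while k <= n and not pos[k]:  # skip the trough
        k += 1
    start = k
    while k <= n and pos[k]:
        k += 1
    return np.arange(start, k)


def movwin_autocorr(
    trace: TemporalTrace,
    window: int = 30,
    max_lag: int = 20,
    alpha: float = 0.05,
    step: int = 1,
    detrend: bool = True,
    method: str = "ttest",
    n_perm: int = 1000,
    seed: int | None = 0,
) -> AutocorrResult:
    """Moving-window autocorrelation with per-lag significance.

    The trace is cut into overlapping windows (linearly detrended by
    default), the sample autocorrelation is computed per window and lag,
    and the across-window mean correlation is tested against zero per lag.
    With ``method='ttest'`` a t-test is used whose sample size is the
    effective number of non-overlapping windows (overlap correction);
    ``method='permutation'`` instead compares against ``n_perm`` seeded
    trace shuffles.  ``significant_lags`` is the set of lags in the first
    recurrent positive lobe of the mean autocorrelation whose mean
    correlation is significantly positive; the associated period is their
    mean lag times the sampling interval.
    """
    if window < max_lag + 2:
        raise ValueError("window must be at least max_lag + 2")
    if len(trace) < window:
        raise ValueError("trace shorter than one window")
    corrs = _windowed_autocorr(trace.value, window, step, max_lag, detrend)
    n_windows = corrs.shape[0]
    mean_corr = corrs.mean(axis=0)
    lags = np.arange(max_lag + 1)

    p = np.ones(max_lag + 1)
    if method == "ttest":
        n_eff = max(3, int(round(n_windows * step / window)))
        sd = corrs.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = mean_corr / (sd / np.sqrt(n_eff))
        p[1:] = 2.0 * stats.t.sf(np.abs(tstat[1:]), df=n_eff - 1)
        p[0] = 0.0
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        exceed = np.zeros(max_lag + 1)
        v = trace.value.copy()
        for _ in range(n_perm):
            rng.shuffle(v)
            pm = _windowed_autocorr(v, window, step, max_lag, detrend).mean(axis=0)
            exceed += np.abs(pm) >= np.abs(mean_corr)
        p = (exceed + 1.0) / (n_perm + 1.0)
        p[0] = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")

    lobe = _recurrent_lobe(mean_corr)
    sig = tuple(
        int(k) for k in lobe if mean_corr[k] > 0 and p[k] < alpha
    )
    period = dominant_period(sig, trace.dt)
    return AutocorrResult(
        lags=lags,
        corr=mean_corr,
        p=p,
        significant_lags=sig,
        period=period,
        dt=trace.dt,
        window=window,
        alpha=alpha,
    )


def dominant_period(significant_lags, dt: float) -> float | None:
    """Dominant fluctuation period: mean significant lag times dt (seconds).

    An empty lag set yields None (no detectable periodicity), not an
    error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lags = np.asarray(sorted(significant_lags), dtype=float)
    if lags.size == 0:
        return None
    return float(lags.mean() * dt)


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComparison:
    """Levene test on raw values plus one-way ANOVA on per-cell CVs."""

    levene_stat: float
    levene_p: float
    anova_f: float | None = None
    anova_p: float | None = None
    warnings: tuple = ()


def levene_cv_comparison(
    groups: Sequence[np.ndarray],
    cv_groups: Sequence[Sequence[float]] | None = None,
) -> VarianceComparison:
    """Compare variability between groups.

    ``groups`` are raw per-group value samples compared with Levene's
    test (mean-centered variant).  Optionally, ``cv_groups`` supplies
    per-cell coefficients of variation per group, compared by one-way
    ANOVA.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 3:
            raise ValueError("each group needs at least 3 points")
    lev_stat, lev_p = stats.levene(*arrays, center="mean")
    warns = []
    anova_f = anova_p = None
    if cv_groups is not None:
        cvs = [np.asarray(c, dtype=float) for c in cv_groups]
        if any(c.size >= 2 and c.std(ddof=1) <= 1e-12 * max(1.0, abs(c.mean())) for c in cvs):
            warns.append("a group has zero variance in its CVs")
        anova_f, anova_p = stats.f_oneway(*cvs)
        anova_f, anova_p = float(anova_f), float(anova_p)
    return VarianceComparison(
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        anova_f=anova_f,
        anova_p=anova_p,
        warnings=tuple(warns),
    )


def mean_centered_expression(
    cells: pd.DataFrame,
    value_col: str = "total",
    control: str = "WT",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-center per-cell expression within each embryo and region.

    Each cell's value has its own embryo-by-region mean subtracted,
    removing embryo-to-embryo heterogeneity in absolute expression so
    that cell-to-cell variance can be compared across conditions.
    Embryo-region groups contributing a single cell are excluded (logged).

    Returns the centered cell table and a per-condition summary with the
    variance of centered values and a Levene test against the control
    condition.
    """
    required = {"embryo_id", "region_id", "condition", value_col}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table lacks columns: {sorted(missing)}")
    df = cells.copy()
    sizes = df.groupby(["embryo_id", "region_id"])[value_col].transform("size")
    singletons = int((sizes < 2).sum())
    if singletons:
        logger.info("excluding %d singleton embryo-region cells", singletons)
    df = df[sizes >= 2].copy()
    df["centered"] = df[value_col] - df.groupby(["embryo_id", "region_id"])[
        value_col
    ].transform("mean")

    ctrl = df.loc[df["condition"] == control, "centered"].to_numpy()
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        vals = grp["centered"].to_numpy()
        row = {
            "condition": cond,
            "n_cells": vals.size,
            "variance": float(np.var(vals, ddof=1)) if vals.size > 1 else np.nan,
        }
        if cond != control and ctrl.size >= 3 and vals.size >= 3:
            stat, p = stats.levene(ctrl, vals, center="mean")
            row["levene_stat_vs_control"] = float(stat)
            row["levene_p_vs_control"] = float(p)
        rows.append(row)
    return df, pd.DataFrame(rows)
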