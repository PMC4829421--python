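"""Gradient-shape regression for abundance-vs-position profiles.

Fits linear, exponential, quadratic, and quadratic-without-linear-term
models to 1-D relative-abundance profiles along the anterior-posterior
axis by ordinary least squares, reports per-coefficient t-tests, adjusted
R^2 and overall F-tests, and decides whether a gradient is present and
whether the candidate shapes are statistically distinguishable.  Over the
shallow dynamic range of the measured RA gradient the exponential is fit
on the log scale (log-abundance regressed on position), where it is again
an OLS problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GradientProfile",
    "FitResult",
    "ComparisonReport",
    "MODEL_NAMES",
    "fit_gradient",
    "compare_fits",
    "split_fit",
    "read_profiles",
    "write_fit_table",
]

MODEL_NAMES = ("linear", "exponential", "quadratic", "quadratic2")


@dataclass(frozen=True)
class GradientProfile:
    """1-D abundance-vs-position profile for one row of cells.

    Positions are in micrometres along the A-P axis (increasing
    posteriorly); abundance is the 1-d_RA statistic in [0, 1].
    """

    position: np.ndarray
    abundance: np.ndarray
    row_id: int = 0
    embryo_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        ab = np.asarray(self.abundance, dtype=float)
        if pos.shape != ab.shape or pos.ndim != 1:
            raise ValueError("position and abundance must be equal-length 1-D arrays")
        if pos.size >= 2 and not (np.diff(pos) > 0).all():
            raise ValueError("positions must be strictly increasing within a row")
        if ab.size and (ab.min() < -1e-9 or ab.max() > 1 + 1e-9):
            raise ValueError("abundance values must lie in [0, 1]")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "abundance", ab)

    def __len__(self) -> int:
        return self.position.size

    def restrict(self, lo: float, hi: float) -> "GradientProfile":
        keep = (self.position >= lo) & (self.position <= hi)
        return GradientProfile(
            self.position[keep], self.abundance[keep], self.row_id, self.embryo_id
        )


@dataclass(frozen=True)
class FitResult:
    """OLS fit of one gradient-shape model.

    ``coefficients`` maps coefficient name to (estimate, standard error);
    ``coef_p`` holds the two-sided t-test p-value per coefficient.  For
    the exponential model the fit is performed on log-abundance and the
    amplitude is back-transformed (``a`` = exp(intercept)); ``adj_r2`` and
    ``f_p`` then refer to the log-scale regression.
    """

    model_name: str
    coefficients: Mapping[str, tuple]
    coef_p: Mapping[str, float]
    adj_r2: float
    f_p: float
    r2: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = {k: v[0] for k, v in self.coefficients.items()}
        if self.model_name == "linear":
            return c["a"] + c["b"] * x
        if self.model_name == "quadratic":
            return c["a"] + c["b"] * x + c["c"] * x**2
        if self.model_name == "quadratic2":
            return c["a"] + c["c"] * x**2
        if self.model_name == "exponential":
            return c["a"] * np.exp(c["b"] * x)
        raise ValueError(self.model_name)


def _design(x: np.ndarray, model_name: str) -> tuple[np.ndarray, list]:
    if model_name in ("linear", "exponential"):
        return np.column_stack([np.ones_like(x), x]), ["a", "b"]
    if model_name == "quadratic":
        return np.column_stack([np.ones_like(x), x, x**2]), ["a", "b", "c"]
    if model_name == "quadratic2":
        return np.column_stack([np.ones_like(x), x**2]), ["a", "c"]
    raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")


def fit_gradient(profile: GradientProfile, model_name: str) -> FitResult:
    """Fit one gradient-shape model to a profile by OLS.

    Raises
    ------
    ValueError
        If fewer than 4 points are supplied, or if the exponential model
        is requested with non-positive abundances (the offending
        positions are named).
    """
    if len(profile) < 4:
        raise ValueError("need at least 4 points to fit a gradient model")
    x = profile.position
    y = profile.abundance
    if model_name == "exponential":
        bad = x[y <= 0]
        if bad.size:
            raise ValueError(
                "exponential fit requires positive abundances; offending "
                f"positions (um): {np.array2string(bad, precision=3)}"
            )
        y = np.log(y)
    X, names = _design(x, model_name)
    res = sm.OLS(y, X).fit()

    coefficients = {}
    coef_p = {}
    for i, name in enumerate(names):
        est, se, p = res.params[i], res.bse[i], res.pvalues[i]
        if model_name == "exponential" and name == "a":
            # back-transform the log-scale intercept; delta-method s.e.
            est, se = np.exp(est), np.exp(est) * se
        coefficients[name] = (float(est), float(se))
        coef_p[name] = float(p)
    return FitResult(
        model_name=model_name,
        coefficients=coefficients,
        coef_p=coef_p,
        adj_r2=float(res.rsquared_adj),
        f_p=float(res.f_pvalue),
        r2=float(res.rsquared),
        n=len(profile),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """All four model fits plus verdicts on gradient presence and shape.

    ``gradient_present`` is True iff the linear slope is significantly
    positive (t-test p < alpha); ``indistinguishable`` is True iff the
    maximal pairwise adjusted-R^2 difference among the successfully
    fitted models is below ``delta_r2_threshold``.
    """

    fits: Mapping[str, FitResult]
    gradient_present: bool
    indistinguishable: bool
    delta_r2_threshold: float
    alpha: float
    errors: Mapping[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            row = {"model": name, "adj_r2": fit.adj_r2, "f_p": fit.f_p, "n": fit.n}
            for cname, (est, se) in fit.coefficients.items():
                row[cname] = est
                row[f"{cname}_se"] = se
                row[f"{cname}_p"] = fit.coef_p[cname]
            rows.append(row)
        return pd.DataFrame(rows)


def compare_fits(
    profile: GradientProfile,
    delta_r2_threshold: float = 0.02,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Fit all four shape models and report gradient/shape verdicts."""
    if len(profile) < 6:
        raise ValueError("need at least 6 points to compare gradient models")
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for name in MODEL_NAMES:
        try:
            fits[name] = fit_gradient(profile, name)
        except ValueError as exc:  # e.g. exponential with zero abundances
            errors[name] = str(exc)
    linear = fits["linear"]
    slope, _ = linear.coefficients["b"]
    gradient_present = bool(linear.coef_p["b"] < alpha and slope > 0)
    adj = [f.adj_r2 for f in fits.values()]
    indistinguishable = bool(max(adj) - min(adj) < delta_r2_threshold)
    return ComparisonReport(
        fits=fits,
        gradient_present=gradient_present,
        indistinguishable=indistinguishable,
        delta_r2_threshold=delta_r2_threshold,
        alpha=alpha,
        errors=errors,
    )


def split_fit(
    profile: GradientProfile,
    x_split: float = 310.0,
    delta_r2_threshold: float = 0.02,
    alpha: float = 0.05,
) -> dict:
    """Compare fits independently on the two sides of a split position.

    The anterior side holds points with x < x_split and the posterior
    side x > x_split; each side must retain at least 6 points.
    """
    sides = {
        "anterior": profile.position < x_split,
        "posterior": profile.position > x_split,
    }
    out = {}
    for side, keep in sides.items():
        if keep.sum() < 6:
            raise ValueError(
                f"{side} side of x = {x_split:g} has only {int(keep.sum())} points "
                "(need >= 6)"
            )
        sub = GradientProfile(
            profile.position[keep], profile.abundance[keep],
            profile.row_id, profile.embryo_id,
        )
        out[side] = compare_fits(sub, delta_r2_threshold, alpha)
    return out


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_profiles(path) -> list:
    """Read (embryo_id, row_id, position_um, abundance) CSV into profiles."""
    df = pd.read_csv(path)
    profiles = []
    for (embryo, row), grp in df.groupby(["embryo_id", "row_id"], sort=True):
        grp = grp.sort_values("position_um")
        profiles.append(
            GradientProfile(
                grp["position_um"].to_numpy(),
                grp["abundance"].to_numpy(),
                row_id=int(row),
                embryo_id=str(embryo),
            )
        )
    return profiles


def write_fit_table(path, report: ComparisonReport) -> None:
    report.table().to_csv(path, index=False)
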