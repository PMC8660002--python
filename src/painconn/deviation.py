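"""Adjusted pain-group predictions versus the adjusted control mean.

For an edge retained by the elimination ladder, the pain-group model
predicts covariate-adjusted connectivity along a grid of duration values
(and intensity levels when the interaction survives).  The control-group
reference is the intercept of ``z ~ covariates`` fitted in the pain-free
group with covariates centred at the pooled sample means, i.e. the
covariate-adjusted control average.  At every grid point the two are
compared with an independent-samples statistic

    t = (yhat_pain - mu_control) / sqrt(SE_yhat^2 + SE_mu^2)

with Welch–Satterthwaite degrees of freedom by default (the two fits use
disjoint subjects, so independence is exact).  The significance threshold
defaults to the FDR q-value the edge attained in the pain-group regression,
and maximal significant grid runs are reported as intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ModelError
from .glm import (
    CONTROL_COVARIATES,
    TERM_INTER,
    TERM_WPINT,
    TERM_X,
    EdgeModelResult,
    OLSFit,
    fit_ols,
)
from .simulate import CODING_COLUMNS

__all__ = [
    "ControlSummary",
    "DeviationProfile",
    "covariate_reference",
    "control_adjusted_mean",
    "duration_grid",
    "deviation_profile",
    "extract_intervals",
]


@dataclass
class ControlSummary:
    """Covariate-adjusted control-group mean connectivity at one edge."""

    mean: float
    se: float
    df: int
    n: int


@dataclass
class DeviationProfile:
    """Grid of adjusted pain predictions contrasted with the control mean."""

    edge: tuple[int, int]
    coding: str
    alpha: float
    table: pd.DataFrame           # grid, intensity, yhat, se, mu/se control, t, df, p, significant
    intervals: list[tuple[float, float, float]]   # (grid lo, grid hi, intensity)


def covariate_reference(
    subjects: pd.DataFrame,
    covariates: Sequence[str],
    shared: Sequence[str] = CONTROL_COVARIATES,
) -> dict[str, float]:
    """Reference covariate profile for adjusted predictions.

    Covariates present in both group models are centred at the pooled
    (pain + control) sample mean; covariates only measured in the pain group
    take pain-group reference values — the modal category for binary
    variables, the mean otherwise.
    """
    pain = subjects[subjects["group"] == "pain"]
    ref: dict[str, float] = {}
    for c in covariates:
        col = subjects[c] if c in shared else pain[c]
        vals = col.dropna().to_numpy(float)
        if vals.size == 0:
            raise ConfigurationError(f"covariate {c!r} has no observed values")
        uniq = np.unique(vals)
        if c not in shared and uniq.size <= 2:
            ref[c] = float(stats.mode(vals, keepdims=False).mode)
        else:
            ref[c] = float(vals.mean())
    return ref


def control_adjusted_mean(
    z_values: np.ndarray,
    control_subjects: pd.DataFrame,
    covariates: Sequence[str] = CONTROL_COVARIATES,
    centers: Mapping[str, float] | None = None,
) -> ControlSummary:
    """Adjusted control mean: the intercept of z ~ centred covariates.

    ``centers`` (typically pooled pain+control sample means, matching the
    reference profile used for the pain-side prediction) are subtracted from
    each covariate so the OLS intercept estimates the adjusted group
    average; its standard error comes from the intercept's sampling
    variance.  When ``centers`` is omitted, covariates are centred at the
    control sample's own means.
    """
    y = np.asarray(z_values, dtype=float)
    sub = control_subjects
    keep = sub[list(covariates)].notna().all(axis=1).to_numpy() & ~np.isnan(y)
    sub, y = sub.loc[keep], y[keep]
    if len(sub) <= len(covariates) + 1:
        raise ModelError(
            f"control n = {len(sub)} does not exceed the "
            f"{len(covariates) + 1} model parameters"
        )
    cols = [np.ones(len(sub))]
    names = ["const"]
    for c in covariates:
        v = sub[c].to_numpy(float)
        if np.ptp(v) == 0.0:
            # constant in this sample: its adjustment is inestimable and the
            # column would be collinear with the intercept; drop it
            continue
        center = float(centers[c]) if centers and c in centers else v.mean()
        cols.append(v - center)
        names.append(c)
    fit = fit_ols(np.column_stack(cols), y, names)
    return ControlSummary(
        mean=fit["const"], se=float(fit.se[0]), df=fit.df_resid, n=fit.n
    )


def duration_grid(
    subjects: pd.DataFrame, coding: str, n_grid: int = 200
) -> np.ndarray:
    """Evenly spaced grid over the observed pain-group duration coding.

    Spacing is uniform in coded units, hence log-spaced in years under the
    log coding; the dichotomous coding yields its two levels.
    """
    xcol = CODING_COLUMNS[coding]
    x = subjects.loc[subjects["group"] == "pain", xcol].dropna().to_numpy(float)
    if x.size == 0:
        raise ConfigurationError(f"no observed {xcol} values in the pain group")
    if coding == "dichotomous":
        return np.array([0.0, 1.0])
    return np.linspace(x.min(), x.max(), n_grid)


def _predict(fit: OLSFit, x: float, w: float, reference: Mapping[str, float]):
    row = np.zeros(len(fit.names))
    for k, name in enumerate(fit.names):
        if name == "const":
            row[k] = 1.0
        elif name == TERM_X:
            row[k] = x
        elif name == TERM_WPINT:
            row[k] = w
        elif name == TERM_INTER:
            row[k] = w * x
        else:
            row[k] = float(reference[name])
    yhat = float(row @ fit.params)
    var = float(row @ fit.cov_params @ row)
    return yhat, np.sqrt(max(var, 0.0))


def extract_intervals(
    grid: np.ndarray, significant: np.ndarray
) -> list[tuple[float, float]]:
    """Maximal runs of significant grid points as closed intervals."""
    sig = np.asarray(significant, dtype=bool)
    out: list[tuple[float, float]] = []
    start = None
    for k, s in enumerate(sig):
        if s and start is None:
            start = k
        elif not s and start is not None:
            out.append((float(grid[start]), float(grid[k - 1])))
            start = None
    if start is not None:
        out.append((float(grid[start]), float(grid[len(sig) - 1])))
    return out


def deviation_profile(
    pain_result: EdgeModelResult,
    control: ControlSummary,
    subjects: pd.DataFrame,
    alpha: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 200,
    intensity_levels: Sequence[float] | None = None,
    reference: Mapping[str, float] | None = None,
    df_method: str = "welch",
) -> DeviationProfile:
    """Contrast the adjusted pain prediction with the adjusted control mean.

    ``alpha`` defaults to the smallest q-value of the edge's terminal-step
    terms; ``grid`` defaults to the observed duration range (coded units);
    ``intensity_levels`` defaults to the pain-group mean intensity when the
    model contains WPINT.  ``df_method`` selects Welch–Satterthwaite
    (default), pooled, or normal-approximation degrees of freedom.
    """
    if df_method not in ("welch", "pooled", "normal"):
        raise ConfigurationError(f"unknown df_method {df_method!r}")
    fit = pain_result.fit
    coding = pain_result.coding
    if alpha is None:
        qs = [q for q in pain_result.qvalues.values() if np.isfinite(q)]
        if not qs:
            raise ConfigurationError("no stored q-values; pass alpha explicitly")
        alpha = min(qs)
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")

    if grid is None:
        grid = duration_grid(subjects, coding, n_grid)
    grid = np.asarray(grid, dtype=float)
    if coding == "log" and not np.all(np.isfinite(grid)):
        raise ConfigurationError("log-coding grid contains non-finite values")

    needs_w = TERM_WPINT in fit.names or TERM_INTER in fit.names
    if needs_w:
        if intensity_levels is None:
            wp = subjects.loc[subjects["group"] == "pain", "wpint"].dropna()
            intensity_levels = [float(wp.mean())]
    else:
        intensity_levels = [np.nan]

    covs = [n for n in fit.names if n not in ("const", TERM_X, TERM_WPINT, TERM_INTER)]
    if reference is None:
        reference = covariate_reference(subjects, covs)

    rows = []
    intervals: list[tuple[float, float, float]] = []
    for w in intensity_levels:
        yh = np.empty(grid.size)
        se = np.empty(grid.size)
        for k, x in enumerate(grid):
            yh[k], se[k] = _predict(fit, float(x), 0.0 if np.isnan(w) else float(w), reference)
        v1, v2 = se**2, control.se**2
        denom = np.sqrt(v1 + v2)
        diff = yh - control.mean
        # degenerate variances: an exact match is a null result (t=0, p=1),
        # a nonzero difference with zero uncertainty is infinitely significant
        tol = 1e-12 * (1.0 + abs(control.mean))
        degenerate = denom <= tol
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, denom))
        t = np.where(degenerate & (np.abs(diff) > tol), np.sign(diff) * np.inf, t)
        if df_method == "welch":
            with np.errstate(divide="ignore", invalid="ignore"):
                df = np.where(
                    v1 + v2 > 0,
                    (v1 + v2) ** 2
                    / (v1**2 / fit.df_resid + v2**2 / max(control.df, 1)),
                    1.0,
                )
            p = 2.0 * stats.t.sf(np.abs(t), df)
        elif df_method == "pooled":
            df = np.full(grid.size, fit.df_resid + control.df, dtype=float)
            p = 2.0 * stats.t.sf(np.abs(t), df)
        else:
            df = np.full(grid.size, np.inf)
            p = 2.0 * stats.norm.sf(np.abs(t))
        p = np.where(degenerate & ~np.isinf(t), 1.0, p)
        sig = p < alpha
        for lo, hi in extract_intervals(grid, sig):
            intervals.append((lo, hi, float(w)))
        rows.append(
            pd.DataFrame(
                {
                    "grid": grid, "intensity": w, "yhat": yh, "se": se,
                    "mu_control": control.mean, "se_control": control.se,
                    "t": t, "df": df, "p": p, "significant": sig,
                }
            )
        )
    return DeviationProfile(
        edge=pain_result.edge, coding=coding, alpha=float(alpha),
        table=pd.concat(rows, ignore_index=True), intervals=intervals,
    )
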