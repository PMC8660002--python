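"""Edge-wise moderated regression with a stepwise FDR elimination ladder.

For every ROI-to-ROI connection, the pain-group Fisher-z connectivity is
modelled as::

    z ~ WPINT * X + covariates        (Wilkinson notation)

where X is the worst-pain duration under one of three codings (log10 years,
raw years, or an indicator for > 5 years) and WPINT the worst-pain
intensity.  Terms are removed by stepwise backward elimination — interaction
first, then the WPINT main effect, always keeping X — where a term survives
a step only if its p-value, Benjamini–Hochberg corrected across all
connections still present at that step, is at or below the elimination
level (default 0.05).  Effect sizes are Cohen's f-squared from nested-model
R-squared comparisons.

Fits are ordinary least squares, computed in closed form simultaneously
across all edges (the design is shared; only the outcome differs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ModelError
from .simulate import CODING_COLUMNS

__all__ = [
    "OLSFit",
    "EdgeModelResult",
    "LadderResult",
    "DEFAULT_COVARIATES",
    "CONTROL_COVARIATES",
    "bh_qvalues",
    "cohens_f2",
    "build_design",
    "fit_ols",
    "fit_edge_model",
    "elimination_ladder",
    "screen_covariates",
]

DEFAULT_COVARIATES: tuple[str, ...] = ("sex", "age", "pain_med", "moca", "scanner_pain")
CONTROL_COVARIATES: tuple[str, ...] = ("sex", "age", "moca")

TERM_X = "X"
TERM_WPINT = "WPINT"
TERM_INTER = "WPINT:X"
_ALL_TERMS = (TERM_X, TERM_WPINT, TERM_INTER)


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with enforced monotonicity.

    ``q[i]`` is the smallest FDR level at which test i is rejected by the
    step-up procedure; tied p-values receive identical q-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cohens_f2(fit_full: "OLSFit", fit_reduced: "OLSFit") -> float:
    """Cohen's f² = (R²_full − R²_reduced)/(1 − R²_full), floored at 0."""
    if fit_full.n != fit_reduced.n:
        raise ModelError("nested fits must use the same subjects")
    if fit_full.df_resid > fit_reduced.df_resid:
        raise ModelError("reduced model must be nested in the full model")
    r2f, r2r = fit_full.r_squared, fit_reduced.r_squared
    if r2f >= 1.0 - 1e-14:
        raise ModelError("R² of the full model is 1; f² undefined")
    return max(0.0, (r2f - r2r) / (1.0 - r2f))


@dataclass
class OLSFit:
    """Closed-form ordinary-least-squares fit of one edge."""

    names: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    n: int
    r_squared: float
    rss: float

    def __getitem__(self, term: str) -> float:
        return float(self.params[self.names.index(term)])

    def term_cov(self, a: str, b: str) -> float:
        return float(self.cov_params[self.names.index(a), self.names.index(b)])

    def p(self, term: str) -> float:
        return float(self.pvalues[self.names.index(term)])


@dataclass
class EdgeModelResult:
    """Terminal-model summary for one edge under one duration coding."""

    edge: tuple[int, int]
    coding: str
    step: int                       # elimination step at which the model froze
    surviving_terms: tuple[str, ...]
    fit: OLSFit
    qvalues: dict[str, float] = field(default_factory=dict)  # terms tested at the terminal step
    f2: dict[str, float] = field(default_factory=dict)

    @property
    def has_interaction(self) -> bool:
        return TERM_INTER in self.surviving_terms


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        involved = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ModelError(f"design is rank deficient; collinear columns: {involved}")


def build_design(
    subjects: pd.DataFrame,
    coding: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    terms: Sequence[str] = _ALL_TERMS,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Regression design for the pain-group model under one duration coding.

    Returns ``(matrix, column names, row index into subjects)`` after
    listwise deletion of rows missing any required column.  Columns are
    intercept, X, then (if requested) WPINT and WPINT:X, then covariates,
    entered uncentered.
    """
    if coding not in CODING_COLUMNS:
        raise ConfigurationError(f"unknown duration coding {coding!r}")
    if TERM_X not in terms:
        raise ConfigurationError("the duration term X is always retained")
    xcol = CODING_COLUMNS[coding]
    needed = [xcol] + list(covariates)
    if TERM_WPINT in terms or TERM_INTER in terms:
        needed.append("wpint")
    missing = [c for c in needed if c not in subjects.columns]
    if missing:
        raise ConfigurationError(f"subject table lacks columns {missing}")
    rows = subjects[needed].notna().all(axis=1).to_numpy()
    sub = subjects.loc[rows]

    cols: list[np.ndarray] = [np.ones(len(sub))]
    names = ["const", TERM_X]
    cols.append(sub[xcol].to_numpy(float))
    if TERM_WPINT in terms:
        names.append(TERM_WPINT)
        cols.append(sub["wpint"].to_numpy(float))
    if TERM_INTER in terms:
        names.append(TERM_INTER)
        cols.append(sub["wpint"].to_numpy(float) * sub[xcol].to_numpy(float))
    for c in covariates:
        names.append(c)
        cols.append(sub[c].to_numpy(float))
    X = np.column_stack(cols)
    return X, names, np.flatnonzero(rows)


def fit_ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> OLSFit:
    """Closed-form OLS with per-term two-tailed t-test p-values."""
    n, k = X.shape
    if n <= k:
        raise ModelError(f"n = {n} subjects <= {k} parameters; fit underdetermined")
    _check_rank(X, names)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    cov = sigma2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OLSFit(
        names=list(names), params=beta, cov_params=cov, se=se, tvalues=t,
        pvalues=p, df_resid=df, n=n, r_squared=r2, rss=rss,
    )


def fit_edge_model(
    z_values: np.ndarray,
    subjects: pd.DataFrame,
    coding: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    terms: Sequence[str] = _ALL_TERMS,
) -> OLSFit:
    """Fit one edge's moderated regression on the pain group.

    ``z_values`` is the per-subject Fisher-z connectivity at the edge,
    aligned with ``subjects`` rows; listwise deletion drops subjects with
    missing covariates before fitting.
    """
    X, names, rows = build_design(subjects, coding, covariates, terms)
    y = np.asarray(z_values, dtype=float)[rows]
    if np.any(np.isnan(y)):
        keep = ~np.isnan(y)
        X, y = X[keep], y[keep]
    return fit_ols(X, y, names)


def _mass_ols(X: np.ndarray, Y: np.ndarray, names: list[str] | None = None):
    """OLS of many outcomes on a shared design; returns per-edge summaries."""
    n, k = X.shape
    if n <= k:
        raise ModelError(f"n = {n} subjects <= {k} parameters; fit underdetermined")
    if names is not None:
        _check_rank(X, names)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                      # k x E
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    return beta, se, t, p, df, r2, sigma2, xtx_inv


@dataclass
class LadderResult:
    """Outcome of the stepwise elimination across all edges."""

    coding: str
    alpha_elim: float
    table: pd.DataFrame                 # long format, one row per edge x term
    edge_results: dict[int, EdgeModelResult]  # keyed by canonical edge index

    def edges_at_step(self, step: int) -> list[int]:
        return [e for e, r in self.edge_results.items() if r.step == step]


def elimination_ladder(
    Z: np.ndarray,
    subjects: pd.DataFrame,
    coding: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha_elim: float = 0.05,
    edges: Sequence[tuple[int, int]] | None = None,
) -> LadderResult:
    """Run the backward-elimination ladder over every edge.

    ``Z`` is subjects x edges (pain group, canonical edge order).  Step 1
    fits the full model everywhere and BH-corrects the interaction p-values
    across all edges: survivors freeze the full model.  Step 2 refits the
    remainder without the interaction and BH-corrects the X and WPINT
    p-values separately across those edges: edges whose WPINT survives
    freeze {X, WPINT}.  Step 3 refits the rest with X only (X is never
    eliminated) and BH-corrects its p-value.  Each edge's report carries the
    q-values of the terms tested at its terminal step, plus Cohen's f² for
    the duration term (and the interaction where retained).
    """
    if not 0 < alpha_elim <= 1:
        raise ConfigurationError(f"alpha_elim must lie in (0, 1], got {alpha_elim}")
    Z = np.asarray(Z, dtype=float)
    n_edges = Z.shape[1]
    if edges is None:
        edges = [(0, e) for e in range(n_edges)]
    valid = ~np.any(np.isnan(Z), axis=0)

    X_full, names_full, rows = build_design(subjects, coding, covariates, _ALL_TERMS)
    X_noint, names_noint, _ = build_design(
        subjects, coding, covariates, (TERM_X, TERM_WPINT)
    )
    X_xonly, names_xonly, _ = build_design(subjects, coding, covariates, (TERM_X,))
    Y = Z[rows]

    def idx(names, term):
        return names.index(term)

    results: dict[int, EdgeModelResult] = {}

    def _freeze(e, step, terms, names, fitted, col, q):
        beta, se, t, p, df, r2, sigma2, xtx_inv = fitted
        fit = OLSFit(
            names=list(names), params=beta[:, col].copy(),
            cov_params=sigma2[col] * xtx_inv, se=se[:, col].copy(),
            tvalues=t[:, col].copy(), pvalues=p[:, col].copy(), df_resid=df,
            n=Y.shape[0], r_squared=float(r2[col]), rss=float(sigma2[col] * df),
        )
        results[e] = EdgeModelResult(
            edge=tuple(edges[e]), coding=coding, step=step,
            surviving_terms=terms, fit=fit, qvalues=q,
        )

    active = np.flatnonzero(valid)
    step2 = active
    if active.size:
        fit1 = _mass_ols(X_full, Y[:, active], names_full)
        p1 = fit1[3]
        q_inter = bh_qvalues(p1[idx(names_full, TERM_INTER), :])
        keep1 = q_inter <= alpha_elim
        for a in np.flatnonzero(keep1):
            _freeze(active[a], 1, _ALL_TERMS, names_full, fit1, a,
                    {TERM_INTER: float(q_inter[a])})
        step2 = active[~keep1]

    step3 = step2
    if step2.size:
        fit2 = _mass_ols(X_noint, Y[:, step2], names_noint)
        p2 = fit2[3]
        q_x2 = bh_qvalues(p2[idx(names_noint, TERM_X), :])
        q_w2 = bh_qvalues(p2[idx(names_noint, TERM_WPINT), :])
        keep2 = q_w2 <= alpha_elim
        for a in np.flatnonzero(keep2):
            _freeze(step2[a], 2, (TERM_X, TERM_WPINT), names_noint, fit2, a,
                    {TERM_X: float(q_x2[a]), TERM_WPINT: float(q_w2[a])})
        step3 = step2[~keep2]

    if step3.size:
        fit3 = _mass_ols(X_xonly, Y[:, step3], names_xonly)
        p3 = fit3[3]
        q_x3 = bh_qvalues(p3[idx(names_xonly, TERM_X), :])
        for a in range(step3.size):
            _freeze(step3[a], 3, (TERM_X,), names_xonly, fit3, a,
                    {TERM_X: float(q_x3[a])})

    # effect sizes: f2 of X (terminal model vs same minus X); f2 of the
    # interaction (full vs no-interaction) for step-1 survivors
    _add_effect_sizes(results, Y, subjects, coding, covariates)

    rows_out = []
    for e in sorted(results):
        r = results[e]
        for term in r.surviving_terms:
            rows_out.append(
                {
                    "edge_index": e,
                    "roi_i": r.edge[0],
                    "roi_j": r.edge[1],
                    "coding": coding,
                    "step": r.step,
                    "surviving_model": "+".join(r.surviving_terms),
                    "term": term,
                    "beta": r.fit[term],
                    "se": r.fit.se[r.fit.names.index(term)],
                    "t": r.fit.tvalues[r.fit.names.index(term)],
                    "p": r.fit.p(term),
                    "q": r.qvalues.get(term, np.nan),
                    "f2": r.f2.get(term, np.nan),
                }
            )
    table = pd.DataFrame(rows_out)
    return LadderResult(coding=coding, alpha_elim=alpha_elim, table=table,
                        edge_results=results)


def _add_effect_sizes(results, Y, subjects, coding, covariates):
    """Cohen's f² via vectorised nested-model R² differences."""
    def _r2(terms, cols):
        X, _, _ = build_design(subjects, coding, covariates, terms)
        if cols.size == 0:
            return np.zeros(0)
        *_, r2, _, _ = _mass_ols(X, Y[:, cols])
        return r2

    by_step: dict[int, np.ndarray] = {}
    for step in (1, 2, 3):
        by_step[step] = np.array(
            [e for e, r in results.items() if r.step == step], dtype=int
        )

    # step 1: f2 for interaction (full vs no-interaction) and for X
    e1 = by_step[1]
    if e1.size:
        r2_full = np.array([results[e].fit.r_squared for e in e1])
        r2_noint = _r2((TERM_X, TERM_WPINT), e1)
        # dropping X from the full model (keep WPINT and the product term)
        r2_nox = _r2_custom(subjects, coding, covariates, Y, e1, drop_x=True,
                            with_inter=True)
        for k, e in enumerate(e1):
            denom = 1.0 - r2_full[k]
            if denom > 1e-14:
                results[e].f2[TERM_INTER] = max(0.0, (r2_full[k] - r2_noint[k]) / denom)
                results[e].f2[TERM_X] = max(0.0, (r2_full[k] - r2_nox[k]) / denom)
    e2 = by_step[2]
    if e2.size:
        r2_m = np.array([results[e].fit.r_squared for e in e2])
        r2_nox = _r2_custom(subjects, coding, covariates, Y, e2, drop_x=True,
                            with_inter=False, with_wpint=True)
        r2_now = _r2((TERM_X,), e2)
        for k, e in enumerate(e2):
            denom = 1.0 - r2_m[k]
            if denom > 1e-14:
                results[e].f2[TERM_X] = max(0.0, (r2_m[k] - r2_nox[k]) / denom)
                results[e].f2[TERM_WPINT] = max(0.0, (r2_m[k] - r2_now[k]) / denom)
    e3 = by_step[3]
    if e3.size:
        r2_m = np.array([results[e].fit.r_squared for e in e3])
        r2_cov = _r2_custom(subjects, coding, covariates, Y, e3, drop_x=True,
                            with_inter=False, with_wpint=False)
        for k, e in enumerate(e3):
            denom = 1.0 - r2_m[k]
            if denom > 1e-14:
                results[e].f2[TERM_X] = max(0.0, (r2_m[k] - r2_cov[k]) / denom)


def _r2_custom(subjects, coding, covariates, Y, cols, *, drop_x,
               with_inter, with_wpint=True):
    """R² of reduced designs not expressible through `build_design` terms."""
    xcol = CODING_COLUMNS[coding]
    needed = [xcol] + list(covariates) + (["wpint"] if (with_inter or with_wpint) else [])
    rows = subjects[[c for c in needed if c in subjects.columns]].notna().all(axis=1)
    sub = subjects.loc[rows.to_numpy()]
    parts = [np.ones(len(sub))]
    if not drop_x:
        parts.append(sub[xcol].to_numpy(float))
    if with_wpint:
        parts.append(sub["wpint"].to_numpy(float))
    if with_inter:
        parts.append(sub["wpint"].to_numpy(float) * sub[xcol].to_numpy(float))
    for c in covariates:
        parts.append(sub[c].to_numpy(float))
    X = np.column_stack(parts)
    *_, r2, _, _ = _mass_ols(X, Y[:, cols])
    return r2


def screen_covariates(
    subjects: pd.DataFrame,
    extra_measures: Sequence[str] = (),
    targets: Sequence[str] = ("log_wpdur", "wpdur", "wpdur5", "wpint"),
) -> pd.DataFrame:
    """Pairwise Pearson screen of candidate covariates vs pain history.

    Correlates every measure (default covariate set plus any extra columns)
    with each pain-history variable using pairwise deletion, and BH-corrects
    across every test in the table.  Cells with fewer than 4 complete pairs
    are reported with NaN statistics.
    """
    measures = [c for c in DEFAULT_COVARIATES if c in subjects.columns]
    measures += [c for c in extra_measures if c not in measures]
    pain = subjects[subjects["group"] == "pain"] if "group" in subjects else subjects
    rows = []
    for m in measures:
        for t in targets:
            x = pain[m].to_numpy(float)
            y = pain[t].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < 4 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append({"measure": m, "target": t, "n": n,
                             "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"measure": m, "target": t, "n": n, "r": r, "p": p})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_qvalues(out.loc[ok, "p"].to_numpy())
    return out
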