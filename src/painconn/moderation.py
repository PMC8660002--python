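"""Simple slopes and Johnson–Neyman regions for surviving interactions.

In a moderated regression ``z ~ b_p*P + b_i*P*W + ...`` the simple slope of
the predictor P at moderator value W is ``b_p + b_i*W`` with sampling
variance ``v_pp + W^2 v_ii + 2 W v_pi`` taken from the coefficient
covariance.  The Johnson–Neyman region is the set of W at which that slope
is significant at level alpha: the sign-consistent solution set of the
quadratic inequality

    (b_i^2 - t^2 v_ii) W^2 + 2 (b_p b_i - t^2 v_pi) W + (b_p^2 - t^2 v_pp) > 0

with t the critical t-value at the model's residual degrees of freedom.
Either intensity or the duration coding may play the moderator role; the
level defaults to the BH q-value the edge's interaction attained, mirroring
the restriction of the moderation analysis by its own FDR outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ModelError
from .glm import TERM_INTER, TERM_WPINT, TERM_X, EdgeModelResult, OLSFit

__all__ = ["JNRegion", "simple_slope", "jn_region", "severity_split"]

SEVERITY_CUT = 5.0


@dataclass
class JNRegion:
    """Moderator values at which the predictor's simple slope is significant."""

    edge: tuple[int, int]
    predictor: str
    moderator: str
    alpha: float
    t_crit: float
    boundaries: tuple[float, ...]            # 0, 1 or 2 real roots, ascending
    intervals: tuple[tuple[float, float], ...]    # open intervals, +-inf allowed
    intervals_clipped: tuple[tuple[float, float], ...]
    moderator_range: tuple[float, float] | None

    def contains(self, w: float | np.ndarray) -> np.ndarray:
        """Vectorised membership test against the unclipped region."""
        w = np.asarray(w, dtype=float)
        inside = np.zeros(w.shape, dtype=bool)
        for lo, hi in self.intervals:
            inside |= (w > lo) & (w < hi)
        return inside

    def describe(self) -> str:
        if not self.intervals:
            return "empty"
        parts = []
        for lo, hi in self.intervals:
            if lo == -math.inf and hi == math.inf:
                parts.append("all W")
            elif lo == -math.inf:
                parts.append(f"W < {hi:.4g}")
            elif hi == math.inf:
                parts.append(f"W > {lo:.4g}")
            else:
                parts.append(f"{lo:.4g} < W < {hi:.4g}")
        return " or ".join(parts)


def _slope_terms(fit: OLSFit, predictor: str):
    if TERM_INTER not in fit.names:
        raise ModelError(
            "interaction term absent from the fit; use the main effect directly"
        )
    b_p = fit[predictor]
    b_i = fit[TERM_INTER]
    v_pp = fit.term_cov(predictor, predictor)
    v_ii = fit.term_cov(TERM_INTER, TERM_INTER)
    v_pi = fit.term_cov(predictor, TERM_INTER)
    return b_p, b_i, v_pp, v_ii, v_pi


def simple_slope(
    fit: OLSFit, predictor: str, moderator_value: float
) -> tuple[float, float, float, float]:
    """Slope, SE, t and two-tailed p of the predictor at one moderator value."""
    b_p, b_i, v_pp, v_ii, v_pi = _slope_terms(fit, predictor)
    w = float(moderator_value)
    slope = b_p + b_i * w
    var = v_pp + w * w * v_ii + 2.0 * w * v_pi
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        t = slope / se
    else:
        t = 0.0 if slope == 0 else math.copysign(math.inf, slope)
    p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
    return slope, se, t, p


def jn_region(
    result: EdgeModelResult,
    predictor: str | None = None,
    moderator: str | None = None,
    alpha: float | None = None,
    moderator_range: tuple[float, float] | None = None,
) -> JNRegion:
    """Solve the Johnson–Neyman inequality for one surviving-interaction edge.

    ``predictor``/``moderator`` default to the duration term moderated by
    WPINT.  ``alpha`` defaults to the edge's interaction q-value.  Returns
    both the unclipped region and its intersection with
    ``moderator_range`` (the observed moderator span) when given.
    """
    if not result.has_interaction:
        raise ModelError("edge did not retain the interaction; no JN region")
    predictor = predictor or TERM_X
    moderator = moderator or (TERM_WPINT if predictor == TERM_X else TERM_X)
    if alpha is None:
        alpha = result.qvalues.get(TERM_INTER)
        if alpha is None:
            raise ConfigurationError("no interaction q-value stored; pass alpha")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")

    fit = result.fit
    b_p, b_i, v_pp, v_ii, v_pi = _slope_terms(fit, predictor)
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid))
    t2 = t_crit * t_crit
    a = b_i * b_i - t2 * v_ii
    b = 2.0 * (b_p * b_i - t2 * v_pi)
    c = b_p * b_p - t2 * v_pp

    scale = max(abs(a), abs(b), abs(c), 1.0)
    if abs(a) <= 1e-14 * scale:
        # degenerate quadratic: at most one linear boundary
        if abs(b) <= 1e-14 * scale:
            intervals = ((-math.inf, math.inf),) if c > 0 else ()
            roots: tuple[float, ...] = ()
        else:
            w0 = -c / b
            roots = (w0,)
            intervals = ((w0, math.inf),) if b > 0 else ((-math.inf, w0),)
    else:
        disc = b * b - 4.0 * a * c
        if disc <= 0:
            roots = ()
            intervals = ((-math.inf, math.inf),) if a > 0 else ()
        else:
            sq = math.sqrt(disc)
            r1, r2 = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
            roots = (r1, r2)
            if a > 0:
                intervals = ((-math.inf, r1), (r2, math.inf))
            else:
                intervals = ((r1, r2),)

    clipped: tuple[tuple[float, float], ...] = intervals
    if moderator_range is not None:
        lo0, hi0 = moderator_range
        clipped = tuple(
            (max(lo, lo0), min(hi, hi0))
            for lo, hi in intervals
            if max(lo, lo0) < min(hi, hi0)
        )
    return JNRegion(
        edge=result.edge, predictor=predictor, moderator=moderator,
        alpha=float(alpha), t_crit=t_crit, boundaries=roots,
        intervals=intervals, intervals_clipped=clipped,
        moderator_range=moderator_range,
    )


def severity_split(
    wpint: np.ndarray, cut: float = SEVERITY_CUT
) -> np.ndarray:
    """Label subjects less/more severe by the intensity cut (<= cut is less).

    The default cut of 5 follows rounding the JN boundary down to the
    nearest reported rating value.
    """
    w = np.asarray(wpint, dtype=float)
    out = np.where(w > cut, "more_severe", "less_severe").astype(object)
    out[np.isnan(w)] = None
    return out
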