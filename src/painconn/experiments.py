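"""Monte-Carlo validation experiments for the pipeline's inference stages.

Two experiment families, both driven entirely by the synthetic-cohort
generator:

* **Null calibration** — all-null cohorts (no planted effect anywhere) are
  pushed through connectivity and the elimination ladder to measure the
  empirical false-discovery behaviour of the interaction step and the
  null significant-fraction of the pain-vs-control deviation profile.
* **Parameter recovery** — a known effect is planted at one edge and the
  edge-wise moderated regression is refit on each replicate, recording
  whether each planted coefficient falls inside its 95% confidence
  interval.

Replicate cohorts use reduced ROI counts (the regression operates per edge,
so edge count affects only the multiplicity correction, which is exercised
at 20 ROIs / 190 edges) and the study's native 300 frames and group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .denoise import edge_list, weighted_connectivity
from .deviation import control_adjusted_mean, covariate_reference, deviation_profile
from .glm import TERM_INTER, TERM_WPINT, TERM_X, elimination_ladder, fit_edge_model
from .simulate import CohortSpec, PlantedEffect, generate_cohort, generate_timeseries

__all__ = [
    "NullCalibration",
    "RecoveryResult",
    "default_planted_effect",
    "cohort_edge_z",
    "null_calibration",
    "parameter_recovery",
]

#: Planted coefficients per coding, sized so the implied Fisher-z stays well
#: inside (-1, 1) across the full duration x intensity support while giving
#: each term a detectable but not overwhelming share of variance.
_PLANTED = {
    "log": dict(beta_x=0.10, beta_wpint=0.015, beta_interaction=0.02),
    "linear": dict(beta_x=0.004, beta_wpint=0.015, beta_interaction=0.0008),
    "dichotomous": dict(beta_x=0.15, beta_wpint=0.015, beta_interaction=0.03),
}


def default_planted_effect(coding: str, edge=(0, 1)) -> PlantedEffect:
    """The standard planted effect used by the recovery experiments."""
    return PlantedEffect(edge=edge, coding=coding, baseline_z=0.1, **_PLANTED[coding])


def cohort_edge_z(spec: CohortSpec, effects) -> tuple[np.ndarray, "object"]:
    """Generate one cohort and return (subjects, subjects x edges Fisher z).

    Spike-free motion and uniform censoring weights: these experiments probe
    the inference stages, so the scrubbing path is bypassed.
    """
    subjects = generate_cohort(spec)
    data, _ = generate_timeseries(subjects, effects, spec, spike_prob=0.0)
    Z = np.vstack(
        [
            weighted_connectivity(data[sid].values.to_numpy(float)).edge_vector()
            for sid in subjects["subject_id"]
        ]
    )
    return subjects, Z


@dataclass
class NullCalibration:
    """Aggregate error rates over all-null replicate cohorts."""

    n_reps: int
    n_edges: int
    fdr_interaction: float        # mean of V/max(R,1) for the step-1 BH test
    mc_se_fdr: float
    type1_interaction: float      # mean uncorrected rejection rate at alpha
    deviation_fraction: float     # mean significant grid fraction, null profile
    mc_se_deviation: float
    alpha: float


def null_calibration(
    n_reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    n_rois: int = 20,
    n_frames: int = 300,
    n_grid: int = 100,
) -> NullCalibration:
    """Empirical FDR / type-I behaviour on cohorts with no planted effect."""
    base = CohortSpec(n_rois=n_rois, n_networks=4, n_frames=n_frames)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    fdp, rate, devfrac = [], [], []
    for rep in range(n_reps):
        spec = replace(base, seed=int(seeds[rep]))
        subjects, Z = cohort_edge_z(spec, effects=[])
        pain = subjects[subjects["group"] == "pain"].reset_index(drop=True)
        control = subjects[subjects["group"] == "control"].reset_index(drop=True)
        ladder = elimination_ladder(
            Z[: len(pain)], pain, "log", alpha_elim=alpha,
            edges=edge_list(n_rois),
        )
        n_step1 = len(ladder.edges_at_step(1))
        fdp.append(1.0 if n_step1 > 0 else 0.0)  # all discoveries are false
        # uncorrected interaction test from the full fit on every edge
        full_p = _full_interaction_p(Z[: len(pain)], pain)
        rate.append(float(np.mean(full_p < alpha)))

        res = ladder.edge_results[0]
        centers = covariate_reference(subjects, ("sex", "age", "moca"))
        ctrl = control_adjusted_mean(Z[len(pain):, 0], control, centers=centers)
        prof = deviation_profile(
            res, ctrl, subjects, alpha=alpha, n_grid=n_grid
        )
        devfrac.append(float(prof.table["significant"].mean()))
    fdp = np.asarray(fdp)
    devfrac = np.asarray(devfrac)
    return NullCalibration(
        n_reps=n_reps, n_edges=len(edge_list(n_rois)),
        fdr_interaction=float(fdp.mean()),
        mc_se_fdr=float(fdp.std(ddof=1) / np.sqrt(n_reps)),
        type1_interaction=float(np.mean(rate)),
        deviation_fraction=float(devfrac.mean()),
        mc_se_deviation=float(devfrac.std(ddof=1) / np.sqrt(n_reps)),
        alpha=alpha,
    )


def _full_interaction_p(Z, pain):
    from .glm import _mass_ols, build_design

    X, names, rows = build_design(pain, "log")
    pv = _mass_ols(X, Z[rows], names)[3]
    return pv[names.index(TERM_INTER)]


@dataclass
class RecoveryResult:
    """95% CI coverage of planted coefficients over replicate cohorts."""

    coding: str
    n_reps: int
    coverage: dict[str, float]          # term -> fraction of CIs covering truth
    mean_estimates: dict[str, float]
    truth: dict[str, float]


def parameter_recovery(
    coding: str,
    n_reps: int = 500,
    seed: int = 0,
    n_rois: int = 6,
    n_frames: int = 300,
    level: float = 0.95,
) -> RecoveryResult:
    """CI coverage of the planted (X, WPINT, interaction) coefficients.

    Each replicate draws a fresh cohort with the standard planted effect at
    edge (0, 1), measures connectivity, fits the full moderated regression
    in the pain group and records whether each true coefficient lies inside
    its two-sided confidence interval.
    """
    effect = default_planted_effect(coding)
    truth = {
        TERM_X: effect.beta_x,
        TERM_WPINT: effect.beta_wpint,
        TERM_INTER: effect.beta_interaction,
    }
    base = CohortSpec(n_rois=n_rois, n_networks=2, n_frames=n_frames, n_control=2)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    hits = {t: 0 for t in truth}
    sums = {t: 0.0 for t in truth}
    edge_col = 0  # edge (0, 1) is first in canonical order
    for rep in range(n_reps):
        spec = replace(base, seed=int(seeds[rep]))
        subjects, Z = cohort_edge_z(spec, [effect])
        pain = subjects[subjects["group"] == "pain"]
        fit = fit_edge_model(Z[: len(pain), edge_col], pain, coding)
        tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
        for term, true_b in truth.items():
            k = fit.names.index(term)
            lo = fit.params[k] - tcrit * fit.se[k]
            hi = fit.params[k] + tcrit * fit.se[k]
            hits[term] += int(lo <= true_b <= hi)
            sums[term] += fit.params[k]
    return RecoveryResult(
        coding=coding, n_reps=n_reps,
        coverage={t: hits[t] / n_reps for t in truth},
        mean_estimates={t: sums[t] / n_reps for t in truth},
        truth=truth,
    )
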