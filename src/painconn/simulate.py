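"""Synthetic cohorts for the chronic-pain connectivity pipeline.

Generates complete study cohorts — covariate tables, ROI BOLD time series,
rigid-body motion traces and white-matter/CSF noise-voxel signals — with
known planted edge-level effects, so that every downstream stage (QC,
denoising, edge-wise moderated regression, Johnson–Neyman moderation,
pain-vs-control deviation) can be validated without access to real data.

The emulated study conditions: a pain group of 40 and a pain-free control
group of 21 older adults, 76 functional ROIs grouped into 10 resting-state
networks, 300 frames at TR = 2 s.  Worst-pain duration (WPDUR, years)
follows a truncated log-normal anchored at the reported quartiles
1 / 5 / 14.25 years on [0.25, 56]; worst-pain intensity (WPINT) is a
normal(4.8, 2.0) density discretised onto the 1..10 rating support.

Per-subject BOLD series are drawn from a stationary multivariate AR(1)
process whose lag-0 population correlation matrix is controlled exactly:
unplanted edges take constant within- / between-network correlations, and
each planted edge takes the inverse Fisher transform of that subject's
linear predictor ``baseline_z + beta_x*X + beta_wpint*WPINT +
beta_interaction*X*WPINT`` under the chosen duration coding.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning: one child stream per logical block (covariates, then one per
subject for series / motion / noise voxels), so adding subjects or ROIs
never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import ConfigurationError, GenerationError

__all__ = [
    "DurationDist",
    "IntensityDist",
    "CovariateDists",
    "CohortSpec",
    "PlantedEffect",
    "SubjectData",
    "generate_cohort",
    "generate_timeseries",
    "add_duration_codings",
    "make_roi_map",
]

Coding = Literal["log", "linear", "dichotomous"]

#: Duration coding column used for each approach.
CODING_COLUMNS: dict[str, str] = {
    "log": "log_wpdur",
    "linear": "wpdur",
    "dichotomous": "wpdur5",
}

#: Years above which a pain history counts as "long duration" in the
#: dichotomous coding.
DURATION_SPLIT_YEARS = 5.0

_Q3_NORM = stats.norm.ppf(0.75)  # 0.67449, quartile z-score


@dataclass(frozen=True)
class DurationDist:
    """Truncated log-normal worst-pain duration (years).

    Defaults anchor the median at 5 years and set the log-scale spread by a
    symmetric fit to the 1 / 14.25 year quartiles, truncated to the observed
    0.25–56 year range.
    """

    median: float = 5.0
    sigma_log: float = float(np.log(14.25 / 5.0) / _Q3_NORM)
    lo: float = 0.25
    hi: float = 56.0

    def _frozen(self) -> stats.rv_continuous:
        return stats.lognorm(s=self.sigma_log, scale=self.median)

    def rvs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n durations by inverse-CDF sampling of the truncated law."""
        if not (0 < self.lo < self.hi):
            raise ConfigurationError(
                f"duration_dist: truncation bounds lo={self.lo}, hi={self.hi} invalid"
            )
        if self.sigma_log <= 0:
            raise ConfigurationError("duration_dist.sigma_log must be positive")
        d = self._frozen()
        a, b = d.cdf(self.lo), d.cdf(self.hi)
        return d.ppf(a + (b - a) * rng.uniform(size=n))

    def moments(self) -> tuple[float, float]:
        """Mean and SD of the truncated distribution (numerical quadrature)."""
        from scipy.integrate import quad

        d = self._frozen()
        mass = d.cdf(self.hi) - d.cdf(self.lo)
        m1 = quad(lambda x: x * d.pdf(x), self.lo, self.hi, limit=200)[0] / mass
        m2 = quad(lambda x: x * x * d.pdf(x), self.lo, self.hi, limit=200)[0] / mass
        return m1, float(np.sqrt(m2 - m1 * m1))


@dataclass(frozen=True)
class IntensityDist:
    """Discrete worst-pain intensity on a numerical rating scale.

    The pmf is a normal(mean, sd) density evaluated on the integer support
    and renormalised, emulating a 0–10 rating instrument whose reported
    values concentrate around a mid-scale mean.
    """

    support_lo: int = 1
    support_hi: int = 10
    mean: float = 4.8
    sd: float = 2.0

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.support_lo, self.support_hi + 1)

    def pmf(self) -> np.ndarray:
        if self.sd <= 0:
            raise ConfigurationError("intensity_dist.sd must be positive")
        if self.support_lo > self.support_hi:
            raise ConfigurationError("intensity_dist: empty support")
        w = stats.norm.pdf(self.support, loc=self.mean, scale=self.sd)
        return w / w.sum()

    def rvs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.support, size=n, p=self.pmf()).astype(float)

    def moments(self) -> tuple[float, float]:
        p, k = self.pmf(), self.support
        m1 = float(p @ k)
        return m1, float(np.sqrt(p @ (k - m1) ** 2))


@dataclass(frozen=True)
class CovariateDists:
    """Distributions of the non-pain covariates.

    Age and cognition (MoCA) are truncated normals; sex and medication use
    are Bernoulli; clinical pain at the scanner (0–100) is zero-inflated
    exponential, reflecting that roughly 40% of participants report no pain
    on the table and the rest mostly mild values.
    """

    age_mean: float = 71.0
    age_sd: float = 7.0
    age_lo: float = 61.0
    age_hi: float = 94.0
    female_prop: float = 0.75
    moca_mean: float = 25.0
    moca_sd: float = 2.5
    moca_lo: float = 17.0
    moca_hi: float = 30.0
    pain_med_prob: float = 0.5
    scanner_pain_zero_prob: float = 0.425
    scanner_pain_scale: float = 15.0
    scanner_pain_max: float = 100.0

    def validate(self) -> None:
        for name in ("age_sd", "moca_sd", "scanner_pain_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"covariate_dists.{name} must be positive")
        for name in ("female_prop", "pain_med_prob", "scanner_pain_zero_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"covariate_dists.{name} must lie in [0, 1]")

    def _truncnorm(self, mean, sd, lo, hi, rng, n):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm(a, b, loc=mean, scale=sd).ppf(rng.uniform(size=n))

    def draw(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        self.validate()
        age = self._truncnorm(self.age_mean, self.age_sd, self.age_lo, self.age_hi, rng, n)
        sex = (rng.uniform(size=n) < self.female_prop).astype(int)
        moca = np.round(
            self._truncnorm(self.moca_mean, self.moca_sd, self.moca_lo, self.moca_hi, rng, n)
        )
        med = (rng.uniform(size=n) < self.pain_med_prob).astype(int)
        pain = rng.exponential(self.scanner_pain_scale, size=n)
        pain = np.where(rng.uniform(size=n) < self.scanner_pain_zero_prob, 0.0, pain)
        pain = np.minimum(np.round(pain), self.scanner_pain_max)
        return pd.DataFrame(
            {"sex": sex, "age": age, "moca": moca, "pain_med": med, "scanner_pain": pain}
        )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort."""

    n_pain: int = 40
    n_control: int = 21
    n_rois: int = 76
    n_networks: int = 10
    n_frames: int = 300
    tr: float = 2.0
    duration_dist: DurationDist = field(default_factory=DurationDist)
    intensity_dist: IntensityDist = field(default_factory=IntensityDist)
    covariate_dists: CovariateDists = field(default_factory=CovariateDists)
    seed: int = 0

    def validate(self) -> None:
        limits = {"n_pain": 2, "n_control": 2, "n_rois": 2, "n_frames": 8,
                  "n_networks": 1}
        for name, lo in limits.items():
            if getattr(self, name) < lo:
                raise ConfigurationError(f"{name} must be >= {lo}, got {getattr(self, name)}")
        if self.tr <= 0:
            raise ConfigurationError(f"tr must be positive, got {self.tr}")
        if self.n_networks > self.n_rois:
            raise ConfigurationError("n_networks cannot exceed n_rois")
        self.intensity_dist.pmf()
        self.covariate_dists.validate()

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PlantedEffect:
    """Known edge-level association planted into a synthetic cohort.

    The subject-level Fisher-z connectivity at ``edge`` is::

        z = baseline_z + beta_x*X + beta_wpint*WPINT + beta_interaction*X*WPINT
            + sum_c covariate_betas[c]*value[c]

    where X is the subject's duration value under ``coding``.  Control
    subjects, who carry no pain history, receive the baseline (plus any
    covariate terms).
    """

    edge: tuple[int, int]
    coding: Coding = "log"
    beta_x: float = 0.0
    beta_wpint: float = 0.0
    beta_interaction: float = 0.0
    baseline_z: float = 0.0
    covariate_betas: Mapping[str, float] | None = None

    def validate(self, n_rois: int) -> None:
        i, j = self.edge
        if i == j or not (0 <= i < n_rois and 0 <= j < n_rois):
            raise ConfigurationError(
                f"planted edge {self.edge} invalid for n_rois={n_rois}"
            )
        if self.coding not in CODING_COLUMNS:
            raise ConfigurationError(f"unknown coding {self.coding!r}")

    def linear_predictor(self, row: pd.Series) -> float:
        z = self.baseline_z
        if row["group"] == "pain":
            x = row[CODING_COLUMNS[self.coding]]
            w = row["wpint"]
            z += self.beta_x * x + self.beta_wpint * w + self.beta_interaction * x * w
        if self.covariate_betas:
            for name, b in self.covariate_betas.items():
                z += b * row[name]
        return float(z)


@dataclass
class SubjectData:
    """One subject's simulated acquisitions."""

    subject_id: str
    values: pd.DataFrame          # frames x ROIs, raw scanner units
    motion: pd.DataFrame          # frames x 6 (trans mm, rot radians)
    wm_signals: np.ndarray        # frames x voxels, white-matter noise pool
    csf_signals: np.ndarray       # frames x voxels, CSF noise pool
    target_corr: np.ndarray       # population lag-0 correlation actually embedded


def add_duration_codings(subjects: pd.DataFrame) -> pd.DataFrame:
    """Populate log10 and dichotomous duration codings from raw WPDUR."""
    out = subjects.copy()
    dur = out["wpdur"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_wpdur"] = np.where(dur > 0, np.log10(dur), np.nan)
    out["wpdur5"] = np.where(dur.notna(), (dur > DURATION_SPLIT_YEARS).astype(float), np.nan)
    return out


def make_roi_map(n_rois: int, n_networks: int) -> pd.DataFrame:
    """Assign ROIs to networks in contiguous, near-equal blocks."""
    bounds = np.linspace(0, n_rois, n_networks + 1).round().astype(int)
    labels = [f"ROI{i + 1:03d}" for i in range(n_rois)]
    nets = np.empty(n_rois, dtype=object)
    for k in range(n_networks):
        nets[bounds[k]:bounds[k + 1]] = f"net{k + 1:02d}"
    return pd.DataFrame({"roi": labels, "network": nets})


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the subject covariate table for one cohort.

    Returns one row per subject with group labels, covariates and — for the
    pain group only — WPDUR/WPINT plus all three duration codings.  Control
    rows carry NaN in every pain-history column.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed).spawn(1)[0]))
    n = spec.n_pain + spec.n_control
    cov = spec.covariate_dists.draw(rng, n)
    cov.insert(0, "subject_id", [f"sub{i + 1:03d}" for i in range(n)])
    cov.insert(1, "group", ["pain"] * spec.n_pain + ["control"] * spec.n_control)
    wpdur = np.full(n, np.nan)
    wpint = np.full(n, np.nan)
    wpdur[: spec.n_pain] = spec.duration_dist.rvs(rng, spec.n_pain)
    wpint[: spec.n_pain] = spec.intensity_dist.rvs(rng, spec.n_pain)
    cov["wpdur"] = wpdur
    cov["wpint"] = wpint
    return add_duration_codings(cov)


def _base_correlation(roi_map: pd.DataFrame, r_within: float, r_between: float) -> np.ndarray:
    nets = roi_map["network"].to_numpy()
    same = nets[:, None] == nets[None, :]
    c = np.where(same, r_within, r_between).astype(float)
    np.fill_diagonal(c, 1.0)
    return c


def _nearest_pd(c: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair, rescaled to unit diagonal."""
    w, v = np.linalg.eigh(c)
    if w.min() >= eps:
        return c
    w = np.clip(w, eps, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def _ar1_sample(rng, corr, n_frames, ar_coef, burn_in=50):
    """Stationary AR(1) with lag-0 covariance exactly `corr` (unit variances)."""
    L = np.linalg.cholesky(corr)
    innov = rng.standard_normal((n_frames + burn_in, corr.shape[0]))
    innov = innov @ (L.T * np.sqrt(1.0 - ar_coef**2))
    x = signal.lfilter([1.0], [1.0, -ar_coef], innov, axis=0)
    return x[burn_in:]


def generate_timeseries(
    subjects: pd.DataFrame,
    effects: Sequence[PlantedEffect],
    spec: CohortSpec,
    *,
    ar_coef: float = 0.3,
    r_within: float = 0.3,
    r_between: float = 0.1,
    spike_prob: float = 0.03,
    spike_mm: float = 1.5,
    walk_sd_mm: float = 0.02,
    walk_sd_rad: float = 2e-4,
    n_noise_voxels: int = 50,
    n_noise_components: int = 5,
    contamination: float = 0.0,
    baseline_level: float = 1000.0,
    signal_amplitude: float = 0.01,
) -> tuple[dict[str, SubjectData], pd.DataFrame]:
    """Simulate BOLD series, motion and noise-voxel pools for every subject.

    Each subject's ROI series is a stationary multivariate AR(1) whose
    population lag-0 correlation equals the network-structured base matrix
    with planted edges overridden by the inverse Fisher transform of that
    subject's linear predictor.  Matrices that lose positive definiteness
    are repaired by eigenvalue clipping before sampling.  Motion traces are
    Gaussian random walks with Bernoulli step artifacts sized to exceed the
    scrubbing threshold; WM/CSF pools share ``n_noise_components`` latent
    components plus white noise, with optional contamination by the mean
    ROI signal.

    Returns ``(per-subject data, roi_map)``.
    """
    spec.validate()
    for eff in effects:
        eff.validate(spec.n_rois)
    if not -1.0 < ar_coef < 1.0:
        raise ConfigurationError(f"ar_coef must lie in (-1, 1), got {ar_coef}")
    if baseline_level <= 0:
        raise ConfigurationError("baseline_level must be positive")

    roi_map = make_roi_map(spec.n_rois, spec.n_networks)
    base = _base_correlation(roi_map, r_within, r_between)
    # child 0 is consumed by generate_cohort; one child per subject after it
    children = np.random.SeedSequence(spec.seed).spawn(1 + len(subjects))
    out: dict[str, SubjectData] = {}
    for k, (_, row) in enumerate(subjects.iterrows()):
        rng = np.random.Generator(np.random.PCG64(children[1 + k]))
        corr = base.copy()
        for eff in effects:
            z = eff.linear_predictor(row)
            if not np.isfinite(z):
                raise GenerationError(
                    f"subject {row['subject_id']}: non-finite linear predictor "
                    f"at edge {eff.edge}"
                )
            r = np.tanh(z)
            if not -1.0 < r < 1.0:
                raise GenerationError(
                    f"subject {row['subject_id']}: implied correlation {r} at "
                    f"edge {eff.edge} outside (-1, 1)"
                )
            i, j = eff.edge
            corr[i, j] = corr[j, i] = r
        repaired = _nearest_pd(corr)
        # benign indefiniteness is repaired; a repair that materially moves a
        # planted correlation means the requested effect is geometrically
        # inconsistent with the background structure
        for eff in effects:
            i, j = eff.edge
            if abs(repaired[i, j] - corr[i, j]) > 0.02:
                raise GenerationError(
                    f"subject {row['subject_id']}: planted correlation at edge "
                    f"{eff.edge} ({corr[i, j]:.3f}) is incompatible with the "
                    "background correlation structure (positive-definite "
                    f"repair moved it to {repaired[i, j]:.3f}); weaken the "
                    "effect or the background correlations"
                )
        corr = repaired
        try:
            x = _ar1_sample(rng, corr, spec.n_frames, ar_coef)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - repaired above
            raise GenerationError(
                f"subject {row['subject_id']}: correlation matrix not positive definite"
            ) from exc

        values = baseline_level * (1.0 + signal_amplitude * x)

        motion = np.cumsum(
            rng.normal(0.0, [walk_sd_mm] * 3 + [walk_sd_rad] * 3, size=(spec.n_frames, 6)),
            axis=0,
        )
        spikes = rng.uniform(size=spec.n_frames) < spike_prob
        spikes[0] = False
        for s, frame in enumerate(np.flatnonzero(spikes)):
            motion[frame:, 0] += spike_mm * (1 if s % 2 == 0 else -1)

        global_sig = x.mean(axis=1)

        def _noise_pool(r):
            load = r.normal(size=(n_noise_components, n_noise_voxels))
            latent = r.standard_normal((spec.n_frames, n_noise_components))
            pool = latent @ load + 0.5 * r.standard_normal((spec.n_frames, n_noise_voxels))
            return pool + contamination * global_sig[:, None]

        sid = row["subject_id"]
        out[sid] = SubjectData(
            subject_id=sid,
            values=pd.DataFrame(values, columns=roi_map["roi"].tolist()),
            motion=pd.DataFrame(
                motion, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
            ),
            wm_signals=_noise_pool(rng),
            csf_signals=_noise_pool(rng),
            target_corr=corr,
        )
    return out, roi_map
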