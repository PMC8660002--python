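"""ROI time-series denoising and weighted Fisher-z connectivity.

Implements the single-subject signal path: nuisance design construction
(motion + derivatives, per-frame scrubbing indicators, anatomical CompCor
components from white-matter/CSF voxel pools, and a session-long boxcar
convolved with the canonical haemodynamic response plus its first two
temporal derivatives), percent-signal conversion, GLM residualisation, an
ideal discrete-Fourier band-pass filter, and the weighted Pearson
correlation of every ROI pair, Fisher transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ModelError

__all__ = [
    "NuisanceDesign",
    "ConnectivityMatrix",
    "canonical_hrf",
    "build_nuisance_design",
    "denoise_and_filter",
    "weighted_connectivity",
    "count_edges",
    "edge_list",
]


def count_edges(n_rois: int) -> int:
    """Number of unique undirected ROI pairs, n*(n-1)/2."""
    if n_rois < 2:
        raise ConfigurationError(f"n_rois must be >= 2, got {n_rois}")
    return n_rois * (n_rois - 1) // 2


def edge_list(n_rois: int) -> list[tuple[int, int]]:
    """Canonical edge enumeration: (i, j) with i < j, row-major order."""
    if n_rois < 2:
        raise ConfigurationError(f"n_rois must be >= 2, got {n_rois}")
    return [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]


def canonical_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at TR.

    The conventional parameterisation: gamma response peaking at 6 s minus a
    gamma undershoot peaking at 16 s at one sixth the amplitude, over a 32 s
    kernel, normalised to unit peak.
    """
    from scipy.stats import gamma

    t = np.arange(0, duration + tr / 2, tr)
    h = gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp) - gamma.pdf(
        t, undershoot_delay / undershoot_disp, scale=undershoot_disp
    ) / ratio
    return h / h.max()


@dataclass
class NuisanceDesign:
    """Named blocks of nuisance regressors sharing one frame axis.

    ``matrix`` concatenates the blocks in a fixed order (motion, motion
    derivatives, scrubbing indicators, WM CompCor, CSF CompCor, rest
    regressor + derivatives), dropping all-zero columns and exact
    duplicates.
    """

    n_frames: int
    motion: np.ndarray | None = None          # frames x 6
    motion_deriv: np.ndarray | None = None    # frames x 6
    scrub: np.ndarray | None = None           # frames x n_outliers, one-hot
    compcor_wm: np.ndarray | None = None      # frames x k
    compcor_csf: np.ndarray | None = None     # frames x k
    rest: np.ndarray | None = None            # frames x 3
    column_names: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        blocks, names = [], []
        for name, blk in [
            ("motion", self.motion),
            ("motion_d", self.motion_deriv),
            ("scrub", self.scrub),
            ("wm_pc", self.compcor_wm),
            ("csf_pc", self.compcor_csf),
            ("rest", self.rest),
        ]:
            if blk is None or blk.size == 0:
                continue
            for c in range(blk.shape[1]):
                blocks.append(blk[:, c])
                names.append(f"{name}{c + 1}")
        if not blocks:
            self.column_names = []
            return np.empty((self.n_frames, 0))
        X = np.column_stack(blocks)
        keep = ~np.all(X == 0.0, axis=0)
        X, names = X[:, keep], [n for n, k in zip(names, keep) if k]
        # drop exact duplicate columns, keeping the first occurrence
        seen, keep_idx = set(), []
        for c in range(X.shape[1]):
            key = X[:, c].tobytes()
            if key not in seen:
                seen.add(key)
                keep_idx.append(c)
        self.column_names = [names[c] for c in keep_idx]
        return X[:, keep_idx]


def _first_difference(x: np.ndarray) -> np.ndarray:
    """Backward first difference, zero at frame 0."""
    d = np.zeros_like(x, dtype=float)
    d[1:] = np.diff(x, axis=0)
    return d


def _compcor(tissue: np.ndarray, k: int, name: str) -> np.ndarray:
    """First k principal-component time courses of a centred voxel pool."""
    if tissue.shape[1] < k:
        raise ModelError(
            f"{name} matrix has {tissue.shape[1]} voxels, fewer than the "
            f"{k} requested components"
        )
    centred = tissue - tissue.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if rank < k:
        raise ModelError(
            f"{name} matrix is rank deficient (rank {rank} < {k} components)"
        )
    return u[:, :k] * np.sqrt(tissue.shape[0])


def build_nuisance_design(
    motion: pd.DataFrame | np.ndarray,
    outlier_flags: np.ndarray,
    wm_signals: np.ndarray | None,
    csf_signals: np.ndarray | None,
    tr: float,
    n_compcor: int = 5,
    *,
    precomputed_components: np.ndarray | None = None,
) -> NuisanceDesign:
    """Assemble the per-subject nuisance regressor set.

    Motion derivatives are backward first differences (zero at frame 0);
    each flagged frame contributes a one-hot scrubbing column; CompCor
    components are PCA time courses of the centred tissue voxel pools; the
    rest block is a session-long boxcar convolved with the canonical HRF
    together with its first and second temporal derivatives.  Tissue pools
    may be replaced by ``precomputed_components`` (already-extracted
    component time courses, used verbatim in place of both pools).
    """
    mot = np.asarray(motion, dtype=float)
    n = mot.shape[0]
    if mot.ndim != 2 or mot.shape[1] != 6:
        raise ConfigurationError(
            f"motion table must have 6 columns, got shape {mot.shape}"
        )
    flags = np.asarray(outlier_flags, dtype=bool)
    if flags.shape[0] != n:
        raise ConfigurationError(
            f"outlier flags length {flags.shape[0]} != {n} motion frames"
        )

    scrub = None
    idx = np.flatnonzero(flags)
    if idx.size:
        scrub = np.zeros((n, idx.size))
        scrub[idx, np.arange(idx.size)] = 1.0

    wm_pc = csf_pc = None
    if precomputed_components is not None:
        comp = np.asarray(precomputed_components, dtype=float)
        if comp.shape[0] != n:
            raise ConfigurationError(
                f"precomputed components have {comp.shape[0]} frames, expected {n}"
            )
        wm_pc = comp
    else:
        if wm_signals is not None and n_compcor > 0:
            if np.asarray(wm_signals).shape[0] != n:
                raise ConfigurationError("WM signals frame count mismatch")
            wm_pc = _compcor(np.asarray(wm_signals, float), n_compcor, "white-matter")
        if csf_signals is not None and n_compcor > 0:
            if np.asarray(csf_signals).shape[0] != n:
                raise ConfigurationError("CSF signals frame count mismatch")
            csf_pc = _compcor(np.asarray(csf_signals, float), n_compcor, "CSF")

    hrf = canonical_hrf(tr)
    boxcar = np.ones(n)
    rest0 = np.convolve(boxcar, hrf)[:n]
    rest = np.column_stack(
        [rest0, _first_difference(rest0), _first_difference(_first_difference(rest0))]
    )

    design = NuisanceDesign(
        n_frames=n,
        motion=mot,
        motion_deriv=_first_difference(mot),
        scrub=scrub,
        compcor_wm=wm_pc,
        compcor_csf=csf_pc,
        rest=rest,
    )
    X = design.matrix
    if X.shape[1]:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
        if rank < X.shape[1] + 1:
            raise ModelError(
                "nuisance design is rank deficient after duplicate removal"
            )
    return design


def to_percent_signal(values: np.ndarray) -> np.ndarray:
    """Per-ROI percent-signal conversion and zero-centering.

    Divides each ROI column by its temporal mean (x100) and subtracts the
    resulting mean; raises if any ROI has non-positive baseline.
    """
    mean = values.mean(axis=0)
    if np.any(mean <= 0):
        bad = int(np.argmax(mean <= 0))
        raise ConfigurationError(
            f"ROI column {bad} has non-positive temporal mean ({mean[bad]:.3g}); "
            "percent-signal conversion undefined"
        )
    pct = 100.0 * values / mean
    return pct - pct.mean(axis=0)


def _bandpass_fft(x: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Ideal band-pass: zero every DFT bin with |f| outside [low, high]."""
    n = x.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def denoise_and_filter(
    values: np.ndarray,
    design: NuisanceDesign | None,
    tr: float,
    band: tuple[float, float] = (0.008, 0.09),
    *,
    outlier_flags: np.ndarray | None = None,
    to_percent: bool = True,
    order: str = "regress-then-filter",
) -> tuple[np.ndarray, np.ndarray]:
    """Residualise against the nuisance design and band-pass filter.

    Returns ``(denoised frames x ROIs, censoring weights)``.  Weights are
    binary: 0 at flagged frames, 1 elsewhere.  ``order`` selects whether the
    nuisance GLM runs on the unfiltered series with filtering applied after
    (default), or on series and design filtered jointly ("simultaneous").
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 <= band[0] < band[1] < nyquist):
        raise ConfigurationError(
            f"band {band} must satisfy 0 <= low < high < Nyquist ({nyquist:.4g} Hz)"
        )
    if order not in ("regress-then-filter", "simultaneous"):
        raise ConfigurationError(f"unknown denoising order {order!r}")
    if design is not None and design.n_frames != n:
        raise ConfigurationError(
            f"design has {design.n_frames} frames, series has {n}"
        )

    y = to_percent_signal(values) if to_percent else values - values.mean(axis=0)
    X = design.matrix if design is not None else np.empty((n, 0))
    if X.shape[1]:
        X = X - X.mean(axis=0)

    if order == "regress-then-filter":
        y = _bandpass_fft(_residualize(y, X), tr, band)
    else:
        yf = _bandpass_fft(y, tr, band)
        Xf = _bandpass_fft(X, tr, band) if X.shape[1] else X
        keep = ~np.all(np.abs(Xf) < 1e-12, axis=0) if Xf.shape[1] else np.array([], bool)
        y = _residualize(yf, Xf[:, keep] if Xf.shape[1] else Xf)

    weights = np.ones(n)
    if outlier_flags is not None:
        weights[np.asarray(outlier_flags, dtype=bool)] = 0.0
    return y, weights


@dataclass
class ConnectivityMatrix:
    """Symmetric edge matrices of weighted correlations and Fisher z."""

    r: np.ndarray
    z: np.ndarray
    roi_labels: list[str]
    effective_n: float

    def edge_vector(self) -> np.ndarray:
        """Fisher-z values in canonical (i<j, row-major) edge order."""
        n = self.z.shape[0]
        iu = np.triu_indices(n, k=1)
        return self.z[iu]

    def to_long(self) -> pd.DataFrame:
        n = self.r.shape[0]
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "roi_i": [self.roi_labels[i] for i in iu[0]],
                "roi_j": [self.roi_labels[j] for j in iu[1]],
                "r": self.r[iu],
                "z": self.z[iu],
            }
        )


def weighted_connectivity(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    roi_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Zero-lagged weighted Pearson correlation of all ROI pairs, Fisher z.

    Weighted means and covariances use the per-frame weights (binary
    censoring weights in the default pipeline); correlations are clipped to
    ±(1 − 1e-12) before ``atanh``.  An ROI with zero weighted variance
    yields NaN on all its edges (marked invalid, excluded downstream).
    """
    values = np.asarray(values, dtype=float)
    n_frames, n_rois = values.shape
    w = np.ones(n_frames) if weights is None else np.asarray(weights, dtype=float)
    if w.shape[0] != n_frames:
        raise ConfigurationError("weights length does not match frame count")
    if np.any((w < 0) | (w > 1)):
        raise ConfigurationError("weights must lie in [0, 1]")
    if np.sum(w > 0) < 3:
        raise ConfigurationError("fewer than 3 frames with positive weight")

    sw = w.sum()
    mean = (w @ values) / sw
    dev = values - mean
    cov = (dev * w[:, None]).T @ dev / sw
    var = np.diag(cov).copy()
    bad = var <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(var, var))
        r = cov / denom
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    rc = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(rc)
    np.fill_diagonal(z, 0.0)
    labels = roi_labels or [f"ROI{i + 1:03d}" for i in range(n_rois)]
    return ConnectivityMatrix(r=r, z=z, roi_labels=list(labels), effective_n=float(sw))
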