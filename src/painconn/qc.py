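"""Frame-level outlier flagging and quality-control summaries.

Scrubbing follows the two-criterion rule: a frame is flagged when its
framewise displacement exceeds 0.9 mm or its standardised global BOLD
signal change exceeds 5 SD (strict inequalities).  Per-subject QC variables
summarise residual signal variability and motion; subjects far outside the
sample distribution are flagged for inspection but never removed
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "QCRecord",
    "framewise_displacement",
    "global_signal_change",
    "flag_outliers",
    "sample_outlier_screen",
    "qc_record",
]

FD_THRESHOLD_MM = 0.9
GS_THRESHOLD_SD = 5.0
HEAD_RADIUS_MM = 50.0
MAX_INVALID_PCT = 50.0


@dataclass
class QCRecord:
    """Per-subject quality-control summary."""

    subject_id: str
    n_frames: int
    n_outliers: int
    pct_invalid: float
    bold_sd: float
    mean_signal_change: float
    max_signal_change: float
    mean_motion_change: float
    max_motion_change: float
    valid: bool

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_frames": self.n_frames,
            "n_outliers": self.n_outliers,
            "pct_invalid": self.pct_invalid,
            "bold_sd": self.bold_sd,
            "mean_signal_change": self.mean_signal_change,
            "max_signal_change": self.max_signal_change,
            "mean_motion_change": self.mean_motion_change,
            "max_motion_change": self.max_motion_change,
            "valid": self.valid,
        }


def framewise_displacement(
    motion: pd.DataFrame | np.ndarray, head_radius: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """Power-style framewise displacement in mm.

    ``fd[k] = sum |delta translation| + head_radius * sum |delta rotation|``
    using backward differences, with ``fd[0] = 0``.  Rotations (radians) are
    converted to arc length on a sphere of ``head_radius`` mm.
    """
    mot = np.asarray(motion, dtype=float)
    if mot.ndim != 2 or mot.shape[1] != 6:
        raise FormatError(f"motion table must have 6 columns, got shape {mot.shape}")
    d = np.abs(np.diff(mot, axis=0))
    fd = np.zeros(mot.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return fd


def global_signal_change(values: np.ndarray) -> np.ndarray:
    """Standardised change of the mean-across-ROIs signal, SD units.

    Backward difference of the global mean signal, divided by that
    difference series' own temporal SD; zero at frame 0 (and everywhere if
    the signal is constant).
    """
    g = np.asarray(values, dtype=float).mean(axis=1)
    dg = np.zeros_like(g)
    dg[1:] = np.diff(g)
    sd = dg[1:].std()
    if sd == 0:
        return np.zeros_like(g)
    return dg / sd


def flag_outliers(
    fd: np.ndarray,
    global_z: np.ndarray,
    fd_thresh: float = FD_THRESHOLD_MM,
    gs_thresh: float = GS_THRESHOLD_SD,
) -> np.ndarray:
    """Binary outlier flags: fd > fd_thresh OR |global_z| > gs_thresh."""
    fd = np.asarray(fd, dtype=float)
    gz = np.asarray(global_z, dtype=float)
    if fd.shape != gz.shape:
        raise FormatError(
            f"fd length {fd.shape[0]} != global-signal length {gz.shape[0]}"
        )
    return (fd > fd_thresh) | (np.abs(gz) > gs_thresh)


def sample_outlier_screen(values, k: float = 3.0) -> np.ndarray:
    """Indices of subjects outside median-based fences Q1-k*IQR, Q3+k*IQR.

    Quartiles use linear interpolation (type 7).  Flagged subjects are
    reported for inspection only; the pipeline never drops them.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise FormatError(f"need at least 4 subjects, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return np.flatnonzero((v < q1 - k * iqr) | (v > q3 + k * iqr))


def _changes_skipping_gaps(x: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Absolute backward differences on the retained-frame subsequence."""
    kept = x[~flags]
    if kept.ndim == 1:
        kept = kept[:, None]
    if kept.shape[0] < 2:
        return np.zeros(0)
    return np.abs(np.diff(kept, axis=0)).sum(axis=1)


def qc_record(
    subject_id: str,
    denoised: np.ndarray,
    motion: pd.DataFrame | np.ndarray,
    flags: np.ndarray,
    max_invalid_pct: float = MAX_INVALID_PCT,
) -> QCRecord:
    """Assemble the per-subject QC summary.

    Mean changes are computed after dropping flagged frames (differences
    taken on the retained subsequence, skipping censoring gaps); maxima are
    computed on the uncensored series.  A subject is valid while strictly
    less than ``max_invalid_pct`` percent of frames are flagged.
    """
    flags = np.asarray(flags, dtype=bool)
    n = flags.shape[0]
    n_out = int(flags.sum())
    g = np.asarray(denoised, dtype=float).mean(axis=1)
    mot = np.asarray(motion, dtype=float)

    sig_changes_all = np.abs(np.diff(g))
    sig_changes_kept = _changes_skipping_gaps(g, flags)
    mot_changes_all = np.abs(np.diff(mot, axis=0)).sum(axis=1)
    mot_changes_kept = _changes_skipping_gaps(mot, flags)

    pct = 100.0 * n_out / n
    return QCRecord(
        subject_id=subject_id,
        n_frames=n,
        n_outliers=n_out,
        pct_invalid=pct,
        bold_sd=float(np.asarray(denoised, float).std()),
        mean_signal_change=float(sig_changes_kept.mean()) if sig_changes_kept.size else 0.0,
        max_signal_change=float(sig_changes_all.max()) if sig_changes_all.size else 0.0,
        mean_motion_change=float(mot_changes_kept.mean()) if mot_changes_kept.size else 0.0,
        max_motion_change=float(mot_changes_all.max()) if mot_changes_all.size else 0.0,
        valid=pct < max_invalid_pct,
    )
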