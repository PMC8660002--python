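"""Readers and writers for the pipeline's plain-text table formats.

All numeric output uses '.' decimals, 17 significant digits (lossless
float64 round-trip), UTF-8 and LF endings.  Readers validate schemas and
raise :class:`~painconn.errors.FormatError` naming the file and the rule
violated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .simulate import SubjectData, add_duration_codings

__all__ = [
    "SUBJECT_COLUMNS",
    "MOTION_COLUMNS",
    "write_subjects", "read_subjects",
    "write_timeseries", "read_timeseries",
    "write_motion", "read_motion",
    "write_roi_map", "read_roi_map",
    "write_components", "read_components",
    "write_connectivity",
    "write_cohort",
]

FLOAT_FMT = "%.17g"
SUBJECT_COLUMNS = [
    "subject_id", "group", "sex", "age", "moca", "pain_med",
    "scanner_pain", "wpdur", "wpint",
]
MOTION_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz"]


def _write_csv(df: pd.DataFrame, path, sep=","):
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT,
              lineterminator="\n")


def _require_numeric(df: pd.DataFrame, path, cols=None):
    for c in cols if cols is not None else df.columns:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df[c][pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise FormatError(
                f"{path}: column {c!r} has non-numeric value at line {line}"
            )


def write_subjects(subjects: pd.DataFrame, path) -> None:
    _write_csv(subjects[SUBJECT_COLUMNS], path)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing subject columns {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate subject_id {dup.iloc[0]!r}")
    bad_group = set(df["group"].unique()) - {"pain", "control"}
    if bad_group:
        raise FormatError(f"{path}: unknown group labels {sorted(bad_group)}")
    _require_numeric(df, path, ["sex", "age", "moca", "pain_med", "scanner_pain"])
    pain = df["group"] == "pain"
    if (df.loc[pain, "wpdur"] <= 0).any():
        raise FormatError(f"{path}: pain rows must have wpdur > 0")
    return add_duration_codings(df)


def write_timeseries(values: pd.DataFrame, path) -> None:
    _write_csv(values, path, sep="\t")


def read_timeseries(path, roi_order: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_numeric(df, path)
    if roi_order is not None:
        missing = [r for r in roi_order if r not in df.columns]
        if missing:
            raise FormatError(f"{path}: ROI columns missing from header: {missing}")
        extra = [c for c in df.columns if c not in roi_order]
        if extra:
            raise FormatError(f"{path}: unknown ROI columns {extra}")
        df = df[roi_order]
    return df


def write_motion(motion: pd.DataFrame, path) -> None:
    _write_csv(motion, path, sep="\t")


def read_motion(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != MOTION_COLUMNS:
        raise FormatError(
            f"{path}: motion table must have columns {MOTION_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    _require_numeric(df, path)
    return df


def write_roi_map(roi_map: pd.DataFrame, path) -> None:
    _write_csv(roi_map[["roi", "network"]], path)


def read_roi_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["roi", "network"]:
        raise FormatError(f"{path}: ROI map must have columns ['roi', 'network']")
    if df["roi"].duplicated().any():
        raise FormatError(f"{path}: duplicate ROI labels")
    return df


def write_components(components: np.ndarray, path, prefix="comp") -> None:
    cols = [f"{prefix}{k + 1}" for k in range(components.shape[1])]
    _write_csv(pd.DataFrame(components, columns=cols), path, sep="\t")


def read_components(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_numeric(df, path)
    return df.to_numpy(float)


def write_connectivity(conn, path, square_path=None) -> None:
    """Long-format (roi_i, roi_j, r, z) CSV, optionally plus a square z matrix."""
    _write_csv(conn.to_long(), path)
    if square_path is not None:
        sq = pd.DataFrame(conn.z, index=conn.roi_labels, columns=conn.roi_labels)
        sq.to_csv(square_path, float_format=FLOAT_FMT, lineterminator="\n")


def write_cohort(
    subjects: pd.DataFrame,
    data: dict[str, SubjectData],
    roi_map: pd.DataFrame,
    out_dir,
) -> None:
    """Write a full synthetic cohort in the pipeline's input layout.

    Layout: ``subjects.csv``, ``roi_map.csv``, ``timeseries/<id>.tsv``,
    ``motion/<id>.tsv``, ``nuisance/<id>_wm.tsv`` and ``_csf.tsv``.
    """
    out = Path(out_dir)
    for sub in ("timeseries", "motion", "nuisance"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    write_subjects(subjects, out / "subjects.csv")
    write_roi_map(roi_map, out / "roi_map.csv")
    for sid, d in data.items():
        write_timeseries(d.values, out / "timeseries" / f"{sid}.tsv")
        write_motion(d.motion, out / "motion" / f"{sid}.tsv")
        write_components(d.wm_signals, out / "nuisance" / f"{sid}_wm.tsv", "vox")
        write_components(d.csf_signals, out / "nuisance" / f"{sid}_csf.tsv", "vox")
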