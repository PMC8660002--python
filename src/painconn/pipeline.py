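"""End-to-end driver: cohort on disk -> QC, connectivity, GLM, JN, deviation.

Reads a cohort laid out as written by :func:`painconn.io.write_cohort`,
runs every stage with the configured thresholds, and writes one CSV per
result family under ``out_dir``.  Deterministic given identical inputs and
configuration; logging goes to stderr and ``out_dir/run.log``, never into
the result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import denoise, deviation, glm, io, moderation, qc
from .config import PipelineConfig
from .errors import FormatError
from .glm import TERM_INTER, LadderResult

__all__ = ["PipelineResult", "run_pipeline", "compute_subject_connectivity"]

log = logging.getLogger("painconn")


@dataclass
class PipelineResult:
    """In-memory bundle of every pipeline output."""

    qc_table: pd.DataFrame
    edge_z: pd.DataFrame              # subjects x edges (canonical order)
    ladders: dict[str, LadderResult]
    jn_tables: dict[str, pd.DataFrame]
    deviation_tables: dict[str, pd.DataFrame]
    excluded: list[str] = field(default_factory=list)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def compute_subject_connectivity(
    values: pd.DataFrame,
    motion: pd.DataFrame,
    wm: np.ndarray | None,
    csf: np.ndarray | None,
    config: PipelineConfig,
    subject_id: str = "",
    tr: float = 2.0,
):
    """Single-subject signal path: QC flags, denoising, weighted connectivity."""
    fd = qc.framewise_displacement(motion, config.head_radius)
    gz = qc.global_signal_change(values.to_numpy(float))
    flags = qc.flag_outliers(fd, gz, config.fd_thresh, config.gs_thresh)
    design = denoise.build_nuisance_design(
        motion, flags, wm, csf, tr, config.n_compcor
    )
    cleaned, weights = denoise.denoise_and_filter(
        values.to_numpy(float), design, tr, config.band,
        outlier_flags=flags, order=config.denoise_order,
    )
    conn = denoise.weighted_connectivity(
        cleaned, weights, roi_labels=list(values.columns)
    )
    record = qc.qc_record(subject_id, cleaned, motion, flags, config.max_invalid_pct)
    return conn, record


def run_pipeline(config: PipelineConfig, tr: float = 2.0) -> PipelineResult:
    """Run every stage over the cohort under ``config.data_dir``.

    Per-subject parse failures are collected and reported together; subjects
    failing the validity gate (too many censored frames) are excluded with a
    logged reason.  Writes result CSVs under ``config.out_dir``.
    """
    config.validate()
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, data, out, tr)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config, data, out, tr) -> PipelineResult:
    log.info("config hash %s", _config_hash(config))
    subjects = io.read_subjects(data / "subjects.csv")
    roi_map = io.read_roi_map(data / "roi_map.csv")
    roi_order = roi_map["roi"].tolist()
    n_rois = len(roi_order)
    edges = denoise.edge_list(n_rois)

    failures: list[str] = []
    conns: dict[str, np.ndarray] = {}
    records = []
    excluded: list[str] = []
    for sid in subjects["subject_id"]:
        try:
            values = io.read_timeseries(data / "timeseries" / f"{sid}.tsv", roi_order)
            motion = io.read_motion(data / "motion" / f"{sid}.tsv")
            if len(values) != len(motion):
                raise FormatError(
                    f"{sid}: time series has {len(values)} frames but motion "
                    f"has {len(motion)}"
                )
            wm_path = data / "nuisance" / f"{sid}_wm.tsv"
            csf_path = data / "nuisance" / f"{sid}_csf.tsv"
            wm = io.read_components(wm_path) if wm_path.exists() else None
            csf = io.read_components(csf_path) if csf_path.exists() else None
        except (FormatError, FileNotFoundError) as exc:
            failures.append(f"{sid}: {exc}")
            continue
        conn, record = compute_subject_connectivity(
            values, motion, wm, csf, config, sid, tr
        )
        records.append(record.to_row())
        if not record.valid:
            excluded.append(sid)
            log.info("excluding %s: %.1f%% invalid frames", sid, record.pct_invalid)
            continue
        conns[sid] = conn.edge_vector()
    if failures:
        raise FormatError(
            "failed to load %d subject(s):\n" % len(failures) + "\n".join(failures)
        )

    qc_table = pd.DataFrame(records)
    screen_vals = qc_table["pct_invalid"].to_numpy()
    flagged = qc.sample_outlier_screen(screen_vals) if len(screen_vals) >= 4 else []
    qc_table["flagged"] = False
    qc_table.loc[list(flagged), "flagged"] = True
    qc_table.to_csv(out / "qc.csv", index=False, float_format=io.FLOAT_FMT,
                    lineterminator="\n")

    kept = subjects[subjects["subject_id"].isin(conns)].reset_index(drop=True)
    Z = np.vstack([conns[s] for s in kept["subject_id"]])
    edge_z = pd.DataFrame(
        Z, index=kept["subject_id"],
        columns=[f"{roi_order[i]}|{roi_order[j]}" for i, j in edges],
    )
    edge_z.to_csv(out / "edge_z.csv", float_format=io.FLOAT_FMT, lineterminator="\n")

    pain_mask = (kept["group"] == "pain").to_numpy()
    pain = kept[pain_mask].reset_index(drop=True)
    control = kept[~pain_mask].reset_index(drop=True)
    centers = deviation.covariate_reference(kept, config.control_covariates)

    ladders: dict[str, LadderResult] = {}
    jn_tables: dict[str, pd.DataFrame] = {}
    dev_tables: dict[str, pd.DataFrame] = {}
    for coding in config.codings:
        ladder = glm.elimination_ladder(
            Z[pain_mask], pain, coding, config.pain_covariates,
            config.alpha_elim, edges=edges,
        )
        ladders[coding] = ladder
        ladder.table.to_csv(out / f"glm_{coding}.csv", index=False,
                            float_format=io.FLOAT_FMT, lineterminator="\n")

        wp = pain["wpint"].dropna()
        jn_rows = []
        for e in ladder.edges_at_step(1):
            res = ladder.edge_results[e]
            reg = moderation.jn_region(
                res, moderator_range=(float(wp.min()), float(wp.max()))
            )
            b = list(reg.boundaries) + [np.nan, np.nan]
            jn_rows.append(
                {
                    "edge_index": e, "roi_i": res.edge[0], "roi_j": res.edge[1],
                    "moderator": reg.moderator, "alpha": reg.alpha,
                    "t_crit": reg.t_crit, "boundary_1": b[0], "boundary_2": b[1],
                    "region": reg.describe(),
                }
            )
        jn_tables[coding] = pd.DataFrame(jn_rows)
        jn_tables[coding].to_csv(out / f"jn_{coding}.csv", index=False,
                                 float_format=io.FLOAT_FMT, lineterminator="\n")

        dev_rows = []
        for e, res in ladder.edge_results.items():
            q = min(res.qvalues.values())
            if q > config.alpha_report:
                continue
            ctrl = deviation.control_adjusted_mean(
                Z[~pain_mask, e], control, config.control_covariates, centers
            )
            prof = deviation.deviation_profile(
                res, ctrl, kept, n_grid=config.grid_size,
                df_method=config.df_method,
            )
            tab = prof.table.copy()
            tab.insert(0, "edge_index", e)
            dev_rows.append(tab)
        dev_tables[coding] = (
            pd.concat(dev_rows, ignore_index=True) if dev_rows else pd.DataFrame()
        )
        dev_tables[coding].to_csv(out / f"deviation_{coding}.csv", index=False,
                                  float_format=io.FLOAT_FMT, lineterminator="\n")

    return PipelineResult(
        qc_table=qc_table, edge_z=edge_z, ladders=ladders,
        jn_tables=jn_tables, deviation_tables=dev_tables, excluded=excluded,
    )
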