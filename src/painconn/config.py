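"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (defaults follow the study protocol)."""

    # input layout (as written by `painconn simulate` / io.write_cohort)
    data_dir: str = "."
    out_dir: str = "results"

    # denoising
    band: tuple[float, float] = (0.008, 0.09)
    n_compcor: int = 5
    denoise_order: str = "regress-then-filter"

    # scrubbing / QC
    fd_thresh: float = 0.9
    gs_thresh: float = 5.0
    head_radius: float = 50.0
    max_invalid_pct: float = 50.0

    # group models
    codings: tuple[str, ...] = ("log", "linear", "dichotomous")
    alpha_elim: float = 0.05
    alpha_report: float = 0.01
    pain_covariates: tuple[str, ...] = (
        "sex", "age", "pain_med", "moca", "scanner_pain"
    )
    control_covariates: tuple[str, ...] = ("sex", "age", "moca")

    # deviation profiles
    grid_size: int = 200
    df_method: str = "welch"

    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.band[0] < self.band[1]):
            raise ConfigurationError(f"band {self.band} must satisfy 0 <= low < high")
        for name in ("fd_thresh", "gs_thresh", "head_radius", "grid_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("alpha_elim", "alpha_report"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        bad = set(self.codings) - {"log", "linear", "dichotomous"}
        if bad:
            raise ConfigurationError(f"unknown codings {sorted(bad)}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, then overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
    for key in ("band", "codings", "pain_covariates", "control_covariates"):
        if key in values and isinstance(values[key], list):
            values[key] = tuple(values[key])
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg
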