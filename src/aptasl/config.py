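"""Schema-validated pipeline configuration.

Unknown keys are rejected so typos fail loudly, and the full config is
serialized into every report (plus a SHA-256 hash) for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Invalid or unreadable configuration."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AslParamsConfig(_StrictModel):
    """Overrides of the pCASL quantification constants (times in ms)."""

    w: float = 2000.0
    TE: float = 13.58
    TR: float = 5500.0
    labeling_duration: float = 1800.0
    T1a: float = 1650.0
    T2a: float = 150.0
    alpha: float = 0.85
    rho: float = 1.0
    lambda_a: float = 0.76
    T1csf: float = 4300.0
    unit_scale: float = 6000.0
    use_bolus_term: bool = False


class PhantomConfig(_StrictModel):
    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    lesion_center: tuple[float, float, float] = (8.0, 16.0, 4.0)
    lesion_radius: float = 8.0
    lesion_mtrasym: float = 0.03
    background_mtrasym: float = 0.0
    lesion_cbf: float = 20.0
    background_cbf: float = 45.0
    noise_sd: float = Field(0.0, ge=0.0)


class CohortConfig(_StrictModel):
    n_favorable: int = Field(18, ge=2)
    n_unfavorable: int = Field(40, ge=2)
    correlation: float = Field(0.0, gt=-0.99, lt=1.0)


class AnalysisConfig(_StrictModel):
    alpha: float = Field(0.05, gt=0.0, le=1.0)
    n_folds: int = Field(10, ge=2)
    lasso_on: Literal["significant", "all"] = "significant"
    lambda_rule: Literal["min", "1se"] = "min"
    cutoff_rule: Literal["youden", "closest01"] = "youden"
    positive_class: Literal["unfavorable", "favorable"] = "unfavorable"
    ridge_eps: float | None = None


class PipelineConfig(_StrictModel):
    """Top-level configuration for every CLI subcommand."""

    seed: int = 0
    outdir: str = "aptasl_out"
    phantom: PhantomConfig = PhantomConfig()
    cohort: CohortConfig = CohortConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    asl_params: AslParamsConfig = AslParamsConfig()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/JSON config file; ``None`` yields the defaults.

    Raises :class:`ConfigError` with the parse location on malformed
    input and on schema violations.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        payload = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as err:
        mark = getattr(err, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigError(f"cannot parse {path}{where}: {err}") from err
    if payload is None:
        payload = {}
    try:
        return PipelineConfig.model_validate(payload)
    except Exception as err:
        raise ConfigError(f"invalid config {path}: {err}") from err


def config_hash(config: PipelineConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
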