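"""Run configuration: a validated schema covering every pipeline stage."""
from __future__ import annotations

import json
import math
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .cohort import DEFAULT_CHANNELS, DEFAULT_SERUM_GROUPS


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or irreconcilable input data (CLI exit code 3)."""


class GroupSpec(BaseModel):
    label: str
    n: int = Field(ge=0)
    specimen: str = "serum"

    @field_validator("specimen")
    @classmethod
    def _spec(cls, v):
        if v not in ("serum", "tissue"):
            raise ValueError("specimen must be 'serum' or 'tissue'")
        return v


class PanelSpec(BaseModel):
    n_ct: int = 213
    n_ta: int = 49
    n_replicates: int = Field(default=3, ge=1)


class PlantedEffectSpec(BaseModel):
    group: str
    channel: str
    antigen_id: str
    log2_fc: float
    penetrance: float = Field(default=1.0, ge=0.0, le=1.0)


class EffectConfig(BaseModel):
    planted_effects: list[PlantedEffectSpec] = []
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = Field(default=0.025, gt=0)
    replicate_log_sd: float = 0.03
    antigen_log_sd: float = 0.30
    background_mean: float = 100.0
    background_sd: float = 15.0
    background_estimation_sd: float = 5.0
    psa_elevation: float = 3.0
    psa_n_range: tuple[int, int] = (81, 150)


class ClusterSpec(BaseModel):
    distance: str = "correlation"
    linkage: str = "average"
    epsilon: float = 1.0


class RunConfig(BaseModel):
    """Global configuration; every stochastic stage derives its stream from
    ``seed``."""

    seed: int = 0
    groups: list[GroupSpec] = [GroupSpec(label=l, n=n, specimen=s)
                               for l, n, s in DEFAULT_SERUM_GROUPS]
    channels: list[str] = list(DEFAULT_CHANNELS)
    psa_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    panel: PanelSpec = PanelSpec()
    effects: EffectConfig = EffectConfig()
    normalization: str = "median_scale"
    control_groups: dict[str, str] = {"serum": "LTBI", "tissue": "normal_adjacent"}
    case: str = "PDAC"
    controls: list[str] = ["DYS", "CP"]
    fdr: float = Field(default=0.01, gt=0, lt=1)
    panel_sizes: tuple[int, int] = (2, 6)
    top_m: int = Field(default=20, ge=1)
    combination_rule: str = "count_positive"
    max_panels: int = 200_000
    lectins: list[str] = ["RCA", "SNA", "LCA", "ECL"]
    cluster: ClusterSpec = ClusterSpec()
    cv_warn: float = 0.20
    exclude_psa: bool = True
    make_plots: bool = False

    @field_validator("normalization")
    @classmethod
    def _norm(cls, v):
        if v not in ("median_scale", "quantile", "none"):
            raise ValueError("normalization must be median_scale, quantile or none")
        return v

    @field_validator("combination_rule")
    @classmethod
    def _rule(cls, v):
        if v not in ("count_positive", "logistic"):
            raise ValueError("combination_rule must be count_positive or logistic")
        return v

    @field_validator("panel_sizes")
    @classmethod
    def _sizes(cls, v):
        lo, hi = v
        if lo < 1 or hi < lo:
            raise ValueError("panel_sizes must be (lo, hi) with 1 <= lo <= hi")
        return v


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file; missing file fields fall back to defaults."""
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
        try:
            data = (json.loads(text) if p.suffix.lower() == ".json"
                    else yaml.safe_load(text)) or {}
        except Exception as exc:
            raise ConfigError(f"cannot parse config {p}: {exc}") from exc
    if overrides:
        data.update(overrides)
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
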