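"""Single-file YAML configuration covering every pipeline stage."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError

from ciedwatch.flags import FlagConfig, default_flag_config
from ciedwatch.keywords import Ruleset, compile_ruleset, default_ruleset
from ciedwatch.synth import SimulationConfig


class ModelConfig(BaseModel):
    covariates: list[str] = Field(default_factory=lambda: [
        "died_90d", "congestive_heart_failure",
        "solid_tumor_without_metastasis", "icd_cied_infection", "icd_ssi",
        "antibiotic_staph_directed", "antibiotic_non_staph",
        "micro_cardiac_pos", "note_infection_post", "note_infection_pre",
    ])
    threshold: float = 0.10
    firth: bool = False
    tol: float = 1e-8
    maxiter: int = 100


class TriageConfig(BaseModel):
    above_fraction: float = 0.8
    below_fraction: float = 0.01


class EvaluationConfig(BaseModel):
    band_edges: list[float] = Field(
        default_factory=lambda: [0.0, 0.01, 0.03, 0.10, 0.50, 1.0])


class AppConfig(BaseModel):
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    flags: FlagConfig = Field(default_factory=default_flag_config)
    ruleset: Optional[dict] = None  # inline rule definitions; None = packaged
    model: ModelConfig = Field(default_factory=ModelConfig)
    triage: TriageConfig = Field(default_factory=TriageConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)

    def compiled_ruleset(self) -> Ruleset:
        if self.ruleset is None:
            return default_ruleset()
        return compile_ruleset(self.ruleset)

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


class ConfigError(ValueError):
    pass


def load_config(path: Optional[Union[str, Path]] = None) -> AppConfig:
    """Load and validate a YAML config; None gives the packaged defaults.

    Validation failures are reported with the offending field paths before
    any computation starts.
    """
    if path is None:
        return AppConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return AppConfig.model_validate(raw)
    except ValidationError as e:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in e.errors())
        raise ConfigError(f"invalid configuration ({path}): {locs}") from e
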