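"""Run-configuration loading and validation.

A run configuration is a small YAML/JSON document naming the two strategies
and, optionally, the cohort size, setting mix, evidence source, bound
selection and paths to evidence/cost/recipe files. Missing fields take the
shipped base-case defaults (cohort 1000, 40/60 hospital/community mix,
published point estimates). Validation failures raise :class:`ConfigError`
with a message naming the offending key.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .analysis import AnalysisConfig
from .cohort import SettingMix, Strategy, StrategyPair
from .costs import load_costs, load_recipe
from .errors import ConfigError, InvalidParameterError, PPHEconError
from .evidence import load_evidence

__all__ = ["ModelConfig", "load_and_validate"]

logger = logging.getLogger("pphecon")

Prophylaxis = Literal["oxytocin", "misoprostol", "none"]
Bound = Literal["point", "low", "high"]


class _StrategySchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hospital: Prophylaxis
    community: Prophylaxis


class _MixSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hospital_fraction: float = Field(ge=0.0, le=1.0)
    community_fraction: Optional[float] = Field(default=None, ge=0.0, le=1.0)


class _ScenarioSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    intervention: _StrategySchema
    comparator: _StrategySchema
    cohort_size: int = Field(default=1000, ge=1)
    mix: _MixSchema = _MixSchema(hospital_fraction=0.4, community_fraction=0.6)
    evidence_source: str = "tuncalp2012"
    rr_bound: Bound = "point"


class _ConfigSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: _ScenarioSchema
    evidence_file: Optional[str] = None
    cost_file: Optional[str] = None
    recipe_file: Optional[str] = None
    drug_cost_bound: Bound = "point"
    treatment_cost_multiplier: float = Field(default=1.0, ge=0.0)
    seed: int = 0
    verbosity: Literal["debug", "info", "warning", "error"] = "info"


@dataclass(frozen=True)
class ModelConfig:
    """A fully validated run configuration with defaults applied."""

    analysis: AnalysisConfig
    seed: int
    verbosity: str


def _resolve(path: Optional[str], base_dir: str) -> Optional[str]:
    if path is None:
        return None
    return path if os.path.isabs(path) else os.path.join(base_dir, path)


def load_and_validate(path: str) -> ModelConfig:
    """Load, schema-validate and materialise a run configuration.

    Referenced evidence/cost/recipe files are resolved relative to the
    configuration file and validated on load, before any computation.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"config file {path!r} is not a mapping")
    try:
        schema = _ConfigSchema.model_validate(dict(doc))
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"config key {key!r}: {first['msg']}") from exc

    base_dir = os.path.dirname(os.path.abspath(path))
    scenario = schema.scenario
    mix_spec = scenario.mix
    community = (
        mix_spec.community_fraction
        if mix_spec.community_fraction is not None
        else 1.0 - mix_spec.hospital_fraction
    )
    try:
        mix = SettingMix(mix_spec.hospital_fraction, community)
        pair = StrategyPair(
            intervention=Strategy(
                scenario.intervention.hospital, scenario.intervention.community
            ),
            comparator=Strategy(
                scenario.comparator.hospital, scenario.comparator.community
            ),
            cohort_size=scenario.cohort_size,
            mix=mix,
            evidence_source=scenario.evidence_source,
            rr_bound=scenario.rr_bound,
        )
        evidence = load_evidence(_resolve(schema.evidence_file, base_dir))
        costs = load_costs(_resolve(schema.cost_file, base_dir))
        recipe, doses = load_recipe(_resolve(schema.recipe_file, base_dir))
    except PPHEconError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if scenario.evidence_source not in evidence:
        raise ConfigError(
            f"config key 'scenario.evidence_source': unknown source "
            f"{scenario.evidence_source!r}; available: {sorted(evidence)}"
        )
    analysis = AnalysisConfig(
        pair=pair,
        evidence=evidence,
        costs=costs,
        doses=doses,
        recipe=recipe,
        drug_cost_bound=schema.drug_cost_bound,
        treatment_cost_multiplier=schema.treatment_cost_multiplier,
    )
    logger.info(
        "loaded config %s: %s vs %s, n=%d, mix=%.2f/%.2f, source=%s",
        path,
        pair.intervention.label(),
        pair.comparator.label(),
        pair.cohort_size,
        mix.hospital_fraction,
        mix.community_fraction,
        pair.evidence_source,
    )
    return ModelConfig(analysis=analysis, seed=schema.seed, verbosity=schema.verbosity)
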