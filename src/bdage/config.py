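"""Run configuration: a validated, round-trippable YAML schema.

A run file fully determines a simulation: model parameters, the initial
population (per-lineage groups of clonal founders), the stop criterion and
the seed.  Unknown keys are rejected so typos fail loudly, and every CLI run
echoes its resolved configuration into the output directory.

Example::

    seed: 42
    params:
      i_b: 1.0
      i_d: 1.0
      c: 0.0009
      p: 0.1
      sigma: 0.05
      lansing_enabled: true
      lansing_magnitude: 1.0
    initial:
      - lineage: lansing
        count: 500
        trait: [1.5, 1.3]
      - lineage: non_lansing
        count: 500
        trait: [1.5, 0.83]
    stop:
      max_events: 200000
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import Individual
from .model import Intensities, LansingRule, ModelParams, MutationKernel, Trait

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsSpec(_Strict):
    i_b: float = Field(ge=0)
    i_d: float = Field(ge=0)
    c: float = Field(default=0.0, ge=0)
    p: float = Field(default=0.0, ge=0, le=1)
    sigma: float = Field(default=0.0, ge=0)
    lansing_enabled: bool = True
    lansing_magnitude: float = Field(default=1.0, ge=0, le=1)


class GroupSpec(_Strict):
    lineage: Literal["lansing", "non_lansing"]
    count: int = Field(ge=1)
    trait: Tuple[float, float]
    age: float = Field(default=0.0, ge=0)


class StopSpec(_Strict):
    max_events: Optional[int] = Field(default=None, gt=0)
    time_horizon: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _at_least_one(self):
        if self.max_events is None and self.time_horizon is None:
            raise ValueError("stop criterion requires max_events and/or time_horizon")
        return self


class RunConfig(_Strict):
    """Complete, validated description of one simulation run."""

    seed: int
    params: ParamsSpec
    initial: List[GroupSpec]
    stop: StopSpec
    output_dir: Optional[str] = None

    def model_params(self) -> ModelParams:
        p = self.params
        return ModelParams(
            intensities=Intensities(p.i_b, p.i_d),
            c=p.c,
            kernel=MutationKernel(p.p, p.sigma),
            lansing=LansingRule(p.lansing_enabled, p.lansing_magnitude),
        )

    def founder_population(self) -> list[Individual]:
        out: list[Individual] = []
        next_id = 0
        for group in self.initial:
            trait = Trait(*group.trait)
            for _ in range(group.count):
                # founders of age a at t=0 carry birth_time -a
                out.append(Individual(next_id, trait, -group.age, group.lineage))
                next_id += 1
        return out


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run file; unknown keys are an error."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: run configuration must be a mapping")
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path) -> None:
    """Write a configuration back to YAML (lossless round trip)."""
    data = cfg.model_dump(exclude_none=True)
    # tuples -> lists for clean YAML
    for group in data["initial"]:
        group["trait"] = list(group["trait"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
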