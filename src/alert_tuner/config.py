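"""Validated pipeline configuration (YAML-friendly, seed mandatory)."""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .extract import AnchorConfig, BoostedConfig, EnsembleConfig
from .metrics import SelectionThresholds
from .simulate import PlantedRule, SimulationConfig

__all__ = ["PipelineConfig", "load_config"]


class _Opts(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessingOptions(_Opts):
    n_bins: int = Field(10, ge=1)
    impute_strategy: Literal["mean", "median", "most_frequent"] = "median"
    min_firings: int = 100
    min_acceptances: int = 10


class ClassifierOptions(_Opts):
    family: Literal[
        "gradient_boosted_trees", "random_forest", "neural_network", "support_vector_machine"
    ] = "gradient_boosted_trees"
    search_budget: int = Field(8, ge=1)
    test_size: float = Field(0.2, gt=0.0, lt=1.0)
    temporal_split: bool = False
    n_bootstrap: int = Field(1000, ge=1)


class EnsembleOptions(_Opts):
    n_estimators: int = 30
    max_depth: int = 3
    min_oob_precision: float = Field(0.95, gt=0.0, le=1.0)
    min_coverage: float = 0.01

    def build(self, seed: int) -> EnsembleConfig:
        return EnsembleConfig(seed=seed, **self.model_dump())


class BoostedOptions(_Opts):
    n_rounds: int = 10
    max_depth: int = Field(1, ge=1, le=2)

    def build(self, seed: int) -> BoostedConfig:
        return BoostedConfig(seed=seed, **self.model_dump())


class AnchorOptions(_Opts):
    enabled: bool = True
    precision_threshold: float = Field(0.95, gt=0.0, le=1.0)
    beam_width: int = 3
    max_predicates: int = 4
    n_samples: int = 500
    n_instances_per_bpa: int = 10

    def build(self, seed: int, excluded_features=()) -> AnchorConfig:
        d = self.model_dump()
        d.pop("enabled")
        d.pop("n_instances_per_bpa")
        return AnchorConfig(seed=seed, excluded_features=tuple(excluded_features), **d)


class ThresholdOptions(_Opts):
    or_min: float = 1.25
    prob_low_min: float = 0.5
    low_acceptance_theta: float = Field(0.02, gt=0.0, lt=1.0)
    decrease_max: float = 0.4
    confidence_min: float = 0.98
    interest_min: float = 1.0
    conviction_min: float = 1.2
    chi2_p_max: float = 0.01

    def build(self) -> SelectionThresholds:
        return SelectionThresholds(**self.model_dump())


class PlantedRuleOptions(_Opts):
    bpa_id: str
    predicates: list
    subgroup_acceptance: float
    target_coverage: float

    def build(self) -> PlantedRule:
        preds = tuple(
            (f, tuple(v) if isinstance(v, (list, tuple)) else v) for f, v in self.predicates
        )
        return PlantedRule(self.bpa_id, preds, self.subgroup_acceptance, self.target_coverage)


class SimulationOptions(_Opts):
    n_bpas: int = 5
    firings_per_bpa: tuple[int, int] = (10_000, 10_000)
    base_acceptance_beta: tuple[float, float] = (6.0, 44.0)
    base_acceptance: Optional[float] = None
    n_categorical: int = 5
    categorical_cardinality: int = 8
    n_numeric: int = 3
    numeric_mean: float = 50.0
    numeric_sd: float = 15.0
    missingness: float = Field(0.05, ge=0.0, le=1.0)
    planted_rules: list[PlantedRuleOptions] = []

    def build(self, seed: int) -> SimulationConfig:
        d = self.model_dump()
        d["planted_rules"] = tuple(p.build() for p in self.planted_rules)
        d["firings_per_bpa"] = tuple(d["firings_per_bpa"])
        d["base_acceptance_beta"] = tuple(d["base_acceptance_beta"])
        return SimulationConfig(seed=seed, **d)


class PipelineConfig(_Opts):
    """Everything one end-to-end run needs; the seed has no wall-clock default."""

    seed: int
    input_log: Optional[str] = None
    simulation: Optional[SimulationOptions] = None
    preprocessing: PreprocessingOptions = PreprocessingOptions()
    classifier: ClassifierOptions = ClassifierOptions()
    ensemble: EnsembleOptions = EnsembleOptions()
    boosted: BoostedOptions = BoostedOptions()
    anchor: AnchorOptions = AnchorOptions()
    thresholds: ThresholdOptions = ThresholdOptions()
    holdout_log: Optional[str] = None


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
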