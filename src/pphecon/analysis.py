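"""End-to-end evaluation of one intervention-vs-comparator comparison.

This is the glue the base case, the one-way sensitivity driver and the
setting-mix sweep all share: evaluate both strategies' expected event counts,
cost both, and difference them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .cohort import (
    CohortResult,
    IncrementalResult,
    StrategyPair,
    evaluate_strategy,
    incremental_outcomes,
)
from .costs import (
    CostBreakdown,
    DoseSchedule,
    IncrementalCost,
    TreatmentRecipe,
    UnitCostTable,
    load_costs,
    load_recipe,
    prophylaxis_cost,
    total_and_incremental_cost,
    treatment_cost,
)
from .errors import EvidenceIncompleteError
from .evidence import EvidenceSet, load_evidence

__all__ = ["AnalysisConfig", "ComparisonResult", "evaluate_comparison"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one comparison run needs: the strategy pair, the evidence
    registry, unit costs, dosing and the treatment recipe."""

    pair: StrategyPair
    evidence: Mapping[str, EvidenceSet]
    costs: UnitCostTable
    doses: DoseSchedule = DoseSchedule()
    recipe: TreatmentRecipe = TreatmentRecipe()
    drug_cost_bound: str = "point"
    treatment_cost_multiplier: float = 1.0

    @classmethod
    def with_defaults(cls, pair: StrategyPair, **overrides) -> "AnalysisConfig":
        """Build a config from the packaged evidence/cost/recipe defaults."""
        recipe, doses = load_recipe()
        base = dict(
            pair=pair,
            evidence=load_evidence(),
            costs=load_costs(),
            doses=doses,
            recipe=recipe,
        )
        base.update(overrides)
        return cls(**base)

    def evidence_set(self) -> EvidenceSet:
        try:
            return self.evidence[self.pair.evidence_source]
        except KeyError as exc:
            raise EvidenceIncompleteError(
                f"evidence incomplete: unknown source "
                f"{self.pair.evidence_source!r}"
            ) from exc


@dataclass(frozen=True)
class ComparisonResult:
    """Scenario columns plus increments for one evaluated comparison."""

    config: AnalysisConfig
    intervention: CohortResult
    comparator: CohortResult
    intervention_costs: CostBreakdown
    comparator_costs: CostBreakdown
    increments: IncrementalResult
    incremental_cost: IncrementalCost


def _cost_strategy(
    config: AnalysisConfig, cohort: CohortResult
) -> CostBreakdown:
    drug = prophylaxis_cost(
        cohort.strategy,
        config.pair.cohort_size,
        config.pair.mix,
        config.costs,
        config.doses,
        config.drug_cost_bound,
    )
    treat = treatment_cost(
        cohort,
        config.recipe,
        config.costs,
        "point",
        config.treatment_cost_multiplier,
    )
    return CostBreakdown(prophylaxis_drug_cost=drug, pph_treatment_cost=treat)


def evaluate_comparison(config: AnalysisConfig) -> ComparisonResult:
    """Run the full deterministic pipeline for one strategy pair."""
    evidence = config.evidence_set()
    pair = config.pair
    intervention = evaluate_strategy(
        pair.intervention, pair.cohort_size, pair.mix, evidence, pair.rr_bound
    )
    comparator = evaluate_strategy(
        pair.comparator, pair.cohort_size, pair.mix, evidence, pair.rr_bound
    )
    i_costs = _cost_strategy(config, intervention)
    c_costs = _cost_strategy(config, comparator)
    return ComparisonResult(
        config=config,
        intervention=intervention,
        comparator=comparator,
        intervention_costs=i_costs,
        comparator_costs=c_costs,
        increments=incremental_outcomes(intervention, comparator),
        incremental_cost=total_and_incremental_cost(i_costs, c_costs),
    )
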