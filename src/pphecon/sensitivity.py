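"""One-way (univariate) sensitivity analyses and the setting-mix sweep.

Each substitution clones the base-case configuration, replaces exactly one
parameter, and re-runs the same cohort and cost engines. Supported targets:

``rr_bound``
    Use the lower/upper 95 % confidence limit of the relative risks instead
    of the point estimates.
``baseline_source``
    Swap the evidence source (both baseline rates and relative risks move
    together — a source substitution, not a per-parameter one).
``drug_cost_bound``
    Reprice the two uterotonic drugs at their low/high listed prices. This
    repricing flows into the treatment-phase oxytocin as well as the
    prophylactic dose.
``treatment_cost_multiplier``
    Scale the whole PPH-treatment side (e.g. 0.5 or 2.0).
``stay_costs_override``
    Replace the overnight-stay unit prices, e.g.
    ``{"overnight_health_centre": 20, "overnight_hospital": 50}``.
``mix``
    Replace the hospital/community birth-setting mix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .analysis import AnalysisConfig, ComparisonResult, evaluate_comparison
from .cohort import SettingMix, round_half_away_from_zero
from .costs import DRUG_ITEMS
from .errors import UnsupportedSubstitutionError
from .evidence import OUTCOMES, Outcome, merge_sources

__all__ = [
    "SUBSTITUTION_TARGETS",
    "Substitution",
    "SensitivityRow",
    "apply_substitution",
    "one_way",
    "mix_sweep",
    "base_row",
]

SUBSTITUTION_TARGETS = (
    "rr_bound",
    "baseline_source",
    "drug_cost_bound",
    "treatment_cost_multiplier",
    "stay_costs_override",
    "mix",
)


@dataclass(frozen=True)
class Substitution:
    """A single replaced parameter (one-way discipline: exactly one)."""

    target: str
    value: object
    label: str | None = None

    def __post_init__(self) -> None:
        if self.target not in SUBSTITUTION_TARGETS:
            raise UnsupportedSubstitutionError(
                f"unsupported substitution target {self.target!r}; "
                f"expected one of {SUBSTITUTION_TARGETS}"
            )

    def display_label(self) -> str:
        return self.label if self.label is not None else f"{self.target}={self.value}"


@dataclass(frozen=True)
class SensitivityRow:
    """Increments for one analysis row (reported integers plus raw values)."""

    label: str
    increments: Mapping[Outcome, int]
    increments_unrounded: Mapping[Outcome, float]
    incremental_cost: float
    incremental_cost_reported: int
    result: ComparisonResult


def _row_from_result(label: str, result: ComparisonResult) -> SensitivityRow:
    unrounded = dict(result.increments.unrounded)
    return SensitivityRow(
        label=label,
        increments={o: round_half_away_from_zero(v) for o, v in unrounded.items()},
        increments_unrounded=unrounded,
        incremental_cost=result.incremental_cost.total,
        incremental_cost_reported=round_half_away_from_zero(
            result.incremental_cost.total
        ),
        result=result,
    )


def base_row(base: AnalysisConfig, label: str = "Base case") -> SensitivityRow:
    """The unmodified base-case comparison, in sensitivity-row form."""
    return _row_from_result(label, evaluate_comparison(base))


def apply_substitution(
    base: AnalysisConfig, substitution: Substitution
) -> AnalysisConfig:
    """Clone the base configuration with exactly one parameter replaced."""
    target, value = substitution.target, substitution.value
    if target == "rr_bound":
        return replace(base, pair=replace(base.pair, rr_bound=str(value)))
    if target == "baseline_source":
        label = str(value)
        if label not in base.evidence:
            raise UnsupportedSubstitutionError(
                f"unknown evidence source {label!r}; available: "
                f"{sorted(base.evidence)}"
            )
        # Overlay the substitute source on the current one so contexts the
        # substitute lacks (e.g. no oxytocin arm in a home-birth review) keep
        # their base-case baselines.
        merged = merge_sources(base.evidence_set(), base.evidence[label])
        registry = dict(base.evidence)
        registry[label] = merged
        return replace(
            base,
            evidence=registry,
            pair=replace(base.pair, evidence_source=label),
        )
    if target == "drug_cost_bound":
        return replace(base, costs=base.costs.at_bound(DRUG_ITEMS, str(value)))
    if target == "treatment_cost_multiplier":
        return replace(base, treatment_cost_multiplier=float(value))  # type: ignore[arg-type]
    if target == "stay_costs_override":
        if not isinstance(value, Mapping):
            raise UnsupportedSubstitutionError(
                "stay_costs_override expects a mapping of item -> price"
            )
        return replace(base, costs=base.costs.with_overrides(value))
    if target == "mix":
        if isinstance(value, SettingMix):
            mix = value
        elif isinstance(value, Mapping):
            mix = SettingMix(**value)
        else:
            hospital, community = value  # type: ignore[misc]
            mix = SettingMix(float(hospital), float(community))
        return replace(base, pair=replace(base.pair, mix=mix))
    raise UnsupportedSubstitutionError(f"unsupported substitution target {target!r}")


def one_way(base: AnalysisConfig, substitution: Substitution) -> SensitivityRow:
    """Recompute the comparison with a single parameter substituted."""
    return _row_from_result(
        substitution.display_label(),
        evaluate_comparison(apply_substitution(base, substitution)),
    )


def mix_sweep(
    base: AnalysisConfig, proportions: Sequence[SettingMix]
) -> list[SensitivityRow]:
    """Recompute the base comparison under each hospital/community mix."""
    rows = []
    for mix in proportions:
        label = (
            f"{round(mix.hospital_fraction * 100)}/"
            f"{round(mix.community_fraction * 100)} %"
        )
        rows.append(one_way(base, Substitution("mix", mix, label=label)))
    return rows
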