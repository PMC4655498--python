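"""Costing cascade: prophylaxis drug costs and PPH treatment costs.

Prophylaxis cost is births times a per-dose drug price (three 200 ug
misoprostol tablets, or one 10 iU oxytocin ampoule; the prophylactic syringe
is excluded by default). Treatment cost follows a WHO Mother-Baby-Package
style referral cascade: every PPH case receives a treatment bundle
(therapeutic oxytocin + syringe + IV fluids + infusion set); hospital-origin
cases may stay extra nights; community cases present at a health post, are
all referred onward with emergency transport (half to a health centre — which
itself refers half onward to hospital — and half straight to hospital); and
transfusion and additional-uterotonic cases consume their own consumables.

The per-case recipe is explicit configuration: the published analysis this
model mirrors never printed its internal per-case formula, so treatment-cost
totals are recipe-dependent while event counts and drug costs are exact.
Money values are plain floats in model currency (2012 US$ for the shipped
tables); all rounding to whole dollars happens in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import yaml

from .cohort import CohortResult, SettingMix, Strategy, round_half_away_from_zero
from .errors import InvalidParameterError, InvalidRecipeError
from .evidence import BOUNDS, Outcome

__all__ = [
    "COST_ITEMS",
    "CostEstimate",
    "UnitCostTable",
    "DoseSchedule",
    "TreatmentRecipe",
    "CostBreakdown",
    "IncrementalCost",
    "prophylaxis_cost",
    "treatment_cost",
    "per_case_treatment_cost",
    "total_and_incremental_cost",
    "inflate_cost",
    "load_costs",
    "load_recipe",
]

COST_ITEMS = (
    "oxytocin_10iu",
    "misoprostol_200ug",
    "iv_fluids",
    "infusion_set",
    "blood_unit",
    "blood_giving_set",
    "transport_per_km",
    "overnight_health_centre",
    "overnight_hospital",
    "syringe",
)

#: Items whose prices a "drug cost" substitution reprices (both the
#: prophylaxis dose and the treatment-phase oxytocin).
DRUG_ITEMS = ("oxytocin_10iu", "misoprostol_200ug")


@dataclass(frozen=True)
class CostEstimate:
    point: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.point <= self.high:
            raise InvalidParameterError(
                f"cost estimate must satisfy 0 < low <= point <= high, "
                f"got {self.low}/{self.point}/{self.high}"
            )

    def value(self, bound: str = "point") -> float:
        if bound not in BOUNDS:
            raise InvalidParameterError(f"bound must be one of {BOUNDS}")
        return getattr(self, bound)


@dataclass(frozen=True)
class UnitCostTable:
    """Per-item unit costs (point/low/high) in model currency."""

    items: Mapping[str, CostEstimate]

    def __post_init__(self) -> None:
        missing = set(COST_ITEMS) - set(self.items)
        if missing:
            raise InvalidParameterError(f"unit cost table missing {sorted(missing)}")

    def get(self, item: str, bound: str = "point") -> float:
        return self.items[item].value(bound)

    def with_overrides(self, overrides: Mapping[str, float]) -> "UnitCostTable":
        """A copy with selected items' point estimates replaced (bounds scaled
        so low <= point <= high stays valid)."""
        new_items = dict(self.items)
        for item, price in overrides.items():
            if item not in new_items:
                raise InvalidParameterError(f"unknown cost item {item!r}")
            if price <= 0:
                raise InvalidParameterError(f"override for {item!r} must be > 0")
            old = new_items[item]
            scale = price / old.point
            new_items[item] = CostEstimate(price, old.low * scale, old.high * scale)
        return UnitCostTable(new_items)

    def at_bound(self, items: tuple[str, ...], bound: str) -> "UnitCostTable":
        """A copy with the chosen items' point estimates moved to ``bound``."""
        return self.with_overrides({i: self.get(i, bound) for i in items})


@dataclass(frozen=True)
class DoseSchedule:
    """Prophylactic dosing: 600 ug oral misoprostol (3 x 200 ug tablets) or
    10 iU oxytocin IV/IM."""

    misoprostol_tablets_per_dose: int = 3
    oxytocin_units_label: str = "10 iU"
    include_syringe_in_prophylaxis: bool = False

    def __post_init__(self) -> None:
        if self.misoprostol_tablets_per_dose < 1:
            raise InvalidParameterError("misoprostol_tablets_per_dose must be >= 1")


@dataclass(frozen=True)
class TreatmentRecipe:
    """Per-case clinical-management recipe for treating one PPH case."""

    bundle_oxytocin: bool = True
    bundle_syringe: bool = True
    bundle_iv_fluids: bool = True
    bundle_infusion_set: bool = True
    hospital_stay_fraction: float = 0.5
    hospital_stay_nights: float = 7.0
    health_centre_stay_fraction: float = 0.5
    health_centre_stay_nights: float = 2.0
    health_post_referral_fraction: float = 1.0
    health_post_to_health_centre_split: float = 0.5
    health_centre_onward_fraction: float = 0.5
    transport_km: float = 10.0
    blood_units_per_transfusion: int = 1
    severe_pph_extra_cost: float = 0.0

    def __post_init__(self) -> None:
        fractions = (
            "hospital_stay_fraction",
            "health_centre_stay_fraction",
            "health_post_referral_fraction",
            "health_post_to_health_centre_split",
            "health_centre_onward_fraction",
        )
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidRecipeError(f"invalid recipe: {name}={v} outside [0, 1]")
        for name in (
            "hospital_stay_nights",
            "health_centre_stay_nights",
            "transport_km",
            "severe_pph_extra_cost",
        ):
            if getattr(self, name) < 0:
                raise InvalidRecipeError(f"invalid recipe: {name} must be >= 0")
        if self.blood_units_per_transfusion < 1:
            raise InvalidRecipeError(
                "invalid recipe: blood_units_per_transfusion must be >= 1"
            )


@dataclass(frozen=True)
class CostBreakdown:
    """Drug-prevention and PPH-treatment cost components for one strategy."""

    prophylaxis_drug_cost: float
    pph_treatment_cost: float

    @property
    def total(self) -> float:
        return self.prophylaxis_drug_cost + self.pph_treatment_cost


@dataclass(frozen=True)
class IncrementalCost:
    """Componentwise cost differences, intervention minus comparator."""

    drug: float
    treatment: float

    @property
    def total(self) -> float:
        return self.drug + self.treatment

    @property
    def reported(self) -> dict[str, int]:
        return {
            "drug": round_half_away_from_zero(self.drug),
            "treatment": round_half_away_from_zero(self.treatment),
            "total": round_half_away_from_zero(self.total),
        }


def _per_dose_cost(
    prophylaxis: str, costs: UnitCostTable, doses: DoseSchedule, bound: str
) -> float:
    if prophylaxis == "none":
        return 0.0
    if prophylaxis == "oxytocin":
        dose = costs.get("oxytocin_10iu", bound)
        if doses.include_syringe_in_prophylaxis:
            dose += costs.get("syringe", bound)
        return dose
    if prophylaxis == "misoprostol":
        return doses.misoprostol_tablets_per_dose * costs.get(
            "misoprostol_200ug", bound
        )
    raise InvalidParameterError(f"unknown prophylaxis {prophylaxis!r}")


def prophylaxis_cost(
    strategy: Strategy,
    cohort_size: float,
    mix: SettingMix,
    costs: UnitCostTable,
    doses: DoseSchedule = DoseSchedule(),
    bound: str = "point",
) -> float:
    """Drug cost of offering prophylaxis to every birth, summed over settings."""
    return cohort_size * mix.hospital_fraction * _per_dose_cost(
        strategy.hospital_prophylaxis, costs, doses, bound
    ) + cohort_size * mix.community_fraction * _per_dose_cost(
        strategy.community_prophylaxis, costs, doses, bound
    )


def _bundle_cost(recipe: TreatmentRecipe, costs: UnitCostTable, bound: str) -> float:
    total = 0.0
    if recipe.bundle_oxytocin:
        total += costs.get("oxytocin_10iu", bound)
    if recipe.bundle_syringe:
        total += costs.get("syringe", bound)
    if recipe.bundle_iv_fluids:
        total += costs.get("iv_fluids", bound)
    if recipe.bundle_infusion_set:
        total += costs.get("infusion_set", bound)
    return total


def per_case_treatment_cost(
    setting: str,
    recipe: TreatmentRecipe,
    costs: UnitCostTable,
    bound: str = "point",
) -> float:
    """Expected treatment cost of one PPH case originating in ``setting``.

    A hospital-origin case is the treatment bundle plus the expected inpatient
    stay. A community-origin case is the bundle, one emergency-transport leg
    from the health post, then the expected downstream cost of the referral
    split: the health-centre path contributes its own expected stay plus, for
    the fraction referred onward, a second transport leg and the hospital
    stay; the direct-hospital path contributes the hospital stay.
    """
    bundle = _bundle_cost(recipe, costs, bound)
    transport = recipe.transport_km * costs.get("transport_per_km", bound)
    hospital_stay = (
        recipe.hospital_stay_fraction
        * recipe.hospital_stay_nights
        * costs.get("overnight_hospital", bound)
    )
    if setting == "hospital":
        return bundle + hospital_stay
    if setting == "community":
        hc_stay = (
            recipe.health_centre_stay_fraction
            * recipe.health_centre_stay_nights
            * costs.get("overnight_health_centre", bound)
        )
        hc_path = hc_stay + recipe.health_centre_onward_fraction * (
            transport + hospital_stay
        )
        split = recipe.health_post_to_health_centre_split
        downstream = recipe.health_post_referral_fraction * (
            transport + split * hc_path + (1.0 - split) * hospital_stay
        )
        return bundle + downstream
    raise InvalidParameterError(f"setting must be 'hospital' or 'community', got {setting!r}")


def treatment_cost(
    cohort: CohortResult,
    recipe: TreatmentRecipe,
    costs: UnitCostTable,
    bound: str = "point",
    multiplier: float = 1.0,
) -> float:
    """Expected PPH treatment cost for one strategy's cohort result.

    Linear in every event count: PPH cases carry the per-case cascade cost of
    their origin setting; additional-uterotonic cases an oxytocin + syringe
    bundle; transfusion cases the configured blood units plus a giving set;
    severe PPH the configured extra cost (0 by default — the cascade already
    prices the haemorrhage case itself). ``multiplier`` scales the whole
    treatment side (the 50 %/200 % sensitivity lever).
    """
    if multiplier < 0:
        raise InvalidParameterError("multiplier must be >= 0")
    pph = cohort.counts[Outcome.PPH]
    cost = pph.hospital * per_case_treatment_cost("hospital", recipe, costs, bound)
    cost += pph.community * per_case_treatment_cost("community", recipe, costs, bound)
    uterotonic_bundle = costs.get("oxytocin_10iu", bound) + costs.get("syringe", bound)
    cost += cohort.total(Outcome.ADDITIONAL_UTEROTONICS) * uterotonic_bundle
    transfusion_cost = recipe.blood_units_per_transfusion * (
        costs.get("blood_unit", bound) + costs.get("blood_giving_set", bound)
    )
    cost += cohort.total(Outcome.BLOOD_TRANSFUSION) * transfusion_cost
    cost += cohort.total(Outcome.SEVERE_PPH) * recipe.severe_pph_extra_cost
    return multiplier * cost


def total_and_incremental_cost(
    intervention: CostBreakdown, comparator: CostBreakdown
) -> IncrementalCost:
    """Componentwise cost differences; incremental total = drug + treatment."""
    return IncrementalCost(
        drug=intervention.prophylaxis_drug_cost - comparator.prophylaxis_drug_cost,
        treatment=intervention.pph_treatment_cost - comparator.pph_treatment_cost,
    )


def inflate_cost(amount: float, factor: float) -> float:
    """Scale a cost by an inflation factor (e.g. a CPI ratio)."""
    if factor <= 0:
        raise InvalidParameterError("inflation factor must be > 0")
    return amount * factor


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

def load_costs(path: str | None = None) -> UnitCostTable:
    """Load a unit-cost file; defaults to the packaged 2012 US$ table."""
    if path is None:
        text = resources.files("pphecon.data").joinpath("costs.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "unit_costs" not in doc:
        raise InvalidParameterError("cost file must have a 'unit_costs' mapping")
    items = {
        name: CostEstimate(**vals) for name, vals in doc["unit_costs"].items()
    }
    return UnitCostTable(items)


def load_recipe(path: str | None = None) -> tuple[TreatmentRecipe, DoseSchedule]:
    """Load a recipe/dose file; defaults to the packaged WHO-style recipe."""
    if path is None:
        text = resources.files("pphecon.data").joinpath("recipe.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text) or {}
    recipe = TreatmentRecipe(**doc.get("recipe", {}))
    doses = DoseSchedule(**doc.get("doses", {}))
    return recipe, doses
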