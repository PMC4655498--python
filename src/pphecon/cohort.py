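"""Deterministic cohort event engine.

A prophylaxis strategy assigns one of {oxytocin, misoprostol, none} to each of
two birth settings (hospital/health centre vs community). For every outcome
the expected number of events among ``n`` births is the closed-form product

    births_in_setting x baseline_rate x relative_risk

with the baseline and relative risk resolved per prophylaxis option:
no treatment and oxytocin use their own observed baseline rates (RR = 1),
while misoprostol is anchored to the placebo baseline multiplied by the
misoprostol-vs-placebo relative risk in both settings. All arithmetic stays
unrounded; integers exist only in reports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .errors import (
    IncomparableResultsError,
    InvalidParameterError,
)
from .evidence import OUTCOMES, EvidenceSet, Outcome

__all__ = [
    "PROPHYLAXIS_OPTIONS",
    "SettingMix",
    "Strategy",
    "StrategyPair",
    "OutcomeCount",
    "CohortResult",
    "IncrementalResult",
    "round_half_away_from_zero",
    "expected_events",
    "resolve_cell",
    "evaluate_strategy",
    "incremental_outcomes",
]

PROPHYLAXIS_OPTIONS = ("oxytocin", "misoprostol", "none")

_MIX_TOL = 1e-12


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, ties away from zero (-3.648 -> -4)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class SettingMix:
    """Fractions of births in the hospital/health-centre vs community setting."""

    hospital_fraction: float
    community_fraction: float

    def __post_init__(self) -> None:
        for name in ("hospital_fraction", "community_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if abs(self.hospital_fraction + self.community_fraction - 1.0) > _MIX_TOL:
            raise InvalidParameterError(
                "hospital_fraction + community_fraction must equal 1"
            )

    @classmethod
    def from_hospital(cls, hospital_fraction: float) -> "SettingMix":
        return cls(hospital_fraction, 1.0 - hospital_fraction)


@dataclass(frozen=True)
class Strategy:
    """Prophylaxis assignment per setting."""

    hospital_prophylaxis: str
    community_prophylaxis: str

    def __post_init__(self) -> None:
        for name in ("hospital_prophylaxis", "community_prophylaxis"):
            v = getattr(self, name)
            if v not in PROPHYLAXIS_OPTIONS:
                raise InvalidParameterError(
                    f"{name} must be one of {PROPHYLAXIS_OPTIONS}, got {v!r}"
                )

    def label(self) -> str:
        return f"{self.hospital_prophylaxis}/{self.community_prophylaxis}"


@dataclass(frozen=True)
class StrategyPair:
    """An intervention/comparator pair evaluated on one shared cohort."""

    intervention: Strategy
    comparator: Strategy
    cohort_size: int = 1000
    mix: SettingMix = SettingMix(0.4, 0.6)
    evidence_source: str = "tuncalp2012"
    rr_bound: str = "point"

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise InvalidParameterError("cohort_size must be >= 1")


@dataclass(frozen=True)
class OutcomeCount:
    """Unrounded expected event counts for one outcome, by setting."""

    hospital: float
    community: float

    @property
    def total(self) -> float:
        return self.hospital + self.community


@dataclass(frozen=True)
class CohortResult:
    """Expected event counts per outcome for one strategy over one cohort."""

    strategy: Strategy
    cohort_size: float
    mix: SettingMix
    counts: Mapping[Outcome, OutcomeCount]

    def total(self, outcome: Outcome) -> float:
        return self.counts[Outcome(outcome)].total

    def reported(self, outcome: Outcome) -> int:
        return round_half_away_from_zero(self.total(outcome))


@dataclass(frozen=True)
class IncrementalResult:
    """Per-outcome differences, intervention minus comparator.

    ``reported`` integers are formed by rounding the unrounded difference
    (never by differencing rounded scenario columns).
    """

    unrounded: Mapping[Outcome, float]

    @property
    def reported(self) -> dict[Outcome, int]:
        return {o: round_half_away_from_zero(v) for o, v in self.unrounded.items()}


def expected_events(n_births: float, baseline_rate: float, rr: float) -> float:
    """Expected events among ``n_births``: n x baseline_rate x rr, unclamped."""
    if n_births < 0:
        raise InvalidParameterError(f"invalid parameter: n_births={n_births} < 0")
    if not 0.0 <= baseline_rate <= 1.0:
        raise InvalidParameterError(
            f"invalid parameter: baseline_rate={baseline_rate} outside [0, 1]"
        )
    if rr <= 0:
        raise InvalidParameterError(f"invalid parameter: rr={rr} must be > 0")
    count = n_births * baseline_rate * rr
    if count > n_births:
        warnings.warn(
            f"expected count {count:.3f} exceeds births {n_births:.3f} "
            f"(rate {baseline_rate} x RR {rr} > 1)",
            RuntimeWarning,
            stacklevel=2,
        )
    return count


def resolve_cell(
    prophylaxis: str,
    outcome: Outcome,
    evidence: EvidenceSet,
    rr_bound: str = "point",
) -> tuple[float, float]:
    """Resolve one (setting, outcome) cell to its (baseline_rate, rr) pair.

    ``none`` -> placebo baseline, RR 1; ``oxytocin`` -> oxytocin baseline,
    RR 1; ``misoprostol`` -> placebo baseline times the misoprostol-vs-placebo
    RR at ``rr_bound``. Misoprostol is anchored to the placebo baseline in
    both settings — its effect is always expressed relative to no treatment,
    not to the oxytocin arm's baseline.
    """
    outcome = Outcome(outcome)
    if prophylaxis == "none":
        return evidence.rate("placebo", outcome, "point"), 1.0
    if prophylaxis == "oxytocin":
        return evidence.rate("oxytocin", outcome, "point"), 1.0
    if prophylaxis == "misoprostol":
        return (
            evidence.rate("placebo", outcome, "point"),
            evidence.rr("misoprostol_vs_placebo", outcome, rr_bound),
        )
    raise InvalidParameterError(
        f"prophylaxis must be one of {PROPHYLAXIS_OPTIONS}, got {prophylaxis!r}"
    )


def evaluate_strategy(
    strategy: Strategy,
    cohort_size: float,
    mix: SettingMix,
    evidence: EvidenceSet,
    rr_bound: str = "point",
) -> CohortResult:
    """Expected event counts for one strategy, per outcome and setting.

    Outcomes are marginal frequencies computed independently; a woman may
    contribute to several outcomes, as in the underlying trial reports.
    """
    n_hospital = cohort_size * mix.hospital_fraction
    n_community = cohort_size * mix.community_fraction
    counts: dict[Outcome, OutcomeCount] = {}
    for outcome in OUTCOMES:
        h_rate, h_rr = resolve_cell(
            strategy.hospital_prophylaxis, outcome, evidence, rr_bound
        )
        c_rate, c_rr = resolve_cell(
            strategy.community_prophylaxis, outcome, evidence, rr_bound
        )
        counts[outcome] = OutcomeCount(
            hospital=expected_events(n_hospital, h_rate, h_rr),
            community=expected_events(n_community, c_rate, c_rr),
        )
    return CohortResult(
        strategy=strategy, cohort_size=cohort_size, mix=mix, counts=counts
    )


def incremental_outcomes(
    intervention: CohortResult, comparator: CohortResult
) -> IncrementalResult:
    """Unrounded per-outcome differences between two strategies' results."""
    if (
        intervention.cohort_size != comparator.cohort_size
        or intervention.mix != comparator.mix
    ):
        raise IncomparableResultsError(
            "incomparable results: cohort size or setting mix differ"
        )
    return IncrementalResult(
        unrounded={
            o: intervention.total(o) - comparator.total(o) for o in OUTCOMES
        }
    )
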