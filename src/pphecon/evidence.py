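"""Epidemiological evidence: baseline event rates, relative risks, and
random-effects pooling of trial-level 2x2 tables.

The model tracks six maternal outcomes of uterotonic prophylaxis. Baseline
rates are frequencies under a reference exposure (placebo/no treatment, or
prophylactic oxytocin); relative risks compare oral misoprostol against those
references. Where a source review does not report a pooled relative risk,
:func:`pool_random_effects` reconstructs one from per-trial event counts with
the DerSimonian-Laird random-effects estimator on the log-RR scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .errors import (
    EvidenceIncompleteError,
    InvalidParameterError,
    UndefinedEffectError,
)

__all__ = [
    "Outcome",
    "OUTCOMES",
    "BOUNDS",
    "RateEstimate",
    "RelativeRiskEstimate",
    "EvidenceSet",
    "TrialTable",
    "PooledRR",
    "pool_random_effects",
    "get_rate",
    "get_rr",
    "merge_sources",
    "load_evidence",
    "read_trials_csv",
]


class Outcome(str, enum.Enum):
    """The six outcomes carried through the cost-consequences analysis."""

    PPH = "pph"
    SEVERE_PPH = "severe_pph"
    ADDITIONAL_UTEROTONICS = "additional_uterotonics"
    BLOOD_TRANSFUSION = "blood_transfusion"
    SHIVERING = "shivering"
    FEVER = "fever"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical outcome ordering used by every report layout.
OUTCOMES: tuple[Outcome, ...] = tuple(Outcome)

#: Valid bound selectors for rates, relative risks and unit costs.
BOUNDS = ("point", "low", "high")


def _check_bound(bound: str) -> None:
    if bound not in BOUNDS:
        raise InvalidParameterError(f"bound must be one of {BOUNDS}, got {bound!r}")


@dataclass(frozen=True)
class RateEstimate:
    """A baseline event proportion with optional lowest/highest trial bounds."""

    outcome: Outcome
    point: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        for name in ("point", "low", "high"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise InvalidParameterError(
                    f"{self.outcome}: rate {name}={v} outside [0, 1]"
                )
        if self.low is not None and self.low > self.point:
            raise InvalidParameterError(f"{self.outcome}: low > point")
        if self.high is not None and self.high < self.point:
            raise InvalidParameterError(f"{self.outcome}: high < point")

    def value(self, bound: str = "point") -> float:
        _check_bound(bound)
        v = getattr(self, bound)
        if v is None:
            raise EvidenceIncompleteError(
                f"evidence incomplete: {self.outcome} has no {bound!r} bound"
            )
        return v


@dataclass(frozen=True)
class RelativeRiskEstimate:
    """A relative risk (treatment vs reference) with 95 % CI limits."""

    outcome: Outcome
    comparison: str
    point: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.point <= 0:
            raise InvalidParameterError(f"{self.outcome}: RR point must be > 0")
        if self.low is not None and not 0 < self.low <= self.point:
            raise InvalidParameterError(f"{self.outcome}: RR low outside (0, point]")
        if self.high is not None and self.high < self.point:
            raise InvalidParameterError(f"{self.outcome}: RR high < point")

    def value(self, bound: str = "point") -> float:
        _check_bound(bound)
        v = getattr(self, bound)
        if v is None:
            raise EvidenceIncompleteError(
                f"evidence incomplete: {self.comparison}/{self.outcome} "
                f"has no {bound!r} bound"
            )
        return v


@dataclass(frozen=True)
class EvidenceSet:
    """All epidemiological inputs from one evidence source.

    ``baseline_rates`` maps a treatment context (``"placebo"`` or
    ``"oxytocin"``) to per-outcome :class:`RateEstimate`; ``relative_risks``
    maps a comparison label (``"misoprostol_vs_placebo"`` or
    ``"misoprostol_vs_oxytocin"``) to per-outcome
    :class:`RelativeRiskEstimate`. A source may omit whole contexts or
    comparisons (the home-birth source has no oxytocin arm), but any context
    or comparison it does carry must cover all six outcomes.
    """

    source_label: str
    baseline_rates: Mapping[str, Mapping[Outcome, RateEstimate]]
    relative_risks: Mapping[str, Mapping[Outcome, RelativeRiskEstimate]]

    def __post_init__(self) -> None:
        for context, rates in self.baseline_rates.items():
            missing = set(OUTCOMES) - set(rates)
            if missing:
                raise EvidenceIncompleteError(
                    f"evidence incomplete: {self.source_label}/{context} lacks "
                    f"{sorted(o.value for o in missing)}"
                )
        for comparison, rrs in self.relative_risks.items():
            missing = set(OUTCOMES) - set(rrs)
            if missing:
                raise EvidenceIncompleteError(
                    f"evidence incomplete: {self.source_label}/{comparison} lacks "
                    f"{sorted(o.value for o in missing)}"
                )

    def rate(self, context: str, outcome: Outcome, bound: str = "point") -> float:
        try:
            est = self.baseline_rates[context][Outcome(outcome)]
        except KeyError as exc:
            raise EvidenceIncompleteError(
                f"evidence incomplete: no baseline rate for "
                f"{self.source_label}/{context}/{outcome}"
            ) from exc
        return est.value(bound)

    def rr(self, comparison: str, outcome: Outcome, bound: str = "point") -> float:
        try:
            est = self.relative_risks[comparison][Outcome(outcome)]
        except KeyError as exc:
            raise EvidenceIncompleteError(
                f"evidence incomplete: no relative risk for "
                f"{self.source_label}/{comparison}/{outcome}"
            ) from exc
        return est.value(bound)


def get_rate(
    evidence: EvidenceSet, context: str, outcome: Outcome, bound: str = "point"
) -> float:
    """Look up a stored baseline event proportion, unchanged."""
    return evidence.rate(context, outcome, bound)


def get_rr(
    evidence: EvidenceSet, comparison: str, outcome: Outcome, bound: str = "point"
) -> float:
    """Look up a stored relative risk, unchanged."""
    return evidence.rr(comparison, outcome, bound)


def merge_sources(base: EvidenceSet, substitute: EvidenceSet) -> EvidenceSet:
    """Overlay one source's estimates on another's.

    Every baseline context and relative-risk comparison the substitute source
    carries replaces the base source's; contexts the substitute lacks (e.g. a
    home-birth review with no oxytocin arm) are retained from the base. This
    is what an evidence-source sensitivity substitution means for a model
    whose oxytocin arm would otherwise lose its baseline.
    """
    rates = dict(base.baseline_rates)
    rates.update(substitute.baseline_rates)
    rrs = dict(base.relative_risks)
    rrs.update(substitute.relative_risks)
    return EvidenceSet(
        source_label=f"{substitute.source_label}+{base.source_label}",
        baseline_rates=rates,
        relative_risks=rrs,
    )


# ---------------------------------------------------------------------------
# Evidence file loading
# ---------------------------------------------------------------------------

def _parse_source(label: str, node: Mapping) -> EvidenceSet:
    rates: dict[str, dict[Outcome, RateEstimate]] = {}
    for context, entries in node.get("baseline_rates", {}).items():
        rates[context] = {
            Outcome(name): RateEstimate(Outcome(name), **vals)
            for name, vals in entries.items()
        }
    rrs: dict[str, dict[Outcome, RelativeRiskEstimate]] = {}
    for comparison, entries in node.get("relative_risks", {}).items():
        rrs[comparison] = {
            Outcome(name): RelativeRiskEstimate(Outcome(name), comparison, **vals)
            for name, vals in entries.items()
        }
    return EvidenceSet(source_label=label, baseline_rates=rates, relative_risks=rrs)


def load_evidence(path: str | None = None) -> dict[str, EvidenceSet]:
    """Load an evidence file (YAML/JSON) into a registry of evidence sets.

    With no ``path``, the packaged defaults (the published review values the
    shipped base case uses) are loaded.
    """
    if path is None:
        text = (
            resources.files("pphecon.data").joinpath("evidence.yaml").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "sources" not in doc:
        raise EvidenceIncompleteError("evidence file must have a 'sources' mapping")
    return {
        label: _parse_source(label, node) for label, node in doc["sources"].items()
    }


# ---------------------------------------------------------------------------
# Random-effects pooling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialTable:
    """One trial's 2x2 binary-outcome table (treated vs control arms)."""

    trial_id: str
    events_treated: int
    n_treated: int
    events_control: int
    n_control: int

    def __post_init__(self) -> None:
        if self.n_treated <= 0 or self.n_control <= 0:
            raise InvalidParameterError(f"{self.trial_id}: arm sizes must be positive")
        if not 0 <= self.events_treated <= self.n_treated:
            raise InvalidParameterError(f"{self.trial_id}: treated events outside [0, n]")
        if not 0 <= self.events_control <= self.n_control:
            raise InvalidParameterError(f"{self.trial_id}: control events outside [0, n]")


@dataclass(frozen=True)
class PooledRR:
    """DerSimonian-Laird pooled relative risk with heterogeneity diagnostics.

    ``tau_squared`` is the between-trial variance on the log-RR scale and
    ``q_statistic`` Cochran's Q; ``continuity_corrected`` lists trials whose
    2x2 cells received the 0.5 continuity correction.
    """

    point: float
    low: float
    high: float
    tau_squared: float
    q_statistic: float
    k: int
    continuity_corrected: tuple[str, ...] = field(default=())


def _log_rr_and_variance(
    trial: TrialTable, continuity: float
) -> tuple[float, float, bool]:
    a, n1 = float(trial.events_treated), float(trial.n_treated)
    c, n2 = float(trial.events_control), float(trial.n_control)
    corrected = False
    if a == 0 or c == 0:
        # Haldane-Anscombe: add the correction to all four cells of this trial.
        a += continuity
        c += continuity
        n1 += 2 * continuity
        n2 += 2 * continuity
        corrected = True
    log_rr = math.log(a / n1) - math.log(c / n2)
    variance = 1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2
    return log_rr, variance, corrected


def pool_random_effects(
    trials: Sequence[TrialTable], continuity: float = 0.5
) -> PooledRR:
    """Pool per-trial relative risks with the DerSimonian-Laird estimator.

    Per trial the log relative risk and its large-sample variance
    ``1/a - 1/n1 + 1/c - 1/n2`` are formed; inverse-variance weights give
    Cochran's Q, the moment estimate
    ``tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))`` is added to
    each variance, and the re-weighted mean with a Wald 95 % interval is
    exponentiated back to the ratio scale.

    Trials with zero events in one arm receive the continuity correction on
    all four cells (and are flagged in the result); trials with zero events in
    both arms carry no information about a ratio and are dropped. If every
    trial is double-zero the effect is undefined.
    """
    if not trials:
        raise InvalidParameterError("at least one trial is required")
    if continuity <= 0:
        raise InvalidParameterError("continuity correction must be positive")

    informative = [
        t for t in trials if not (t.events_treated == 0 and t.events_control == 0)
    ]
    if not informative:
        raise UndefinedEffectError(
            "undefined effect: zero events in both arms of every trial"
        )

    stats_per_trial = [_log_rr_and_variance(t, continuity) for t in informative]
    y = np.array([s[0] for s in stats_per_trial])
    v = np.array([s[1] for s in stats_per_trial])
    corrected = tuple(
        t.trial_id for t, s in zip(informative, stats_per_trial) if s[2]
    )
    k = len(informative)

    w = 1.0 / v
    mu_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(math.sqrt(1.0 / np.sum(w_star)))
    z = stats.norm.ppf(0.975)
    return PooledRR(
        point=math.exp(mu),
        low=math.exp(mu - z * se),
        high=math.exp(mu + z * se),
        tau_squared=tau2,
        q_statistic=q,
        k=k,
        continuity_corrected=corrected,
    )


def read_trials_csv(path: str) -> list[TrialTable]:
    """Read trial 2x2 tables from a CSV with columns
    ``trial_id,events_treated,n_treated,events_control,n_control``."""
    import pandas as pd

    frame = pd.read_csv(path)
    required = [
        "trial_id",
        "events_treated",
        "n_treated",
        "events_control",
        "n_control",
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InvalidParameterError(f"trial CSV missing columns: {missing}")
    return [
        TrialTable(
            trial_id=str(row.trial_id),
            events_treated=int(row.events_treated),
            n_treated=int(row.n_treated),
            events_control=int(row.events_control),
            n_control=int(row.n_control),
        )
        for row in frame.itertuples(index=False)
    ]
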