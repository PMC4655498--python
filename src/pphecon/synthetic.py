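"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without external data:

* :func:`generate_trials` draws trial-level 2x2 tables under the standard
  random-effects data-generating process — per-trial log relative risks are
  normal around ``log(true_rr)`` with between-trial variance ``tau_squared``,
  and arm event counts are binomial — so DerSimonian-Laird pooling can be
  checked for parameter recovery and CI coverage.

* :func:`simulate_cohort` is the stochastic twin of the deterministic cohort
  engine: each birth draws every outcome independently as
  Bernoulli(baseline_rate x RR) in its setting, so replicate means must
  converge to the closed-form expectations at the Monte-Carlo rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import SettingMix, Strategy, resolve_cell
from .errors import InvalidParameterError, ProbabilityOverflowError
from .evidence import OUTCOMES, EvidenceSet, Outcome, TrialTable

__all__ = [
    "TrialGenSpec",
    "CohortSimSpec",
    "CohortSimResult",
    "generate_trials",
    "simulate_cohort",
]


@dataclass(frozen=True)
class TrialGenSpec:
    """Data-generating parameters for a set of synthetic trials."""

    true_rr: float
    k_trials: int
    n_per_arm: int
    control_risk: float
    seed: int
    tau_squared: float = 0.0

    def __post_init__(self) -> None:
        if self.true_rr <= 0:
            raise InvalidParameterError("true_rr must be > 0")
        if self.tau_squared < 0:
            raise InvalidParameterError("tau_squared must be >= 0")
        if self.k_trials < 1 or self.n_per_arm < 1:
            raise InvalidParameterError("k_trials and n_per_arm must be >= 1")
        if not 0.0 < self.control_risk < 1.0:
            raise InvalidParameterError("control_risk must be in (0, 1)")


def generate_trials(spec: TrialGenSpec) -> list[TrialTable]:
    """Draw ``k_trials`` 2x2 tables under a log-normal random-effects model.

    Per trial, ``theta_i ~ Normal(log(true_rr), tau_squared)`` sets the
    treated-arm risk ``control_risk * exp(theta_i)`` (clipped into (0, 1));
    event counts are binomial per arm. Deterministic given ``seed``. Warns
    when clipping touches more than 10 % of trials — the spec is then too
    close to the probability boundary for the nominal RR to be recoverable.
    """
    rng = np.random.default_rng(spec.seed)
    theta = rng.normal(
        np.log(spec.true_rr), np.sqrt(spec.tau_squared), size=spec.k_trials
    )
    treated_risk = spec.control_risk * np.exp(theta)
    eps = 1e-12
    clipped = (treated_risk >= 1.0) | (treated_risk <= 0.0)
    if clipped.mean() > 0.10:
        warnings.warn(
            "spec near boundary: treated-arm risk clipped in "
            f"{int(clipped.sum())}/{spec.k_trials} trials",
            RuntimeWarning,
            stacklevel=2,
        )
    treated_risk = np.clip(treated_risk, eps, 1.0 - eps)
    events_treated = rng.binomial(spec.n_per_arm, treated_risk)
    events_control = rng.binomial(
        spec.n_per_arm, spec.control_risk, size=spec.k_trials
    )
    return [
        TrialTable(
            trial_id=f"synthetic_{i + 1:02d}",
            events_treated=int(events_treated[i]),
            n_treated=spec.n_per_arm,
            events_control=int(events_control[i]),
            n_control=spec.n_per_arm,
        )
        for i in range(spec.k_trials)
    ]


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters for a person-level Bernoulli simulation of one strategy."""

    strategy: Strategy
    cohort_size: int
    mix: SettingMix
    n_replicates: int
    seed: int
    evidence_source: str = "tuncalp2012"
    rr_bound: str = "point"

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise InvalidParameterError("cohort_size must be >= 1")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")


@dataclass(frozen=True)
class CohortSimResult:
    """Replicate means and standard errors of event counts per outcome."""

    means: Mapping[Outcome, float]
    standard_errors: Mapping[Outcome, float]
    n_replicates: int
    births_hospital: int
    births_community: int


def simulate_cohort(spec: CohortSimSpec, evidence: EvidenceSet) -> CohortSimResult:
    """Simulate replicate cohorts of independent Bernoulli births.

    Every birth in a setting experiences each outcome independently with
    probability ``baseline_rate x RR`` for that setting's prophylaxis; the
    replicate total of each outcome is therefore binomial per setting, which
    is what is drawn. Probabilities above 1 are a hard error — the
    deterministic engine tolerates them with a warning, but no Bernoulli
    variable exists there.
    """
    n_hospital = int(round(spec.cohort_size * spec.mix.hospital_fraction))
    n_community = spec.cohort_size - n_hospital
    rng = np.random.default_rng(spec.seed)
    means: dict[Outcome, float] = {}
    ses: dict[Outcome, float] = {}
    for outcome in OUTCOMES:
        h_rate, h_rr = resolve_cell(
            spec.strategy.hospital_prophylaxis, outcome, evidence, spec.rr_bound
        )
        c_rate, c_rr = resolve_cell(
            spec.strategy.community_prophylaxis, outcome, evidence, spec.rr_bound
        )
        p_h, p_c = h_rate * h_rr, c_rate * c_rr
        for label, p in (("hospital", p_h), ("community", p_c)):
            if p > 1.0:
                raise ProbabilityOverflowError(
                    f"probability overflow: {outcome} {label} rate x RR = {p:.4f} > 1"
                )
        counts = rng.binomial(n_hospital, p_h, size=spec.n_replicates) + rng.binomial(
            n_community, p_c, size=spec.n_replicates
        )
        means[outcome] = float(np.mean(counts))
        ses[outcome] = float(
            np.std(counts, ddof=1) / np.sqrt(spec.n_replicates)
            if spec.n_replicates > 1
            else 0.0
        )
    return CohortSimResult(
        means=means,
        standard_errors=ses,
        n_replicates=spec.n_replicates,
        births_hospital=n_hospital,
        births_community=n_community,
    )
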