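"""Evidence lookups and DerSimonian-Laird random-effects pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pphecon import (
    EvidenceIncompleteError,
    InvalidParameterError,
    Outcome,
    TrialTable,
    UndefinedEffectError,
    get_rate,
    get_rr,
    merge_sources,
    pool_random_effects,
)

# ---------------------------------------------------------------------------
# Stored-input lookups
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    ("source", "context", "outcome", "bound", "expected"),
    [
        ("tuncalp2012", "placebo", Outcome.PPH, "point", 0.160),
        ("tuncalp2012", "oxytocin", Outcome.SHIVERING, "point", 0.060),
        ("hundley2013", "placebo", Outcome.FEVER, "point", 0.138),
        ("tuncalp2012", "placebo", Outcome.BLOOD_TRANSFUSION, "low", 0.005),
        ("tuncalp2012", "oxytocin", Outcome.FEVER, "high", 0.070),
    ],
)
def test_get_rate_returns_stored_value(
    evidence_registry, source, context, outcome, bound, expected
):
    assert get_rate(evidence_registry[source], context, outcome, bound) == expected


@pytest.mark.parametrize(
    ("source", "comparison", "outcome", "bound", "expected"),
    [
        ("tuncalp2012", "misoprostol_vs_placebo", Outcome.PPH, "point", 0.77),
        ("tuncalp2012", "misoprostol_vs_oxytocin", Outcome.FEVER, "point", 6.77),
        ("hundley2013", "misoprostol_vs_placebo", Outcome.SEVERE_PPH, "low", 0.04),
        ("tuncalp2012", "misoprostol_vs_placebo", Outcome.SHIVERING, "high", 3.39),
    ],
)
def test_get_rr_returns_stored_value(
    evidence_registry, source, comparison, outcome, bound, expected
):
    assert get_rr(evidence_registry[source], comparison, outcome, bound) == expected


def test_missing_context_signals_evidence_incomplete(hundley):
    with pytest.raises(EvidenceIncompleteError):
        get_rate(hundley, "oxytocin", Outcome.PPH)
    with pytest.raises(EvidenceIncompleteError):
        get_rr(hundley, "misoprostol_vs_oxytocin", Outcome.PPH)
    with pytest.raises(EvidenceIncompleteError):
        # Hundley baseline bounds were never calculated in the source review.
        get_rate(hundley, "placebo", Outcome.PPH, "low")


def test_merge_sources_overlays_substitute_and_keeps_missing_contexts(
    tuncalp, hundley
):
    merged = merge_sources(tuncalp, hundley)
    assert get_rate(merged, "placebo", Outcome.PPH) == 0.122
    assert get_rr(merged, "misoprostol_vs_placebo", Outcome.PPH) == 0.58
    # the home-birth source has no oxytocin arm: base values are retained
    assert get_rate(merged, "oxytocin", Outcome.PPH) == 0.124
    assert get_rr(merged, "misoprostol_vs_oxytocin", Outcome.FEVER) == 6.77


# ---------------------------------------------------------------------------
# DerSimonian-Laird pooling
# ---------------------------------------------------------------------------

# Step-by-step spreadsheet-style computation of the same formulas, frozen:
# three trials (12/120 vs 24/115), (30/300 vs 40/290), (5/80 vs 9/85) give
# Q = 1.0910698..., tau^2 truncates to 0, and the pooled log-RR is the
# fixed-effect inverse-variance mean.
HOMOGENEOUS_TRIALS = [
    TrialTable("t1", 12, 120, 24, 115),
    TrialTable("t2", 30, 300, 40, 290),
    TrialTable("t3", 5, 80, 9, 85),
]
HOMOGENEOUS_EXPECTED = {
    "point": 0.6292707105906448,
    "low": 0.44535552185281335,
    "high": 0.889135999840873,
    "q": 1.091069828930291,
    "tau2": 0.0,
}

# A deliberately heterogeneous set: (40/200 vs 20/200), (10/200 vs 30/200),
# (25/150 vs 25/150) gives Q = 17.0975... >> k-1 and tau^2 = 0.6089998...
HETEROGENEOUS_TRIALS = [
    TrialTable("h1", 40, 200, 20, 200),
    TrialTable("h2", 10, 200, 30, 200),
    TrialTable("h3", 25, 150, 25, 150),
]
HETEROGENEOUS_EXPECTED = {
    "point": 0.8967589039644075,
    "low": 0.3496040776506302,
    "high": 2.300249291265656,
    "q": 17.09753813051906,
    "tau2": 0.6089998224108069,
}


@pytest.mark.parametrize(
    ("trials", "expected"),
    [
        (HOMOGENEOUS_TRIALS, HOMOGENEOUS_EXPECTED),
        (HETEROGENEOUS_TRIALS, HETEROGENEOUS_EXPECTED),
    ],
    ids=["homogeneous", "heterogeneous"],
)
def test_pooling_matches_hand_computed_oracle(trials, expected):
    pooled = pool_random_effects(trials)
    assert math.log(pooled.point) == pytest.approx(
        math.log(expected["point"]), abs=1e-10
    )
    assert pooled.low == pytest.approx(expected["low"], abs=1e-10)
    assert pooled.high == pytest.approx(expected["high"], abs=1e-10)
    assert pooled.q_statistic == pytest.approx(expected["q"], abs=1e-10)
    assert pooled.tau_squared == pytest.approx(expected["tau2"], abs=1e-10)
    assert pooled.k == 3


def test_pooling_cross_checked_against_statsmodels():
    """Independent route: statsmodels' DL estimator on the same log-RRs.

    statsmodels does not truncate a negative moment estimate of tau^2, so the
    heterogeneous set (tau^2 > 0) checks the random-effects path directly and
    the homogeneous set (tau^2 truncated to 0) checks against statsmodels'
    fixed-effect estimate, which truncation makes the DL answer."""
    from statsmodels.stats.meta_analysis import combine_effects

    import warnings

    def _reference(trials):
        eff = np.array(
            [
                math.log(t.events_treated / t.n_treated)
                - math.log(t.events_control / t.n_control)
                for t in trials
            ]
        )
        var = np.array(
            [
                1 / t.events_treated
                - 1 / t.n_treated
                + 1 / t.events_control
                - 1 / t.n_control
                for t in trials
            ]
        )
        with warnings.catch_warnings():
            # statsmodels takes sqrt of its untruncated (possibly negative)
            # tau^2 internally; irrelevant to the estimates compared here
            warnings.simplefilter("ignore", RuntimeWarning)
            return combine_effects(eff, var, method_re="dl")

    het_ref = _reference(HETEROGENEOUS_TRIALS)
    het = pool_random_effects(HETEROGENEOUS_TRIALS)
    assert math.log(het.point) == pytest.approx(het_ref.mean_effect_re, abs=1e-10)
    assert het.tau_squared == pytest.approx(het_ref.tau2, abs=1e-10)

    hom_ref = _reference(HOMOGENEOUS_TRIALS)
    hom = pool_random_effects(HOMOGENEOUS_TRIALS)
    assert hom_ref.tau2 < 0  # statsmodels' untruncated moment estimate
    assert hom.tau_squared == 0.0
    assert math.log(hom.point) == pytest.approx(hom_ref.mean_effect_fe, abs=1e-10)


def test_single_trial_pooling_is_identity():
    """k=1: the pooled RR is that trial's RR with its own Wald interval."""
    pooled = pool_random_effects([TrialTable("only", 10, 100, 20, 100)])
    assert pooled.point == pytest.approx(0.5, abs=1e-12)
    se = math.sqrt(1 / 10 - 1 / 100 + 1 / 20 - 1 / 100)
    from scipy.stats import norm

    z = norm.ppf(0.975)
    assert pooled.low == pytest.approx(0.5 * math.exp(-z * se), rel=1e-12)
    assert pooled.high == pytest.approx(0.5 * math.exp(z * se), rel=1e-12)
    assert pooled.tau_squared == 0.0
    assert pooled.q_statistic == 0.0
    assert pooled.k == 1


def test_null_effect_pooling_near_one():
    """Trials generated with identical risks in both arms pool to RR ~ 1."""
    rng = np.random.default_rng(7)
    trials = [
        TrialTable(
            f"null{i}",
            int(rng.binomial(20000, 0.15)),
            20000,
            int(rng.binomial(20000, 0.15)),
            20000,
        )
        for i in range(3)
    ]
    pooled = pool_random_effects(trials)
    assert abs(math.log(pooled.point)) < 0.05
    assert pooled.tau_squared < 0.01


def test_fixed_effect_equivalence_when_tau2_truncates():
    """With Q <= k-1 the DL estimate equals the fixed-effect IV estimate."""
    pooled = pool_random_effects(HOMOGENEOUS_TRIALS)
    y = np.array(
        [
            math.log(t.events_treated / t.n_treated)
            - math.log(t.events_control / t.n_control)
            for t in HOMOGENEOUS_TRIALS
        ]
    )
    w = 1.0 / np.array(
        [
            1 / t.events_treated
            - 1 / t.n_treated
            + 1 / t.events_control
            - 1 / t.n_control
            for t in HOMOGENEOUS_TRIALS
        ]
    )
    fixed = float(np.sum(w * y) / np.sum(w))
    assert pooled.tau_squared == 0.0
    assert math.log(pooled.point) == pytest.approx(fixed, abs=1e-12)


@given(permutation=st.permutations(range(3)))
@settings(deadline=None, derandomize=True)
def test_pooling_invariant_to_trial_ordering(permutation):
    shuffled = [HETEROGENEOUS_TRIALS[i] for i in permutation]
    a = pool_random_effects(HETEROGENEOUS_TRIALS)
    b = pool_random_effects(shuffled)
    assert b.point == pytest.approx(a.point, rel=1e-12)
    assert b.tau_squared == pytest.approx(a.tau_squared, rel=1e-12)
    assert b.q_statistic == pytest.approx(a.q_statistic, rel=1e-12)


def test_zero_cell_continuity_correction_is_recorded():
    trials = [
        TrialTable("clean", 12, 120, 24, 115),
        TrialTable("zero", 0, 50, 5, 50),
    ]
    pooled = pool_random_effects(trials)
    assert pooled.continuity_corrected == ("zero",)
    # corrected trial contributes log((0.5/51)/(5.5/51))
    corrected_rr = (0.5 / 51) / (5.5 / 51)
    assert corrected_rr < pooled.point < 12 / 120 / (24 / 115) * 1.01


def test_double_zero_trials_are_dropped_and_all_double_zero_is_undefined():
    informative = TrialTable("info", 10, 100, 20, 100)
    double_zero = TrialTable("dz", 0, 50, 0, 50)
    pooled = pool_random_effects([informative, double_zero])
    assert pooled.k == 1
    assert pooled.point == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(UndefinedEffectError):
        pool_random_effects([double_zero])


def test_pooling_input_validation():
    with pytest.raises(InvalidParameterError):
        pool_random_effects([])
    with pytest.raises(InvalidParameterError):
        pool_random_effects([TrialTable("t", 1, 10, 1, 10)], continuity=0.0)
    with pytest.raises(InvalidParameterError):
        TrialTable("bad", 11, 10, 1, 10)
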