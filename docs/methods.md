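# Methods

## Model structure and assumptions

The engine is a deterministic cohort expectation model, not a microsimulation
or Markov model. A cohort of `N` births is split into a hospital/health-centre
fraction and a community fraction; each setting has exactly one prophylaxis
option (oxytocin, oral misoprostol, or none). For each of six outcomes — PPH
(blood loss ≥ 500 mL), severe PPH (≥ 1000 mL), additional uterotonic use,
blood transfusion, shivering, fever — the expected count in a setting is

    births × baseline_rate × RR.

Assumptions this encodes:

* **Outcomes are independent marginal frequencies.** A woman can count toward
  both PPH and shivering; no joint distribution or mutual exclusivity is
  modelled. Increments are therefore valid per outcome but cannot be summed
  into "women affected".
* **Misoprostol is anchored to the placebo baseline in both settings**
  (placebo rate × misoprostol-vs-placebo RR), never to the oxytocin baseline.
  Each strategy is expressed relative to its own reference arm; the
  misoprostol-vs-oxytocin RR set is stored and exposed for user-defined
  comparisons but is not used by any shipped scenario.
* **No clamping.** `rate × RR` can exceed 1 for extreme sensitivity bounds
  (e.g. the home-birth fever RR upper limit of 12.09 on a 13.8 % baseline);
  the deterministic engine keeps the algebraic value and emits a warning,
  because the reference analyses print such values unclamped. The stochastic
  simulator refuses the same input (no Bernoulli probability exists).
* **No time dimension.** Single delivery episode, no discounting, no
  mortality, no quality-of-life weighting.

All computation is unrounded; integers exist only in reports, via
round-half-away-from-zero. That convention is observable in the shipped base
case: the transfusion increment is −3.648, reported −4, whereas differencing
the rounded scenario columns (6 − 9) would give −3.

## Evidence inputs

The packaged evidence file carries two sources: a mixed hospital/community
systematic-review set (placebo and oxytocin baseline rates, plus
misoprostol-vs-placebo and misoprostol-vs-oxytocin RRs with 95 % CIs) and a
home-birth review set (placebo baselines and misoprostol-vs-placebo RRs only —
it has no oxytocin arm). Baseline "low/high" are the lowest/highest
single-trial estimates, RR low/high are CI limits; selection among
point/low/high is a `bound` argument everywhere.

An evidence-source sensitivity substitution overlays the substitute source on
the base source: contexts and comparisons the substitute carries replace the
base's, contexts it lacks (the oxytocin arm) are retained. In the shipped
comparison the retained oxytocin arm is shared by intervention and comparator
and cancels from every increment, so the overlay changes only what the
substitute actually measured.

## Random-effects pooling

`pool_random_effects` is DerSimonian–Laird on the log-RR scale, the
conventional reading of "random-effects meta-analysis" for binary relative
risks: per-trial variance `1/a − 1/n₁ + 1/c − 1/n₂`, inverse-variance weights,
Cochran's Q, moment estimator `τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`,
re-weighting by `1/(vᵢ + τ²)`, Wald 95 % CI with `z = Φ⁻¹(0.975)`.

Numerical choices:

* `k = 1` short-circuits to τ² = 0, Q = 0 (the denominator of the moment
  estimator is degenerate); pooling is then exactly the single trial's RR and
  Wald CI.
* Zero events in one arm: Haldane–Anscombe correction, +0.5 to all four cells
  of that trial only; corrected trials are recorded on the result object.
* Zero events in both arms: the trial carries no information about a ratio
  and is dropped; if every trial is double-zero the effect is undefined and a
  `UndefinedEffectError` is raised.
* τ² is truncated at zero (so under observed homogeneity DL coincides with
  the fixed-effect estimate). Note statsmodels' `combine_effects` reports the
  untruncated moment estimate; the test suite uses it as an independent
  cross-check with that difference accounted for.

## Costing

Money is represented as plain floats in model currency (2012 US$ in the
shipped tables). Event counts are real-valued person-equivalents, so cost
arithmetic is float regardless; at the model's magnitudes (≤ 10⁴ dollars,
unit costs with ≤ 4 decimals) float error is ~10⁻¹² dollars against a
whole-dollar reporting precision. Whole-dollar rounding happens only in
reports.

Prophylaxis: oxytocin 10 iU at its ampoule price (the administration syringe
is excluded by default — the published drug-cost column matches
400 × $0.2184 = $87.36, not the syringe-inclusive $115.36 — but is a
`DoseSchedule` flag); misoprostol 3 × 200 µg tablets; none, zero.

Treatment per PPH case, default recipe (the WHO Mother-Baby-Package referral
conventions, with unprinted quantities as explicit config):

| parameter | default | note |
|---|---|---|
| treatment bundle | oxytocin + syringe + IV fluids + infusion set | $2.3984 at point prices |
| hospital stay | 50 % of cases × 7 nights | hospital-origin and referred cases |
| health-centre stay | 50 % of cases × 2 nights | |
| health-post referral | 100 %, split 50/50 health centre / hospital | community cases |
| health-centre onward referral | 50 % to hospital | second transport leg |
| transport distance | 10 km per leg | not printed anywhere; config |
| blood units per transfusion | 1 (+ giving set) | config |
| severe-PPH extra cost | $0 | hook for unmodelled cost structure |

With point prices this gives $14.5434 per hospital-origin case and $17.32715
per community-origin case. The reference analysis never printed its per-case
formula, and its four treatment-cost totals cannot be reproduced
simultaneously from the printed unit costs under any single recipe we could
construct — so the engine reproduces event counts and drug costs exactly,
while treatment totals are honest functions of this documented recipe and are
asserted structurally (linearity, zero-at-zero, monotonicity, the
total = drugs + treatment identity), not against the printed dollar figures.

A drug-price sensitivity substitution reprices both uterotonics in the unit
cost table, so the treatment-phase oxytocin moves together with the
prophylactic dose. This was a genuinely open choice; the reference analysis's
"lower drug cost" row differs from prophylaxis-only repricing in the
direction this choice predicts.

## Synthetic data generators

`generate_trials` draws per-trial effects θᵢ ~ Normal(log RR, τ²) — the
standard log-normal random-effects data-generating process — sets the treated
risk to `control_risk · exp(θᵢ)` (clipped into (0,1), warning when clipping
touches > 10 % of trials), and draws binomial arm counts. Defaults in tests
mirror the evidence the model consumes (control risk 0.16, RR 0.77 — the PPH
cell). `simulate_cohort` draws each outcome for each birth independently as
Bernoulli(rate × RR), realised as per-setting binomials, and returns replicate
means and standard errors.

What a green test establishes: the deterministic engine equals the expectation
of the stated person-level stochastic model, and the pooling routine recovers
a known RR from data generated under its own assumptions. What it does not:
correlated outcomes within a woman, over-dispersion between facilities,
referral behaviour at person level, or any fidelity of the evidence tables to
the world — those are inputs.

## Tolerances and test design

* Closed-form results (event counts, drug costs, increments) are asserted to
  1e−9 absolute or exactly as integers.
* DL pooling is asserted to 1e−10 on the log scale against a frozen
  step-by-step hand computation, and cross-checked against statsmodels.
* Parameter recovery: |log pooled − log true| < 0.05 at 10 trials ×
  50 000/arm; CI coverage ≥ 90/100 seeded repetitions at true RR 1.
* Monte-Carlo oracle: every outcome within 3 standard errors at 200
  replicates × 1000 births (≈ 1 in 370 per-outcome false-alarm rate per
  fixed seed; seeds are pinned).

## Known limitations

* Cost conclusions are conditional on the treatment recipe; only the event
  and drug-cost sides are recipe-free.
* The six outcomes share no joint model, so no "total adverse events" column
  is meaningful.
* One-way sensitivity only; no probabilistic (Monte-Carlo) sensitivity
  analysis over the full parameter space.
* The evidence tables are consumed as given; the package does not re-derive
  the published pooled RRs from trial-level data (those 2×2 tables were never
  published), it only provides the pooling machinery used to fill gaps.
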