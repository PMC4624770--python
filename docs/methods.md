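# Methods

## Model structure

`sadcea` evaluates 28 interventions for adult social anxiety disorder with a
hybrid cohort model: a decision tree covering 12 weeks of initial treatment
plus the first post-treatment year, followed by a two-state Markov model run
in annual cycles for post-treatment years 2 onward (4 cycles at the default
5-year horizon). The two health states are 'no social anxiety disorder'
(recovered/well) and 'social anxiety disorder' (ill). Parameter uncertainty
is cohort-level: one joint draw applies to the whole cohort per PSA
iteration; there is no individual-level microsimulation, no treatment
switching after non-response, and no re-recovery within the first year after
an early relapse (the year-1 relapse is a tree branch, not a cycle).

### Decision tree

At the end of treatment a fraction `p_recover` (one draw from the recovery
posterior) moves to the well state. Recoverers face one relapse opportunity
during the first post-treatment year:

| relapse class | probability | construction |
|---|---|---|
| drug (all pharmacological arms and pill placebo) | 0.4169 | midpoint of two pooled beta risks, Beta(107, 293) and Beta(222, 170) |
| psychological (all psychological arms incl. self-help) | 0.139 | drug relapse ÷ relapse risk ratio (3.0; log-normal with 95% CI 0.73–12.39 in the PSA), clipped to [0, 1] |
| wait list | 0.0409 | annualised years-2–5 relapse (see below); configurable via `relapse_waitlist_y1` — the source evaluation derived it from the same naturalistic study but never reports the number |

### Markov years

Annual transition probabilities for all cohorts, regardless of initial
treatment: recovery 0.0377 and relapse 0.0409, obtained from 12-year
probabilities (Beta(65, 111) and Beta(26, 40) in the PSA) under a constant
hazard: `p_annual = 1 − (1 − p_12yr)^(1/12)`. This conversion is chosen
because it reproduces both published annual values exactly at 4 decimals.

## Timing conventions

The published account of the model leaves the within-year timing open; the
following are this package's choices, fixed before any comparison with the
published cost/QALY table and then checked against it:

* **Horizon clock.** The decision tree spans the 12 treatment weeks plus a
  full 52-week post-treatment year; total model time is 12/52 + 5 years at
  the default horizon. The alternative reading (decision tree = one calendar
  year including treatment) understates the published wait-list QALY total
  by almost exactly `u_ill × 12/52`, so the full-year reading is used.
* **Utility paths.** Utilities change linearly on transition: recoverers
  ramp 0.659 → 0.866 across the treatment weeks (trapezoid integration);
  non-recoverers stay at 0.659. Year-1 relapsers are credited the average of
  the two state utilities over the post-treatment year, the expected value
  under a uniformly distributed relapse time; their state costs are split
  50/50 the same way.
* **State costs** (£645/year well, £1,037/year ill; gamma-distributed in the
  PSA) start at the end of treatment week 12 — none accrue during treatment,
  whose costs are carried entirely by the intervention cost, avoiding double
  counting.
* **Discounting** is annual at 3.5% for both costs and QALYs. The decision
  tree is undiscounted; Markov cycle *k* (post-treatment year *k* + 1)
  carries the factor `(1 + r)^−k`.
* **Half-cycle correction** credits each Markov cycle at the mean of its
  start and end state occupancy (intervention costs all fall in the decision
  tree and are not corrected).
* The **fraction well at horizon** is read after the final cycle's
  transition, before any correction averaging.

At published point estimates these conventions reproduce the published
probabilistic means closely (wait list: 3.369 QALYs / £4,590 / 20.30% well
versus the published 3.37 / £4,593 / 20.43%), though exact agreement is not
expected: the original posterior draws are unavailable and the original
timing conventions are unstated.

## Synthetic recovery posterior

The model consumes a joint posterior of end-of-treatment recovery
probabilities across the 28 arms. Only per-arm marginals (mean, median, 95%
credible interval) are published, so the package generates a calibrated
stand-in:

    logit(p_k) = b + d_k,  b ~ N(−2.629, 1.235),  d_k ~ N(μ_k, σ_k²)

* `b` is the wait-list baseline log-odds of recovery, drawn **once per
  iteration and shared across arms** — the only source of cross-arm
  correlation. The true posterior also correlates the treatment effects
  themselves; those correlations are unpublished, so effects are sampled
  independently. This reproduces every published marginal and the
  baseline-driven dependence, but cross-arm rank probabilities (e.g. CEAF
  probabilities) inherit only the baseline-induced correlation.
* `μ_k = logit(median_k) − (−2.629)`: the logit is monotone, so the median
  maps exactly.
* `σ_k² = ((logit(hi_k) − logit(lo_k))/3.92)² − 1.235`, floored at zero when
  the published interval is narrower than the baseline implies (one arm,
  supported internet self-help, is floored). The wait-list arm is pinned to
  the exact null effect (0, 0).

The published means are then a free check: at 10⁵ draws all 28 column means
fall within ±0.012 of the published values (Gauss–Hermite quadrature of the
logistic-normal mean puts the analytic discrepancy below ±0.009, driven by
the 2-decimal rounding of the published medians and intervals).

A conversion between standardised mean differences and recovery log-odds
ratios (`LOR = −(π/√3)·SMD`) is provided for users supplying SMD-scale
effects; the default pipeline calibrates directly from the probability-scale
summaries and does not need it.

What the generator does **not** emulate: between-arm effect correlations
beyond the shared baseline (see above), any skew or heavy tails the true
posterior may have on the logit scale, and the sampling error of the original
MCMC run. Tests passing against this generator therefore validate the
economic model and decision layer, not the original evidence synthesis.

## Costing

2015 prices throughout. Drug arms: acquisition cost for 12 initial weeks
plus, for recoverers only, 26 maintenance weeks; 4 + 3 GP visits at £46.75.
In the PSA the GP visit counts are categorical (initial: 65% 4 visits, 10%
spread over 3/5/6, 25% over 1/2; maintenance: 55% 3 visits, 45% over
0/1/2/4 — quoted group masses are split equally within their value sets) and
are shared across all drug arms within an iteration. Contingencies: one
initial visit ⇒ half the 12-week acquisition cost; fewer than three initial
visits ⇒ no maintenance; zero maintenance visits ⇒ no 26-week acquisition
cost. The published drug totals embed a GP component of £327.27 while their
own footnote prices 7 × £46.75 = £327.25; the package uses the stated unit
cost exactly and treats the 2p gap as upstream rounding.

Psychological arms bill therapist time at £110/h (Band 7) plus a GP referral
visit. Individual therapies scale with attended sessions (categorical
distributions per arm; the first session of the Hope programme runs 90
minutes instead of 60); group therapies cost the full course regardless of
attendance (sessions run and empty seats are not refilled); self-help bills
therapist contact minutes — normal with SD = 0.3 × mean, truncated at zero —
plus consumables (book £20.66; internet: £14,000/year hosting over 30 users
plus £13 hardware/overheads). Recomputed component sums may differ from the
published per-person totals by £1–3 (e.g. £2,356.75 versus the published
£2,359); these are treated as upstream rounding of the therapist unit cost.

All amounts are carried at full precision; rounding to whole pounds happens
only in report writers.

## Probabilistic analysis and decision layer

10,000 iterations by default. A master seed (numpy `SeedSequence`) spawns one
substream for posterior generation and one for parameter draws, so results
are bit-reproducible and independent of how the posterior was produced.
Within an iteration every arm is evaluated under the same draw (common random
numbers); iteration-global quantities are drawn before per-arm resource
draws (sorted by arm id), so excluding drug arms from a run leaves every
other arm's results bit-identical.

Net monetary benefit uses λ = £20,000/QALY by default. The incremental
analysis removes absolutely dominated arms, then extendedly dominated arms by
the standard increasing-ICER sweep; ties are deterministic (equal QALYs → the
cheaper arm; full ties collapse to the lexicographically first id). The CEAF
grid is £0–£50,000 in £250 steps; per threshold it reports the arm with the
highest mean NMB and the fraction of iterations in which that arm has the
highest NMB, splitting iteration-level ties equally.

## Scenario analyses

Packaged deterministic/probabilistic scenarios: (1) self-help supported by a
Band 5 therapist (£87/h) and groups run by one Band 7 + one Band 6 therapist
(blended £101.50 per therapist-hour); (2) utilities 0.79 (ill) / 0.91 (well),
replacing the PSA betas by point masses; (3) post-treatment horizons of 1, 3
and 10 years (0, 2 and 9 Markov cycles); (4) fixed relapse risk ratios 1.0,
1.15, 1.5 and 2.0 in place of the log-normal. Scenario application is pure:
base parameters and packaged profiles are never mutated.

## Numerical choices and problem sizes

* Log-normal parameters from a reported mean + 95% CI: log-SD =
  (ln hi − ln lo)/3.92, log-mean = midpoint of the log CI (≈ ln 3.007 for the
  relapse risk ratio, versus the reported 3.00 kept as the deterministic
  point value).
* Gamma parameters by method of moments: shape = (mean/SE)², scale =
  SE²/mean.
* Point estimates use published values even where a stated distribution's
  mean differs slightly (ill-state utility 0.659 versus the Beta(40, 20)
  mean of 0.667): deterministic runs use 0.659, the PSA samples the stated
  beta.
* `expit` saturates beyond |x| ≈ 37; posterior draws are clipped to the open
  unit interval at the floating-point boundary.
* The test suite uses reduced problem sizes (2,000-draw shared posterior,
  60–1,000-iteration PSA runs, 10⁵ draws for the calibration checks) chosen
  so Monte-Carlo checks sit at least 3 standard errors inside their
  tolerances; every stochastic test is seeded and therefore deterministic.

## Known limitations

* Drug side effects, productivity losses and treatment switching are outside
  the model, as in the source evaluation.
* The published probabilistic means cannot be reproduced exactly (original
  posterior draws and timing conventions unavailable); agreement is close
  but validation of the decision layer against the published table uses the
  published means as inputs rather than regenerated ones.
* The wait-list year-1 relapse probability is a modelling default (the
  annualised years-2–5 value), not a published number.
* Utilities come from survey respondents with and without mental disorder,
  not from state-specific elicitation; costs derive from a 1993–94 service
  use survey inflated to 2015 — both caveats carry over from the source data.
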