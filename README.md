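# sadcea

Cost-utility modelling of psychological and pharmacological interventions for
adult social anxiety disorder.

Social anxiety disorder is a common, persistent anxiety disorder with many
candidate first-line treatments — SSRIs/SNRIs, MAOIs, individually delivered
and group cognitive behavioural therapies, and guided or unguided self-help.
`sadcea` implements a decision-analytic model that compares 28 such
interventions (including pill placebo and wait list) on costs and
quality-adjusted life years (QALYs) from the perspective of the British NHS
and personal social services, for health economists and guideline developers
who want a tested, reusable, fully scriptable version of this evaluation.

## The model

Each intervention's cohort passes through a hybrid structure:

* **Decision tree (12 weeks of treatment + first post-treatment year).**
  A fraction *p* recovers at end of treatment (leaving the
  'social anxiety disorder' state); recoverers may relapse once during the
  first year, with relapse probability 0.4169 for drugs, 0.4169 / RR
  (RR = 3.0) for psychological therapies, and the annualised naturalistic
  estimate for wait list.
* **Two-state Markov model (post-treatment years 2–5).** Annual cycles
  between 'no social anxiety disorder' and 'social anxiety disorder' with
  common annual recovery (0.0377) and relapse (0.0409) probabilities,
  half-cycle correction and 3.5%/year discounting.

QALYs use utilities 0.866 (well) / 0.659 (ill) with linear transitions;
state costs are £645 / £1,037 per year; intervention costs combine drug
acquisition, GP visits (£46.75) and Band 7 therapist time (£110/h).

The evidence input is the joint posterior of end-of-treatment recovery
probabilities from a network meta-analysis. Because only marginal summaries
of that posterior are published, `sadcea` reconstructs a calibrated stand-in:
`logit(p_k) = b + d_k` with a shared wait-list baseline
`b ~ N(−2.629, 1.235)` and per-arm effects `d_k ~ N(μ_k, σ_k²)` calibrated so
the implied marginals match the published medians and 95% credible
intervals. A user-supplied draw matrix (CSV) can replace the synthetic
posterior.

A 10,000-iteration probabilistic sensitivity analysis propagates every input
distribution (beta, gamma, log-normal, categorical resource-use
distributions) through the model with common random numbers across arms, and
the decision layer reports net monetary benefit
(`NMB = λ·QALYs − cost`), NMB rankings, absolute/extended dominance with the
efficiency frontier and its ICERs, cost-effectiveness planes, and the
cost-effectiveness acceptability frontier (CEAF).

## Worked example

```python
import sadcea

params = sadcea.ModelParameters.defaults()
interventions = sadcea.load_interventions()

baseline, specs = sadcea.default_effect_specs()
posterior = sadcea.sample_recovery_posterior(specs, baseline, n_draws=10_000, seed=42)
result = sadcea.run_psa(interventions, posterior, params, n_iter=10_000, seed=42)

summary = sadcea.summarize(result, threshold=20_000.0)
print(summary.head(6).round(2))
for p in sadcea.ceaf(result, [0, 5_000, 20_000, 30_000]):
    print(f"threshold {p.threshold:>8.0f}  best {p.best:<11s} P(best)={p.probability:.2f}")
```

prints (abridged):

```
               mean_cost  mean_qaly  pct_well_at_horizon       nmb  rank                status
id
icbt_cw          6177.55       3.77                49.93  69143.71     1              frontier
icbt_general     5711.14       3.66                41.00  67439.10     2  extendedly dominated
icbt_hope        5854.27       3.61                37.26  66395.09     6             dominated
icbt_short       5955.34       3.60                36.28  66058.61     9             dominated
phenelzine       4564.85       3.60                34.65  67402.00     3              frontier
shws_internet    5196.04       3.57                33.69  66184.78     7             dominated

threshold        0  best shns_book   P(best)=0.25
threshold     5000  best phenelzine  P(best)=0.30
threshold    20000  best icbt_cw     P(best)=0.56
threshold    30000  best icbt_cw     P(best)=0.66
```

Reading the output: individual cognitive therapy (Clark & Wells model,
`icbt_cw`) accrues the most QALYs (3.77 per person over 12 weeks + 5 years)
and, despite the highest intervention cost, attains the highest mean NMB at
the £20,000/QALY threshold — it is the most cost-effective option. The
efficiency frontier runs book-based unsupported self-help → phenelzine →
individual cognitive therapy; generic individual CBT is extendedly dominated
(a mix of phenelzine and `icbt_cw` beats it on both axes). The CEAF shows
which arm is preferred as willingness-to-pay grows and with what probability.

The same pipeline is available from the shell:

```bash
sadcea run --n-iter 10000 --seed 42 --out-dir results/
sadcea scenarios --mode deterministic --out-dir results/scenarios/
sadcea validate     # recompute packaged derived inputs, exit 0 when all match
```

`sadcea scenarios` reruns the analysis under the packaged sensitivity
scenarios: cheaper therapist bands, an alternative utility pair (0.79/0.91),
1/3/10-year horizons, and fixed relapse risk ratios from 1.0 to 2.0.

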