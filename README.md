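# dietpaf

Population attributable fractions (PAFs) of cancer for dietary factors,
computed from published relative risks and national food-consumption
survey summaries, with Monte Carlo confidence intervals and
attributable case counts. The bundled configuration reproduces a
comparative risk assessment for Italy: dietary intakes around 2005
(INRAN-SCAI survey summaries) against cancer incidence in 2020,
assuming a ~15-year exposure-to-outcome lag.

The package is aimed at epidemiologists doing burden-of-disease
estimation from aggregate inputs: no microdata are required — a factor
is described by its prevalence of consumers and the mean/SD of intake
among consumers.

## The model

For a **continuous** dietary factor, intake among consumers is modelled
as Gamma(k, θ) fitted by the method of moments (k = μ²/σ², θ = σ²/μ).
The population distribution combines the non-consumers (point mass at
0) with 10 equal-probability consumer categories bounded by the gamma
deciles; each category is represented by the arithmetic midpoint of its
boundaries, with the lowest boundary at 0 and the top category closed
at the 99th percentile. Against a counterfactual (recommended) intake,
each category's deviation Dev_k (excess for harmful factors, deficit
for protective ones; floored at 0) yields an excess relative risk

    ERR_k = exp(lnRR_1g · Dev_k) − 1,

where lnRR_1g = ln(RR)/increment (the reciprocal RR is used for
protective factors), and

    PAF = Σ_k Pr_k·ERR_k / (1 + Σ_k Pr_k·ERR_k).

For an **any-vs-none** factor the formula collapses to Levin's formula,
PAF = Pr(RR−1)/(1 + Pr(RR−1)), with Pr the proportion of consumers.

95% CIs come from 10,000 Monte Carlo draws: ln RR from the normal
implied by its published CI; the consumer mean intake from its
standard-error normal (continuous factors); the prevalence from the
binomial normal approximation (dichotomous factors). The CI is the
empirical 2.5th–97.5th percentile interval, lower bound clipped at 0.
Attributable cases are the PAF (rounded to 0.1 pp) times the observed
case counts; subtype counts not reported by registries are derived by
fixed splitting fractions.

## Worked example

```python
import dietpaf as dp

summary = dp.IntakeSummary("processed_meat", "male",
                           prevalence=0.87, mean_intake=40.7,
                           sd_intake=31.0, n_subjects=1068)
dist = dp.build_exposure_distribution(summary)
rr = dp.RelativeRisk(1.16, 1.10, 1.28, increment=50, exposure_form="continuous")
est = dp.paf_continuous(dist, rr, dp.Counterfactual("zero_intake"))
print(f"PAF = {est.paf * 100:.1f}%")
```

prints `PAF = 10.5%`: about one in ten male colorectal cancers is
attributable to processed-meat intake under a zero-intake
counterfactual. Adding the Monte Carlo interval
(`examples/monte_carlo_ci.py`) gives `PAF = 10.5% (95% CI 5.1-15.8%)`.

The full pipeline on the bundled inputs:

```
python examples/full_pipeline.py     # or: dietpaf run --out results/
```

ends with

```
diet_related (male): PAF 15.7% — 12,148 of 77,396 cases
 all_cancers (male): PAF 6.2% — 12,148 of 194,754 cases
diet_related (female): PAF 14.8% — 8,185 of 55,341 cases
 all_cancers (female): PAF 4.5% — 8,185 of 181,857 cases
```

i.e. the analysed dietary factors account for roughly 6.2% of male and
4.5% of female cancer cases in Italy in 2020. Totals sum per-pair
attributable cases; factors acting on the same cancer site overlap, so
these are upper-end estimates.

Each script in `examples/` demonstrates one capability: point PAFs,
Monte Carlo CIs, the full configured pipeline, and synthetic-survey
recovery experiments.

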