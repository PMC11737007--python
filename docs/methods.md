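# Methods

## Scope and inputs

dietpaf estimates the share of cancer cases attributable to dietary
factors by comparing a population's intake distribution against
counterfactual (recommended-intake) scenarios. Everything is computed
from aggregate inputs:

* per factor and sex: prevalence of consumers, mean and SD of intake
  among consumers (g/day), and the survey stratum size;
* per factor–cancer pair: a published relative risk with 95% CI, the
  intake increment it refers to, and the counterfactual scenario;
* per cancer and sex: observed case (and optionally death) counts.

The bundled `italy2020` configuration carries the Italian inputs:
intake summaries from the INRAN-SCAI 2005–06 national survey (men
n=1068, women n=1244, ages 18–65), sixteen factor–cancer pair families
over eight dietary factors, and 2020 registry counts. The ~15-year lag
between exposure (2005) and outcome (2020) is carried as metadata
(`exposure_year`/`outcome_year`) on outputs; it does not enter any
computation.

## Exposure model

Intake among consumers is modelled as a gamma distribution fitted by
the method of moments: shape k = (μ/σ)², scale θ = σ²/μ. The survey
mean and SD are treated as population values; no small-sample
correction is applied. The population exposure distribution has 11
categories: the non-consumers (probability 1−prevalence, intake 0) and
10 consumer categories of equal probability bounded by the gamma
deciles.

Representative intakes are arithmetic midpoints of the category
boundaries, with the lowest boundary fixed at 0 and the open-ended top
category closed at a cap quantile so its midpoint is finite. The cap
defaults to 1 − 0.1/K (0.99 for the standard K=10), scaling with the
number of categories so the top category always spans the same relative
tail mass. Midpoints were chosen over decile medians or conditional
means because they reproduce the published Italian PAFs; the cap is
configurable.

A factor with prevalence 0 degenerates to a point mass at zero intake
(not an error). A prevalence of "~100%" in the source table is treated
as exactly 1.

Discretization error: at K=10 the PAF sits within 1 percentage point of
the converged (K→∞) value for every bundled pair, within 0.5 pp for all
but the strongest dose-response (vegetables→nasopharynx, RR 0.74 per
100 g/day, where the gap is ~0.8 pp). The coarse grid is intentional —
it is part of the published method, and the printed values match K=10,
not the converged limit. Between K=100 and K=1000 all pairs agree
within 0.1 pp.

## PAF formulas

Continuous factors use the categorized counterfactual-deviation
formula: for category k with representative intake x_k, the deviation
from the counterfactual is

* harmful factor, zero-intake counterfactual: Dev_k = x_k;
* harmful, "at most T": Dev_k = max(0, x_k − T);
* protective, "at least T": Dev_k = max(0, T − x_k).

Deviations are floored at zero — categories already meeting the
recommendation contribute nothing. The excess relative risk is
ERR_k = exp(lnRR_1g·Dev_k) − 1 with lnRR_1g = ln(r)/increment, where
r is the RR for harmful factors and its reciprocal for protective ones,
so lnRR_1g is always ≥ 0 and measures the risk increase per gram of
excess (harmful) or deficit (protective). Then
PAF = S/(1+S), S = Σ_k Pr_k·ERR_k.

Any-vs-none factors use Levin's formula with the proportion of
consumers and, for protective factors, the reciprocal RR — the PAF then
measures the burden attributable to *not* consuming the protective
food. Using the consumer (rather than non-consumer) prevalence in this
configuration follows the published analysis verbatim; no alternative
parametrization is exposed.

PAFs are carried at full floating precision internally and rounded only
for reporting (one decimal in percent) and burden arithmetic.

## Uncertainty propagation

Per Monte Carlo draw (default 10,000 per pair):

* ln RR ~ Normal(ln value, s) with s = (ln ci_high − ln ci_low)/(2·z),
  z = Φ⁻¹(0.975). The published CI is treated as symmetric on the log
  scale.
* Continuous factors: consumer mean ~ Normal(μ, σ/√n_c) with
  n_c = round(prevalence × n_subjects), since mean and SD are computed
  among consumers. The gamma is refitted with the simulated mean and
  the observed SD, the exposure distribution rebuilt and the PAF
  recomputed. Non-positive simulated means are redrawn (counted and
  reported) to keep the gamma defined.
* Dichotomous factors: prevalence ~ Normal(p, √(p(1−p)/n)) truncated to
  [0,1].

Draws where the simulated RR crosses 1 keep the published direction of
contrast and therefore contribute negative PAFs; they stay in the
sample, and only the final interval's lower bound is clipped at zero.
The CI is the empirical (1−level)/2 and 1−(1−level)/2 quantile pair.
Each (pair, sex) gets an independent substream seeded deterministically
from the run seed and the pair identity, so results do not depend on
pair order and identical seeds give bit-identical output.

Mean uncertainty is propagated only for continuous factors and
prevalence uncertainty only for dichotomous ones, matching the wording
of the source analysis; sampled quantities are independent.

### Confidence-interval reproduction

Under this sampling model the CI endpoints converge (checked with up to
2×10⁶ draws) to values whose lower bounds match the published Italian
intervals within 0.2 pp, while the upper bounds for the two strongest
pairs (processed meat→colorectum men; coffee→liver men) sit about
0.5 pp inside the published ones (15.78 vs 16.3; 42.26 vs 42.8).
Plausible variants — adding prevalence uncertainty for continuous
factors, normal-approximation intervals from the draws, natural-scale
RR sampling, asymmetric log-normal SDs — do not reproduce all published
bounds simultaneously, so the published intervals appear to depend on
implementation details their description does not determine. The
package implements the described model exactly and documents the
residual gap rather than tuning toward the printed bounds.

## Burden arithmetic

Attributable cases = round(PAF rounded to 0.001 × observed cases), with
half-away-from-zero rounding in both steps. Rounding the PAF to 0.1 pp
first matches the reported precision and is the only convention that
reproduces every published count exactly (e.g. 0.105 × 23,420 = 2459).
CI bounds for counts apply the same arithmetic to the PAF CI bounds.

Registries do not report every subtype: nasopharyngeal cancers are
derived as 8.7% (men) / 6.9% (women) of oral and pharyngeal cancers;
esophageal adenocarcinoma and squamous cell carcinoma as 33%/67% of
esophageal cancers. Counts present in the input table take precedence
over derivation — in particular the cardia stomach counts are the
printed ones (≈15% of stomach totals), not the 33% rule stated
alongside them, which contradicts the printed table.

Per-sex totals sum per-pair attributable counts against the observed
diet-related and all-cancer totals. Factors acting on the same site are
summed without overlap correction, so aggregate PAFs can exceed any
single-factor PAF and should be read as upper-end figures.

## Synthetic survey generator

`dietpaf.survey` generates individual-level microdata with exactly the
structure the analysis assumes: each subject consumes each factor
independently with its prevalence (Bernoulli) and consumer intakes are
gamma draws. Defaults in tests mirror the Italian survey conditions
(stratum sizes 1068/1244, survey-level prevalences and moments). The
generator deliberately omits features of real food-record data —
within-subject correlation across foods, 3-day averaging, measurement
error, seasonal and sampling weights — because the pipeline consumes
only marginal summary moments. Passing recovery and coverage tests
therefore validate the summarize→model→PAF chain under its own
assumptions, not robustness to dietary measurement error.

Recovery experiments (generate → summarize → PAF vs PAF from truth)
show |bias| < 0.2 pp at n = 100,000 subjects; 95% CIs cover the true
PAF in ≥ 90% of 200 replications at the real survey's n = 1068 (the
coverage is conservative because RR uncertainty also enters the CI).
The coverage check uses 2,000 Monte Carlo draws per replicate, enough
for stable 95% quantile estimates.

## Numerical and design choices

* Gamma quantiles and CDF via scipy; RNG via numpy Generator
  (PCG64); quantiles via numpy's default linear interpolation.
* Seeds: the run seed plus a CRC32 of "factor|cancer|sex" feed a
  SeedSequence per pair; all derived seeds stay below 2³¹.
* Degenerate inputs: prevalence 0 → point mass (PAF 0 against harmful
  counterfactuals); SD 0 is rejected (the gamma fit is undefined);
  a degenerate RR CI gives zero sampling variance.
* Validation reports all configuration problems at once; the run log
  records seed, draw count, category count, cap quantile and rounding
  conventions — enough to reproduce any output byte-identically.

## Limitations

Single-factor PAFs only: no joint or pathway-specific PAFs, no
substitution effects, no age-stratified estimates (age-specific intake
data are not part of the inputs). RRs are applied identically to
incidence and mortality. The counterfactual scenarios and RR choices
drive the estimates as much as the intake data; results are not
directly comparable across studies using different choices.
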