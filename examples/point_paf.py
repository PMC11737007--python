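"""Point PAF for a single factor-cancer pair, from summary statistics.

Builds the men's processed-meat exposure distribution (87% consumers;
mean 40.7, SD 31.0 g/day among consumers) from the Italian 2005-06
survey summaries, and computes the fraction of colorectal cancer
attributable to any processed-meat intake (RR 1.16 per 50 g/day,
counterfactual 0 g/day).
"""

import dietpaf as dp

summary = dp.IntakeSummary(
    factor_id="processed_meat", sex="male",
    prevalence=0.87, mean_intake=40.7, sd_intake=31.0, n_subjects=1068,
)
params = dp.fit_gamma_moments(summary.mean_intake, summary.sd_intake)
print(f"fitted gamma: shape={params.shape:.3f}, scale={params.scale:.2f} g/day")

dist = dp.build_exposure_distribution(summary)
print(f"exposure categories: {dist.n_categories}, "
      f"non-consumers {dist.probabilities[0]:.2f}, "
      f"discretized mean {dist.mean:.1f} g/day")

rr = dp.RelativeRisk(1.16, 1.10, 1.28, increment=50,
                     exposure_form="continuous", factor_id="processed_meat")
est = dp.paf_continuous(dist, rr, dp.Counterfactual("zero_intake"))
print(f"PAF = {est.paf * 100:.1f}%")
print("-> share of male colorectal cancers attributable to processed meat:")
print("   about 1 in 10 cases would not occur under zero intake.")
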