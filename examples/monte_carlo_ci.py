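"""Monte Carlo confidence interval for one PAF.

Propagates the sampling uncertainty of the published RR (via its 95%
CI) and of the survey's consumer mean intake into a percentile CI for
the processed meat -> colorectal cancer PAF in men.
"""

import dietpaf as dp

summary = dp.IntakeSummary("processed_meat", "male", 0.87, 40.7, 31.0, 1068)
rr = dp.RelativeRisk(1.16, 1.10, 1.28, increment=50, exposure_form="continuous")
cf = dp.Counterfactual("zero_intake")

print(f"SD of ln RR implied by the CI: {dp.rr_sampling_sd(rr):.4f}")

sample = dp.simulate_paf_distribution(
    rr, cf, summary, dp.SimulationSettings(n_sims=10_000, seed=42)
)
low, high = dp.percentile_ci(sample, ci_level=0.95)

point = dp.paf_continuous(dp.build_exposure_distribution(summary), rr, cf).paf
print(f"PAF = {point * 100:.1f}% (95% CI {low * 100:.1f}-{high * 100:.1f}%)")
print("-> the interval reflects RR and intake-mean uncertainty only;")
print("   10,000 draws, empirical 2.5th/97.5th percentiles, lower bound")
print("   clipped at zero.")
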