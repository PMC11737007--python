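"""PAF recovery from synthetic survey microdata.

Generates individual-level consumption records from known parameters
(Bernoulli consumption x gamma intake), summarizes them back to the
statistics the pipeline consumes, and checks that the recomputed PAF
recovers the PAF implied by the truth.
"""

import dietpaf as dp

truth = dp.SurveyFactorTruth(
    "processed_meat", prevalence=0.87,
    shape=(40.7 / 31.0) ** 2, scale=31.0**2 / 40.7,
)
rr = dp.RelativeRisk(1.16, 1.10, 1.28, increment=50, exposure_form="continuous")
cf = dp.Counterfactual("zero_intake")

records = dp.generate_survey([truth], n_subjects=1068, seed=11)
summary = dp.summarize_survey(records, "processed_meat", "male")
print(f"simulated survey (n=1068): prevalence {summary.prevalence:.3f}, "
      f"mean {summary.mean_intake:.1f}, SD {summary.sd_intake:.1f} g/day")

report = dp.recovery_experiment(truth, rr, cf, n_subjects=10_000,
                                n_replicates=20, seed=5)
print(f"true PAF {report.true_paf * 100:.2f}%; over {report.n_replicates} "
      f"replicates at n={report.n_subjects:,}: "
      f"bias {report.bias * 100:+.3f} pp, RMSE {report.rmse * 100:.3f} pp")
print("-> the summarize-then-model pipeline recovers the generating PAF;")
print("   bias shrinks toward zero as the survey grows.")
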