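"""End-to-end validation study on a synthetic ICU cohort.

Generates 2,000 patients under the modern-era preset, builds the
suspected-infection cohort, scores day-1 SOFA (original, M2, M3) and runs
the discrimination/calibration analysis, printing the AUROCs with DeLong
95% CIs, the paired comparisons, and the original CV score's structural
skew.
"""

from cvsofa import SimParams, build_cohort, run_validation, score_cohort, simulate_bundle

params = SimParams(n_patients=2000, seed=7)
bundle, truth = simulate_bundle(params)
cohort = build_cohort(bundle)
scores = score_cohort(bundle, cohort)

death = bundle.stays.set_index("stay_id")["hospital_death"]
outcomes = scores["stay_id"].map(death).astype(int).to_numpy()
report = run_validation(scores, outcomes)

print(f"cohort: {report.n} included, in-hospital mortality {report.mortality:.3f}\n")
print("AUROC (DeLong 95% CI):")
for name, roc in report.roc.items():
    print(f"  {name:<14s} {roc.auroc:.3f} ({roc.ci_low:.3f}-{roc.ci_high:.3f})")
print("\npaired DeLong comparisons (p):")
for name, p in report.paired_p.items():
    print(f"  {name:<28s} {p:.4f}")

dist = report.distribution["cv_original"].set_index("score_level")
print("\noriginal CV-SOFA distribution and mortality by level:")
print(dist[["n", "observed_mortality"]].round(3).to_string())
print(
    "\nLevel 2 (dopamine/dobutamine) is nearly empty under modern practice,\n"
    "so its mortality estimate is unstable and the level-to-level mortality\n"
    "gradient breaks down - the skew the modified score removes."
)
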