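"""Full synthetic pipeline: cohort + phantoms -> quantification -> agreement.

Generates a 145-patient cohort with a known CT-vs-thermodilution
disagreement (bias -104 ml, SD ~530 ml), builds one phantom per patient
whose tissue mass encodes the CT-side edema, quantifies every phantom,
and reports the agreement statistics the analysis should recover.
"""

import warnings

from edemaquant import CohortSpec, RunConfig, run_pipeline

spec = CohortSpec(n=145, seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_pipeline(RunConfig(cohort_spec=spec, seed=7))

ba = report.agreement["auto_vs_tptd"]
print(f"paired scans: {ba['n']}")
print(f"bias (TPTD - CT): {ba['bias_ml']:.0f} ml   (injected: -104 ml)")
print(f"limits of agreement: [{ba['loa_lower_ml']:.0f}, {ba['loa_upper_ml']:.0f}] ml")
print(f"Spearman rho: {ba['spearman_rho']:.2f}")
print()
print("cohort summary (mean +/- SD):")
for _, row in report.summary.iterrows():
    print(f"  {row['parameter']:42s} {row['mean']:8.0f} +/- {row['sd']:.0f}")
print()
print(f"segmentation grades (%): {report.grades.percentages}")
# The bias and limits match the injected disagreement within sampling
# error at n=145; per-scan weights equal phantom truth up to image noise.
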