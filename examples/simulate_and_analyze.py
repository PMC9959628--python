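"""Generate a synthetic six-reader study and run the full analysis.

The default configuration mirrors the target study composition: 32 lesions
(14 PZ, 11 TZ, 7 AFMS with a fixed significance split), six raters in two
experience groups, two sessions.  Prints an excerpt of the per-CDE
agreement table, the PI-RADS category agreement, the between-group score
comparison on clinically significant lesions, and diagnostic accuracy at
the overall-category >= 3 threshold.
"""

import pandas as pd

from pirads_cde import (
    GeneratorConfig,
    category_agreement_table,
    design_from_study,
    diagnostic_accuracy,
    feature_agreement_table,
    generate_study,
    group_score_comparison,
)

pd.set_option("display.width", 120)

study = generate_study(GeneratorConfig(seed=1))
design = design_from_study(study)
print(f"{len(study.manifest)} lesions, {len(study.rater_groups)} raters, "
      f"{len(study.reports)} reports\n")

features = feature_agreement_table(study.reports, design)
print("per-CDE inter-rater agreement (excerpt; PA in %, mean over 30 pair-sessions):")
excerpt = features[features["feature"].isin(
    ["t2w_abnormality", "t2w_shape", "t2w_margin", "dce_enhancement"]
)]
print(excerpt[["modality", "feature", "pa", "ac1", "ci_low", "ci_high", "band"]]
      .round(3).to_string(index=False))

categories = category_agreement_table(study.reports, design)
inter = categories[(categories["analysis"] == "interrater")
                   & (categories["stratum"] == "overall")]
print("\nPI-RADS category inter-rater agreement (sessions pooled):")
print(inter[["feature", "pa", "ac1", "band"]].round(3).to_string(index=False))

comp = group_score_comparison(study.reports, design)
print(f"\noverall category on clinically significant lesions: "
      f"experienced {comp.mean_experienced:.2f} (SD {comp.sd_experienced:.2f}) vs "
      f"inexperienced {comp.mean_inexperienced:.2f} (SD {comp.sd_inexperienced:.2f}), "
      f"Wilcoxon W = {comp.statistic:.1f}, p = {comp.p_value:.4f}")

acc = diagnostic_accuracy(study.reports, list(study.manifest), threshold=3, design=design)
print("\ndiagnostic accuracy of overall >= 3 (per-rater metrics averaged by group):")
print(acc.by_group.round(3).to_string(index=False))
# Detection-type CDEs (abnormality) agree far better than subjective shape
# and margin descriptors; the coarser three-outcome DCE variable shows the
# highest raw category agreement; experienced raters score higher and
# separate significant lesions slightly better.
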