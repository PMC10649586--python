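"""Up/down expression ratios scored as classifiers.

Builds all 5 x 10 = 50 up/down ratios from the microarray view of a
simulated cohort (linear scale: 2^log2-intensity; the per-sample reference
cancels inside a ratio, so no normalization is needed first) and ranks
them by ROC AUC with the Youden-optimal operating point (sensitivity
refers to detecting malignant samples).
"""

from mirsig import (
    GroupDesign,
    build_ratios,
    default_study_params,
    simulate_study,
    summarize_ratios,
)

# weaker biomarkers than the package default (|log2 effect| 1 instead of 2,
# more noise) so the ratios show a realistic spread of performance
params = default_study_params(
    seed=7,
    de_up={f"miR-up-{i + 1:02d}": 1.0 for i in range(5)},
    de_down={f"miR-dn-{i + 1:02d}": -1.0 for i in range(10)},
    noise_sd=0.8,
)
study = simulate_study(GroupDesign(), params)

linear = 2.0**study.expression.values
ratios = build_ratios(linear, study.up_ids, study.down_ids)
summary = summarize_ratios(ratios, study.expression.groups)

print(f"{len(ratios.values)} ratios; "
      f"{int(summary['significant'].sum())} significantly different (p < 0.05)\n")
cols = ["auc", "youden_j", "sensitivity", "specificity", "p"]
print("top 5 ratios by AUC:")
print(summary.sort_values("auc", ascending=False).head(5)[cols].round(3).to_string())

# an AUC of 1.0 means the ratio ranks every malignant sample above every
# borderline one; J = sensitivity + specificity - 1 summarizes the best
# single threshold (J = 1 is a perfect split)
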