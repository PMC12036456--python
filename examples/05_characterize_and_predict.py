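"""Characterize subphenotypes and test their predictability from baselines.

Uses the planted subphenotype labels directly (the clustering example shows
how to derive them from data) to demonstrate the characterization and
prediction machinery: transition-time statistics, 5-year post-AD survival
with a log-rank test, prevalence profiling, and pre-index prediction.
"""

import numpy as np

from progsub import (
    CohortSpec, apply_inclusion_criteria, build_baseline_features,
    build_feature_space, fit_classifier, km_logrank, simulate_cohort,
    transition_stats,
)

cohort, _ = apply_inclusion_criteria(simulate_cohort(CohortSpec(n_patients=240, seed=5)))
labels = np.array([t.true_subphenotype for t in cohort])

stats = transition_stats(cohort, labels)
print("MCI->AD transition days by subphenotype:")
for _, row in stats.iterrows():
    tag = "overall" if row.cluster == -1 else f"S{int(row.cluster) + 1}"
    print(f"  {tag:8s} n={int(row.n_patients):3d} mean={row.mci_to_ad_mean:7.1f} "
          f"sd={row.mci_to_ad_sd:6.1f}")

curves, stat, p = km_logrank(cohort, labels)
print(f"5-year post-AD survival: log-rank statistic {stat:.1f}, p = {p:.2e}")
for c in curves:
    five_year = c.survival[-1]
    print(f"  S{c.cluster + 1}: survival at horizon {five_year:.2f}")

space = build_feature_space()
dataset = build_baseline_features(cohort, {t.patient_id: int(l) for t, l in zip(cohort, labels)}, space)
_, report = fit_classifier(dataset, family="gradient-boosted-trees",
                           resampling="none", search_budget=5, seed=0)
print(f"pre-index subphenotype prediction macro AUROC: "
      f"{report.metrics['macro']['auroc']:.3f}")
print("top 5 features by mean |attribution|:")
print(report.attribution.head(5)[["mean"]].to_string())
# A low log-rank p indicates genuinely different post-AD survival between
# subphenotypes; the attribution table shows which baseline features drive
# subphenotype membership.
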