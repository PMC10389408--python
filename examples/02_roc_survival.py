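"""Cutoff derivation and survival stratification on a simulated cohort.

Simulates an 84-patient cohort, derives the S-TAM/L-TAM area cutoff from the
ROC of slide-mean area against recurrence (Youden's J with the one-SE
sensitivity-favoring rule), and runs Kaplan-Meier, log-rank and a
bootstrap-validated Cox model on disease-free survival.
"""

import numpy as np

from tammorph import (
    GeneratorConfig, build_roc, classify_patients, cox_fit, generate_cohort,
    km_estimate, logrank_test, one_se_cutoff, survival_at,
)
from tammorph.morphometry import measure_cells, sample_cells, summarize_cohort

seed = 11
sc = generate_cohort(GeneratorConfig(seed=seed, spatial_subset_size=0))
outlines = [o for s in sc.slides.values() for o in s.outlines]
summary = summarize_cohort(measure_cells(sample_cells(outlines, seed=seed)))
cohort = sc.cohort.merge(
    summary.rename(columns={"slide_mean_area_um2": "mean_tam_area"})[
        ["slide_id", "mean_tam_area"]
    ],
    on="slide_id",
)

roc = build_roc(cohort["mean_tam_area"], cohort["dfs_event"].astype(bool))
cutoff = one_se_cutoff(roc)
print(f"AUC {roc.auc:.2f} (95% CI {roc.auc_ci[0]:.2f}-{roc.auc_ci[1]:.2f}); "
      f"cutoff {cutoff:.2f} um^2")

cohort = classify_patients(cohort, cutoff)
groups = []
for cls, grp in cohort.groupby("tam_class"):
    curve = km_estimate(grp["dfs_time"], grp["dfs_event"].astype(bool))
    print(f"{cls}: n={len(grp)}, 3-year DFS {100 * survival_at(curve, 36):.1f}%")
    groups.append((grp["dfs_time"], grp["dfs_event"].astype(bool)))
chi2, p = logrank_test(*groups)
print(f"log-rank chi2={chi2:.2f}, p={p:.2g}")

cohort["ltam"] = (cohort["tam_class"] == "L-TAM").astype(int)
cox = cox_fit(cohort, ["ltam"], n_bootstrap=500, seed=seed)
row = cox.summary.loc["ltam"]
print(f"Cox HR (L-TAM vs S-TAM) {row['hr']:.2f} "
      f"[{row['ci_low']:.2f}-{row['ci_high']:.2f}], p={row['p']:.2g}")
print(f"bootstrap 95% CI [{cox.bootstrap.loc['ltam', 'hr_ci_low']:.2f}-"
      f"{cox.bootstrap.loc['ltam', 'hr_ci_high']:.2f}]; "
      f"concordance {cox.concordance:.2f} "
      f"(optimism-corrected {cox.concordance_corrected:.2f})")
# Patients with large macrophages (area >= cutoff) recur much faster; the
# generator's true hazard ratio is 5, and the fitted CI should cover it.
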