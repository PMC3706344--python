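"""Group statistics on the bundled reference cohort AUC(CV_T) scores.

Five healthy volunteers vs five patients with advanced COPD, scored
against the healthy group's CV_T of 22%: summaries with t-based 95%
confidence intervals and the exact Mann-Whitney comparison.
"""

import spectcv as sc
from spectcv.datasets import reference_cohort_auc

cohort = reference_cohort_auc()
for name, values in cohort.items():
    s = sc.group_summary(values)
    print(f"{name:>8}: AUC(CV_T) {s.mean:.0f}% +/- {s.ci95_half_width:.0f}% "
          f"(95% CI, n={s.n})")

cmp = sc.mann_whitney_u(cohort["healthy"], cohort["copd"])
print(f"Mann-Whitney U = {cmp.u_statistic:g} ({cmp.method}), "
      f"two-tailed p = {cmp.p_two_tailed:.4f}")
print("-> complete separation of the groups: every patient scores above")
print("   every healthy volunteer, significant at p < 0.05 despite n = 5.")
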