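"""Bundled reference data.

``reference_cohort_auc`` holds the published AUC(CV_T) scores (percent)
from the clinical evaluation of the method: five healthy, life-long
non-smoking volunteers (H1-H5) and five patients with advanced
(grade 3-4) COPD and emphysema (P1-P5), each scored against the healthy
group's CV_T of 22%.  The values are useful as a worked example for the
group statistics and as a smoke test of the scoring conventions.
"""

from __future__ import annotations

__all__ = ["HEALTHY_AUC_PERCENT", "COPD_AUC_PERCENT", "reference_cohort_auc"]

HEALTHY_AUC_PERCENT: tuple[float, ...] = (52.0, 75.0, 57.0, 72.0, 71.0)
COPD_AUC_PERCENT: tuple[float, ...] = (99.0, 100.0, 100.0, 100.0, 100.0)


def reference_cohort_auc() -> dict[str, tuple[float, ...]]:
    """AUC(CV_T) scores of the reference cohort, by group."""
    return {"healthy": HEALTHY_AUC_PERCENT, "copd": COPD_AUC_PERCENT}
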