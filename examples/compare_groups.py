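"""Full in-memory study loop: simulate 20 controls vs 19 cases, extract
the feature panel per subject, and compare the groups feature by feature.

Each feature is screened for normality per group (one-sample KS); normal
pairs go to a pooled t-test, the rest to Mann-Whitney U. The printed
table mirrors a clinical report: group means +/- SD, the test used, and a
two-tailed p-value (uncorrected for multiple comparisons).
"""

import pandas as pd

from histofeat import (
    compare_cohorts,
    extract_features,
    generate_cohort_subjects,
    study_cohort_spec,
)

rows = []
for sspec, image, mask in generate_cohort_subjects(study_cohort_spec(seed=7)):
    row = {"subject_id": sspec.subject_id, "group": sspec.group_label}
    row.update(extract_features(image, mask).as_dict())
    rows.append(row)
table = pd.DataFrame(rows)

print(f"{'feature':<20} {'control':>18} {'case':>18} {'test':<13} {'p':>8}")
for r in compare_cohorts(table):
    ctrl = f"{r.control.mean:8.2f} +/- {r.control.sd:6.2f}"
    case = f"{r.case.mean:8.2f} +/- {r.case.sd:6.2f}"
    flag = "*" if r.significant else " "
    print(f"{r.feature_name:<20} {ctrl:>18} {case:>18} {r.test_used:<13} {r.p_two_tailed:8.4f}{flag}")
print(
    "\n* = p < 0.05 (two-tailed, uncorrected). With the default group "
    "models, mean intensity, SD and entropy separate the arms strongly; "
    "skewness does not."
)
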