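"""Classify the packaged 16-case atypical-diabetes roster.

Runs the deterministic chart-review rule engine over the packaged roster of
sixteen confirmed atypical cases and prints each case's diabetes-type
category and atypical subtype.  With the default configuration the subtype
partition is 1 ketosis-prone (KPD), 7 mild age-related (MARD), and 8
insulin-sufficient non-metabolic (ISNM) — the published split.
"""

from collections import Counter

from adscreen import classify_ad_subtype, classify_diabetes_type
from adscreen.fixtures import load_case_roster

cases, _ = load_case_roster()

print(f"{'case':<6}{'dx age':>7}{'HbA1c max':>10}{'meds':>6}"
      f"{'category':>10}{'subtype':>9}")
tally = Counter()
for case in cases:
    outcome = classify_diabetes_type(case)
    subtype = classify_ad_subtype(case)
    tally[subtype.value] += 1
    a1c = "-" if case.hba1c_range is None else f"{case.hba1c_range[1]:.1f}"
    print(f"{case.patient_id:<6}{case.age_at_diagnosis:>7.0f}{a1c:>10}"
          f"{case.n_noninsulin_dm_meds:>6}{outcome.category.value:>10}"
          f"{subtype.value:>9}")

print(f"\nsubtype partition: KPD={tally['KPD']}, MARD={tally['MARD']}, "
      f"ISNM={tally['ISNM']}")
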