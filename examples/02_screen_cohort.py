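"""Screen a synthetic cohort: base exclusion algorithm plus the six branches.

The base algorithm starts from ML-flagged T2D patients and removes anyone
with metabolic-syndrome evidence (HDL ever < 50 mg/dL, TG ever > 150, BMI
ever > 30), too few BMI records, cystic fibrosis codes, or a positive islet
antibody.  The six branch algorithms then each prune likely T1D a different
way; their union is the candidate set sent to chart review.  The attrition
table shows where patients drop out — the whole point of the method is the
large reduction between the ML-T2D group and the candidate union.
"""

from adscreen import (
    apply_base_algorithm, assemble_candidates, default_config,
    generate_cohort, run_all_branches,
)
from adscreen.branch_algorithms import BRANCH_NAMES

cohort, _ = generate_cohort(default_config(n_patients=10_000, seed=1))

base = apply_base_algorithm(cohort)
print(f"ML T2D input: {base.input_size}")
print("base-algorithm attrition (sequential accounting):")
for criterion, n_excluded, n_remaining in base.attrition_rows():
    print(f"  {criterion:<14} -{n_excluded:>4}  -> {n_remaining}")

by_id = cohort.by_id()
survivors = [by_id[pid] for pid in base.kept]
branches = run_all_branches(survivors)
candidates = assemble_candidates(branches)

print("\nbranch algorithms over the base-kept set "
      f"(n={len(base.kept)}):")
for result in branches:
    print(f"  {result.branch_id}. {BRANCH_NAMES[result.branch_id]:<32}"
          f" kept {len(result.kept):>3}")
print(f"\ncandidate union: {len(candidates.union_ids)} patients "
      f"({100 * len(candidates.union_ids) / len(cohort):.2f}% of cohort) "
      "-> manual chart review")
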