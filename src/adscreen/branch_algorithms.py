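"""Six branch algorithms that prune likely T1D from the base-kept set.

Each branch is an independent predicate over the base-algorithm survivors,
yielding six overlapping candidate cohorts:

1. keep only patients with documented all-negative islet-antibody testing;
2. keep only patients who never used insulin in the outpatient setting;
3. keep only patients ever exposed to a T2D-specific medication class
   (sulfonylurea, meglitinide, TZD, DPP-4i, alpha-glucosidase inhibitor,
   GLP-1 RA, or SGLT2i);
4. keep only patients ever exposed to a T2D-specific medication or
   metformin;
5. keep only patients for whom the biobank ML algorithm ruled out T1D
   (NPV 0.99);
6. keep only patients without a confident ML T1D call (PPV 0.95).

The branches run independently over the same input (not chained); the final
candidate set is their union with a per-branch membership matrix.  GLP-1 RA
and SGLT2i became common outside T2D after early 2020, so branches 3 and 4
accept an optional exposure cutoff date that ignores later prescriptions.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .ehr_model import CareSetting, Cohort, DrugClass, PatientRecord
from .vocab import T2D_SPECIFIC_CLASSES

__all__ = [
    "BranchResult", "CandidateSet", "BRANCH_NAMES",
    "branch_1_documented_negative_antibodies", "branch_2_no_outpatient_insulin",
    "branch_3_t2d_specific_med", "branch_4_t2d_med_or_metformin",
    "branch_5_t1d_ruled_out", "branch_6_not_confident_t1d",
    "run_all_branches", "assemble_candidates",
]

BRANCH_NAMES = {
    1: "documented-negative-antibodies",
    2: "no-outpatient-insulin",
    3: "t2d-specific-medication",
    4: "t2d-medication-or-metformin",
    5: "ml-t1d-ruled-out",
    6: "no-confident-ml-t1d",
}


@dataclass
class BranchResult:
    branch_id: int
    kept: list[str]       # ordered by patient_id
    excluded: set[str]

    def __post_init__(self) -> None:
        if not 1 <= self.branch_id <= 6:
            raise ValueError(f"branch_id must be 1-6, got {self.branch_id}")
        if set(self.kept) & self.excluded:
            raise ValueError("kept and excluded overlap")


@dataclass
class CandidateSet:
    """Union of the six branch cohorts with a membership matrix."""

    union_ids: list[str]                      # ordered by patient_id
    membership: dict[str, tuple[bool, ...]]   # patient_id -> 6 booleans

    def n_branches(self, patient_id: str) -> int:
        return sum(self.membership[patient_id])


def _run_branch(branch_id: int, patients: Sequence[PatientRecord],
                keep: Callable[[PatientRecord], bool]) -> BranchResult:
    kept, excluded = [], set()
    for p in sorted(patients, key=lambda p: p.patient_id):
        (kept.append(p.patient_id) if keep(p) else excluded.add(p.patient_id))
    return BranchResult(branch_id=branch_id, kept=kept, excluded=excluded)


def branch_1_documented_negative_antibodies(
        patients: Sequence[PatientRecord]) -> BranchResult:
    """Keep patients with at least one antibody test, all results negative.

    Any single documented negative suffices by default (patients with a
    positive result cannot appear after the base algorithm, but the predicate
    still requires zero positives so it is safe standalone).
    """
    def keep(p: PatientRecord) -> bool:
        return bool(p.antibodies) and all(
            a.result.value == "negative" for a in p.antibodies)
    return _run_branch(1, patients, keep)


def branch_2_no_outpatient_insulin(
        patients: Sequence[PatientRecord]) -> BranchResult:
    """Keep patients with no outpatient insulin exposure at any date."""
    def keep(p: PatientRecord) -> bool:
        return not any(m.drug_class is DrugClass.insulin
                       and m.setting is CareSetting.outpatient
                       for m in p.medications)
    return _run_branch(2, patients, keep)


def branch_3_t2d_specific_med(
        patients: Sequence[PatientRecord],
        exposure_cutoff: Optional[datetime.date] = None) -> BranchResult:
    """Keep patients ever exposed to a T2D-specific medication class."""
    def keep(p: PatientRecord) -> bool:
        return any(m.drug_class in T2D_SPECIFIC_CLASSES
                   and (exposure_cutoff is None or m.date <= exposure_cutoff)
                   for m in p.medications)
    return _run_branch(3, patients, keep)


def branch_4_t2d_med_or_metformin(
        patients: Sequence[PatientRecord],
        exposure_cutoff: Optional[datetime.date] = None) -> BranchResult:
    """Keep patients ever exposed to a T2D-specific medication or metformin."""
    eligible = T2D_SPECIFIC_CLASSES | {DrugClass.metformin}

    def keep(p: PatientRecord) -> bool:
        return any(m.drug_class in eligible
                   and (exposure_cutoff is None or m.date <= exposure_cutoff)
                   for m in p.medications)
    return _run_branch(4, patients, keep)


def branch_5_t1d_ruled_out(patients: Sequence[PatientRecord]) -> BranchResult:
    """Keep patients whose T1D was ruled out by the ML algorithm (NPV 0.99)."""
    return _run_branch(5, patients, lambda p: p.ml_flags.ml_t1d_ruled_out)


def branch_6_not_confident_t1d(patients: Sequence[PatientRecord]) -> BranchResult:
    """Keep patients without a confident ML T1D call (PPV 0.95)."""
    return _run_branch(6, patients, lambda p: not p.ml_flags.ml_t1d_high_ppv)


def run_all_branches(
        patients: Sequence[PatientRecord],
        exposure_cutoff: Optional[datetime.date] = None) -> list[BranchResult]:
    return [
        branch_1_documented_negative_antibodies(patients),
        branch_2_no_outpatient_insulin(patients),
        branch_3_t2d_specific_med(patients, exposure_cutoff),
        branch_4_t2d_med_or_metformin(patients, exposure_cutoff),
        branch_5_t1d_ruled_out(patients),
        branch_6_not_confident_t1d(patients),
    ]


def assemble_candidates(branch_results: Sequence[BranchResult]) -> CandidateSet:
    """Union the six branch cohorts into a candidate set.

    All six results must cover the same input set (kept + excluded); a
    mismatch indicates the branches were not run over one shared base-kept
    set and is an error.
    """
    if len(branch_results) != 6:
        raise ValueError(f"expected 6 branch results, got {len(branch_results)}")
    inputs = [set(r.kept) | r.excluded for r in branch_results]
    if any(s != inputs[0] for s in inputs[1:]):
        raise ValueError("branch results cover different input sets")
    by_branch = {r.branch_id: set(r.kept) for r in branch_results}
    if sorted(by_branch) != [1, 2, 3, 4, 5, 6]:
        raise ValueError("need exactly one result per branch 1-6")
    union = sorted(set().union(*by_branch.values()))
    membership = {
        pid: tuple(pid in by_branch[b] for b in range(1, 7)) for pid in union
    }
    return CandidateSet(union_ids=union, membership=membership)
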