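import random

import pytest

from adscreen.base_filters import apply_base_algorithm
from adscreen.branch_algorithms import (
    assemble_candidates, branch_1_documented_negative_antibodies,
    branch_2_no_outpatient_insulin, branch_3_t2d_specific_med,
    branch_4_t2d_med_or_metformin, branch_5_t1d_ruled_out,
    branch_6_not_confident_t1d, run_all_branches, BranchResult,
)
from tests.conftest import make_patient


class TestBranchPredicates:
    def test_documented_negative_antibodies_kept(self):
        p = make_patient(antibodies=(("GAD65", "negative"),))
        assert branch_1_documented_negative_antibodies([p]).kept == [p.patient_id]

    def test_untested_antibodies_excluded(self):
        p = make_patient()
        assert branch_1_documented_negative_antibodies([p]).kept == []

    def test_empty_input_gives_empty_result(self):
        res = branch_1_documented_negative_antibodies([])
        assert res.kept == [] and res.excluded == set()

    def test_outpatient_insulin_excluded(self):
        p = make_patient(drugs=(("insulin glargine", "insulin", "outpatient"),))
        assert branch_2_no_outpatient_insulin([p]).kept == []

    def test_inpatient_only_insulin_kept(self):
        p = make_patient(drugs=(("insulin regular", "insulin", "inpatient"),))
        assert branch_2_no_outpatient_insulin([p]).kept == [p.patient_id]

    def test_no_medications_kept_by_branch_2(self):
        assert branch_2_no_outpatient_insulin([make_patient()]).kept == ["P1"]

    def test_sulfonylurea_satisfies_t2d_specific(self):
        p = make_patient(drugs=(("glipizide", "sulfonylurea", "outpatient"),))
        assert branch_3_t2d_specific_med([p]).kept == [p.patient_id]

    def test_metformin_alone_is_not_t2d_specific(self):
        p = make_patient(drugs=(("metformin", "metformin", "outpatient"),))
        assert branch_3_t2d_specific_med([p]).kept == []
        assert branch_4_t2d_med_or_metformin([p]).kept == [p.patient_id]

    def test_diet_controlled_excluded_by_both_medication_branches(self):
        p = make_patient()
        assert branch_3_t2d_specific_med([p]).kept == []
        assert branch_4_t2d_med_or_metformin([p]).kept == []

    def test_ml_flag_branches(self):
        ruled = make_patient(pid="A", ruled_out=True)
        not_ruled = make_patient(pid="B", ruled_out=False)
        confident = make_patient(pid="C", ruled_out=False, high_ppv=True)
        patients = [ruled, not_ruled, confident]
        assert branch_5_t1d_ruled_out(patients).kept == ["A"]
        assert branch_6_not_confident_t1d(patients).kept == ["A", "B"]


def random_mini_cohort(rng):
    """Cheap random patients exercising every predicate dimension."""
    patients = []
    for i in range(rng.randint(2, 8)):
        high_ppv = rng.random() < 0.3
        drugs = []
        if rng.random() < 0.5:
            drugs.append(("insulin glargine", "insulin",
                          rng.choice(["outpatient", "inpatient"])))
        if rng.random() < 0.4:
            drugs.append(("metformin", "metformin", "outpatient"))
        if rng.random() < 0.4:
            drugs.append(("glipizide", "sulfonylurea", "outpatient"))
        antibodies = ()
        if rng.random() < 0.5:
            antibodies = (("GAD65", "negative"),)
        patients.append(make_patient(
            pid=f"R{i}", high_ppv=high_ppv,
            ruled_out=(not high_ppv) and rng.random() < 0.7,
            drugs=tuple(drugs), antibodies=antibodies))
    return patients


class TestStructuralLaws:
    def test_branch_3_subset_of_branch_4_on_random_cohorts(self):
        rng = random.Random(0)
        for _ in range(1000):
            patients = random_mini_cohort(rng)
            assert set(branch_3_t2d_specific_med(patients).kept) <= set(
                branch_4_t2d_med_or_metformin(patients).kept)

    def test_branch_5_subset_of_branch_6_on_random_cohorts(self):
        rng = random.Random(1)
        for _ in range(1000):
            patients = random_mini_cohort(rng)
            assert set(branch_5_t1d_ruled_out(patients).kept) <= set(
                branch_6_not_confident_t1d(patients).kept)

    def test_branches_partition_their_input(self):
        rng = random.Random(2)
        for _ in range(200):
            patients = random_mini_cohort(rng)
            ids = {p.patient_id for p in patients}
            for res in run_all_branches(patients):
                assert set(res.kept) | res.excluded == ids
                assert not set(res.kept) & res.excluded

    def test_order_invariance_and_idempotence(self):
        rng = random.Random(3)
        patients = random_mini_cohort(rng)
        shuffled = list(patients)
        rng.shuffle(shuffled)
        for fwd, rev in zip(run_all_branches(patients),
                            run_all_branches(shuffled)):
            assert fwd.kept == rev.kept
        res = branch_2_no_outpatient_insulin(patients)
        kept_patients = [p for p in patients if p.patient_id in res.kept]
        again = branch_2_no_outpatient_insulin(kept_patients)
        assert again.kept == res.kept and not again.excluded


class TestAssembly:
    def test_union_and_membership_rows(self):
        results = [
            BranchResult(1, kept=["A"], excluded={"B"}),
            BranchResult(2, kept=["B"], excluded={"A"}),
            BranchResult(3, kept=["A"], excluded={"B"}),
            BranchResult(4, kept=[], excluded={"A", "B"}),
            BranchResult(5, kept=[], excluded={"A", "B"}),
            BranchResult(6, kept=[], excluded={"A", "B"}),
        ]
        cands = assemble_candidates(results)
        assert cands.union_ids == ["A", "B"]
        assert cands.membership["A"] == (True, False, True, False, False, False)
        assert cands.membership["B"] == (False, True, False, False, False, False)

    def test_identical_branches_union_to_same_set(self):
        results = [BranchResult(b, kept=["X", "Y"], excluded=set())
                   for b in range(1, 7)]
        assert assemble_candidates(results).union_ids == ["X", "Y"]

    def test_mismatched_inputs_rejected(self):
        results = [BranchResult(b, kept=["A"], excluded=set())
                   for b in range(1, 6)]
        results.append(BranchResult(6, kept=["Z"], excluded=set()))
        with pytest.raises(ValueError, match="different input"):
            assemble_candidates(results)

    def test_union_matches_per_patient_predicate_reevaluation(self, mid_cohort):
        """Oracle: re-evaluate all six predicates independently per patient."""
        cohort, _ = mid_cohort
        base = apply_base_algorithm(cohort)
        by_id = cohort.by_id()
        survivors = [by_id[pid] for pid in base.kept]
        cands = assemble_candidates(run_all_branches(survivors))

        expected = set()
        for p in survivors:
            neg_ab = bool(p.antibodies) and all(
                a.result.value == "negative" for a in p.antibodies)
            no_out_insulin = not any(
                m.drug_class.value == "insulin" and m.setting.value == "outpatient"
                for m in p.medications)
            t2d_specific = any(m.drug_class.value in (
                "sulfonylurea", "meglitinide", "TZD", "DPP4i", "AGI",
                "GLP1RA", "SGLT2i") for m in p.medications)
            t2d_or_met = t2d_specific or any(
                m.drug_class.value == "metformin" for m in p.medications)
            if (neg_ab or no_out_insulin or t2d_specific or t2d_or_met
                    or p.ml_flags.ml_t1d_ruled_out
                    or not p.ml_flags.ml_t1d_high_ppv):
                expected.add(p.patient_id)
        assert set(cands.union_ids) == expected
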