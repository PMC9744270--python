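"""Deterministic rule engine approximating expert chart review.

Two classifiers live here.  The first assigns a diabetes-type category to a
condensed case summary: atypical diabetes (AD), a recognisable non-atypical
form (typical T1D/T2D, MODY, autoimmune/LADA, pancreatic-secondary,
steroid-induced), or "need more information" (NMI) when the chart lacks the
facts required to decide.  The second subdivides confirmed AD cases into
ketosis-prone diabetes (KPD, specifically antibody-negative / beta-cell-
positive), mild age-related diabetes (MARD: onset after age 60 with a mild,
non-progressive course — HbA1c consistently under 8% on at most two
non-insulin agents over at least five years), and the residual
insulin-sufficient non-metabolic (ISNM) phenotype.

The type classifier is data-driven: rules are evaluated first-match-wins in
a documented default order, and callers may supply a reordered or edited
rule list.  Every rule carries the chart fields it needs; when a rule's
inputs are undocumented the rule simply cannot fire, and a case that reaches
the end of the positive rules with required fields missing lands in NMI with
the missing fields recorded — never in a not-atypical category.  A
MODY-suspicious presentation (diagnosis before 35 with a multigenerational
family history) without genetic testing is always NMI, since MODY cases are
a subset of the ISNM phenotype and only genetic testing separates them.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .branch_algorithms import CandidateSet
from .ehr_model import (
    Analyte, AntibodyResult, CPeptideStatus, Cohort, DrugClass,
    GeneticTestStatus, PatientRecord, Sex,
)
from .vocab import DIABETES_MED_CLASSES

__all__ = [
    "AntibodyStatus", "Category", "Subtype", "CaseSummary",
    "ClassificationOutcome", "SubtypeConfig", "Rule", "ClassifierRules",
    "default_rules", "summarize_case", "classify_diabetes_type",
    "classify_ad_subtype", "classify_cohort", "CohortClassification",
    "YOUTH_ONSET_CEILING",
]

#: Onset before this age (years) is treated as youth-onset in the rules.
YOUTH_ONSET_CEILING = 20.0

#: Onset before this age combined with multigenerational family history is
#: MODY-suspicious and demands genetic testing before classification.
MODY_SUSPICION_AGE = 35.0


class AntibodyStatus(str, enum.Enum):
    positive = "positive"
    negative_documented = "negative_documented"
    untested = "untested"


class Category(str, enum.Enum):
    AD = "AD"
    NMI = "NMI"
    typical_T1D = "typical_T1D"
    typical_T2D = "typical_T2D"
    MODY = "MODY"
    LADA_autoimmune = "LADA_autoimmune"
    pancreatic_secondary = "pancreatic_secondary"
    steroid_induced = "steroid_induced"


class Subtype(str, enum.Enum):
    KPD = "KPD"
    MARD = "MARD"
    ISNM = "ISNM"
    none = "none"


@dataclass(frozen=True)
class CaseSummary:
    """The condensed chart-review view a classifier consumes."""

    patient_id: str
    sex: Sex = Sex.unknown
    current_age: Optional[float] = None
    age_at_diagnosis: Optional[float] = None
    age_at_diagnosis_is_upper_bound: bool = False
    bmi_range: Optional[tuple[float, float]] = None
    hba1c_range: Optional[tuple[float, float]] = None
    n_noninsulin_dm_meds: int = 0
    uses_insulin_long_term: Optional[bool] = None
    antibody_status: AntibodyStatus = AntibodyStatus.untested
    c_peptide_status: CPeptideStatus = CPeptideStatus.untested
    ketosis_history_adult: Optional[bool] = None
    mody_genetic_test: GeneticTestStatus = GeneticTestStatus.untested
    multigenerational_family_history: Optional[bool] = None
    pancreatic_disease_before_dx: Optional[bool] = None
    chronic_steroid_exposure_at_dx: Optional[bool] = None
    insulin_dependent_from_onset: Optional[bool] = None
    observation_span_years: float = 0.0
    metabolic_features_at_dx: Optional[bool] = None

    def __post_init__(self) -> None:
        for rng in (self.bmi_range, self.hba1c_range):
            if rng is not None and rng[0] > rng[1]:
                raise ValueError(f"range must be ordered min <= max: {rng}")
        if self.n_noninsulin_dm_meds < 0:
            raise ValueError("medication count must be >= 0")


@dataclass
class ClassificationOutcome:
    patient_id: str
    category: Category
    subtype: Subtype = Subtype.none
    fired_rules: list[str] = field(default_factory=list)
    nmi_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.subtype is not Subtype.none) != (self.category is Category.AD):
            raise ValueError("subtype set iff category is AD")
        if bool(self.nmi_reasons) != (self.category is Category.NMI):
            raise ValueError("nmi_reasons nonempty iff category is NMI")


@dataclass(frozen=True)
class SubtypeConfig:
    mard_age_cutoff: float = 60.0       # onset strictly after this age
    mard_hba1c_ceiling: float = 8.0     # max recorded HbA1c strictly below (%)
    mard_max_noninsulin_meds: int = 2
    mard_min_span: float = 5.0          # years of observed mild course
    hba1c_window_years: Optional[float] = None  # None: max over all records

    def __post_init__(self) -> None:
        if min(self.mard_age_cutoff, self.mard_hba1c_ceiling,
               self.mard_min_span) <= 0 or self.mard_max_noninsulin_meds < 0:
            raise ValueError("subtype thresholds must be positive")


# ---------------------------------------------------------------------------
# diabetes-type rules

@dataclass(frozen=True)
class Rule:
    identifier: str
    predicate: Callable[[CaseSummary], bool]
    category: Category


def _onset_age(case: CaseSummary) -> Optional[float]:
    # ages recorded as "X or earlier" are used at their bound value X
    return case.age_at_diagnosis


def _youth_onset_insulin_dependent(case: CaseSummary) -> bool:
    age = _onset_age(case)
    return (age is not None and age < YOUTH_ONSET_CEILING
            and case.insulin_dependent_from_onset is True)


def default_rules() -> list[Rule]:
    """The default first-match-wins rule order for diabetes-type review."""
    return [
        Rule("mody-genetic-positive",
             lambda c: c.mody_genetic_test is GeneticTestStatus.positive,
             Category.MODY),
        Rule("antibody-positive-youth-insulin",
             lambda c: (c.antibody_status is AntibodyStatus.positive
                        and _youth_onset_insulin_dependent(c)),
             Category.typical_T1D),
        Rule("antibody-positive-adult",
             lambda c: c.antibody_status is AntibodyStatus.positive,
             Category.LADA_autoimmune),
        Rule("pancreatic-disease-before-dx",
             lambda c: c.pancreatic_disease_before_dx is True,
             Category.pancreatic_secondary),
        Rule("steroid-exposure-at-dx",
             lambda c: c.chronic_steroid_exposure_at_dx is True,
             Category.steroid_induced),
        Rule("metabolic-features-at-dx",
             lambda c: c.metabolic_features_at_dx is True,
             Category.typical_T2D),
        Rule("youth-onset-insulin-low-cpeptide",
             lambda c: (_youth_onset_insulin_dependent(c)
                        and c.c_peptide_status is CPeptideStatus.low),
             Category.typical_T1D),
    ]


@dataclass
class ClassifierRules:
    rules: list[Rule] = field(default_factory=default_rules)
    #: fields the chart must document before an AD call is allowed; each
    #: entry is a tuple of alternatives, any one of which suffices.
    required_fields: tuple[tuple[str, ...], ...] = (
        ("antibody_status", "c_peptide_status"),
        ("age_at_diagnosis",),
        ("metabolic_features_at_dx",),
    )

    def __post_init__(self) -> None:
        names = [r.identifier for r in self.rules]
        if len(names) != len(set(names)):
            raise ValueError("rule identifiers must be unique")


def _field_documented(case: CaseSummary, name: str) -> bool:
    value = getattr(case, name)
    if name in ("antibody_status", "c_peptide_status"):
        return value not in (AntibodyStatus.untested, CPeptideStatus.untested)
    if name == "mody_genetic_test":
        return value is not GeneticTestStatus.untested
    return value is not None


def classify_diabetes_type(
        case: CaseSummary,
        rules: Optional[ClassifierRules] = None) -> ClassificationOutcome:
    """Assign AD / not-atypical subcategory / NMI to one case summary.

    Rules fire first-match-wins; a case that no positive rule claims becomes
    AD only if every required chart field is documented, otherwise NMI with
    the missing fields listed.  The MODY-suspicion check (young onset plus
    multigenerational family history without genetic testing) precedes the
    completeness check because only MODY testing can resolve such cases.
    """
    rules = rules or ClassifierRules()
    fired: list[str] = []
    for rule in rules.rules:
        fired.append(rule.identifier)
        if rule.predicate(case):
            return ClassificationOutcome(
                case.patient_id, rule.category, fired_rules=fired)

    age = _onset_age(case)
    if (age is not None and age < MODY_SUSPICION_AGE
            and case.multigenerational_family_history is True
            and case.mody_genetic_test is GeneticTestStatus.untested):
        fired.append("mody-suspicion-needs-testing")
        return ClassificationOutcome(
            case.patient_id, Category.NMI, fired_rules=fired,
            nmi_reasons=["mody_genetic_test"])

    missing = ["|".join(group) for group in rules.required_fields
               if not any(_field_documented(case, name) for name in group)]
    if missing:
        fired.append("incomplete-information")
        return ClassificationOutcome(
            case.patient_id, Category.NMI, fired_rules=fired,
            nmi_reasons=missing)

    fired.append("default-atypical")
    return ClassificationOutcome(
        case.patient_id, Category.AD,
        subtype=classify_ad_subtype(case), fired_rules=fired)


def classify_ad_subtype(case: CaseSummary,
                        config: SubtypeConfig = SubtypeConfig()) -> Subtype:
    """Subdivide a confirmed-AD case into KPD, MARD, or ISNM.

    KPD (antibody-negative, beta-cell-positive): a history of ketosis in
    adulthood without autoimmunity or long-term insulin need.  MARD: onset
    strictly after the age cutoff with every recorded HbA1c under the
    ceiling, at most two non-insulin agents, no long-term insulin, observed
    over at least the minimum span.  Everything else is ISNM.  Onset ages
    recorded only as an upper bound are evaluated at the bound value.
    """
    if (case.ketosis_history_adult is True
            and case.antibody_status is not AntibodyStatus.positive
            and case.uses_insulin_long_term is not True):
        return Subtype.KPD
    age = _onset_age(case)
    if (age is not None and age > config.mard_age_cutoff
            and case.hba1c_range is not None
            and case.hba1c_range[1] < config.mard_hba1c_ceiling
            and case.n_noninsulin_dm_meds <= config.mard_max_noninsulin_meds
            and case.uses_insulin_long_term is not True
            and case.observation_span_years >= config.mard_min_span):
        return Subtype.MARD
    return Subtype.ISNM


# ---------------------------------------------------------------------------
# summarisation from raw patient records

def summarize_case(patient: PatientRecord,
                   reference_year: Optional[int] = None) -> CaseSummary:
    """Condense a longitudinal record into the view the classifiers consume.

    Lab and BMI ranges run over all recorded values; the non-insulin
    medication count is the number of distinct glucose-lowering drug classes
    excluding insulin (steroids and non-diabetes drugs never count); the
    observation span is the number of years between the first and last dated
    entry of any kind.  Current age is computed against ``reference_year``,
    defaulting to the latest record date's year.
    """
    dates = ([l.date for l in patient.labs] + [b.date for b in patient.bmi]
             + [m.date for m in patient.medications]
             + [d.date for d in patient.diagnoses]
             + [a.date for a in patient.antibodies])
    span = ((max(dates) - min(dates)).days / 365.25) if dates else 0.0
    if reference_year is None:
        reference_year = max(dates).year if dates else None
    current_age = (None if reference_year is None
                   else float(reference_year - patient.birth_year))

    bmis = [b.value for b in patient.bmi]
    a1cs = [l.value for l in patient.labs if l.analyte is Analyte.HBA1C]

    med_classes = {m.drug_class for m in patient.medications
                   if m.drug_class in DIABETES_MED_CLASSES}
    n_noninsulin = len(med_classes - {DrugClass.insulin})

    if any(a.result is AntibodyResult.positive for a in patient.antibodies):
        antibody_status = AntibodyStatus.positive
    elif patient.antibodies:
        antibody_status = AntibodyStatus.negative_documented
    else:
        antibody_status = AntibodyStatus.untested

    chart = patient.chart
    uses_insulin = chart.long_term_insulin_use
    if uses_insulin is None and DrugClass.insulin not in med_classes:
        uses_insulin = False  # no documented exposure anywhere in the record

    if chart.bmi_at_diagnosis is not None:
        metabolic_at_dx: Optional[bool] = chart.bmi_at_diagnosis > 30.0
    else:
        metabolic_at_dx = None

    return CaseSummary(
        patient_id=patient.patient_id,
        sex=patient.sex,
        current_age=current_age,
        age_at_diagnosis=chart.age_at_diagnosis,
        age_at_diagnosis_is_upper_bound=chart.age_at_diagnosis_is_upper_bound,
        bmi_range=(min(bmis), max(bmis)) if bmis else None,
        hba1c_range=(min(a1cs), max(a1cs)) if a1cs else None,
        n_noninsulin_dm_meds=n_noninsulin,
        uses_insulin_long_term=uses_insulin,
        antibody_status=antibody_status,
        c_peptide_status=chart.c_peptide_status,
        ketosis_history_adult=chart.ketosis_history_adult,
        mody_genetic_test=chart.mody_genetic_test,
        multigenerational_family_history=chart.multigenerational_family_history,
        pancreatic_disease_before_dx=chart.pancreatic_disease_before_dx,
        chronic_steroid_exposure_at_dx=chart.chronic_steroid_exposure_at_dx,
        insulin_dependent_from_onset=chart.insulin_dependent_from_onset,
        observation_span_years=span,
        metabolic_features_at_dx=metabolic_at_dx,
    )


# ---------------------------------------------------------------------------
# cohort-level classification

@dataclass
class CohortClassification:
    outcomes: dict[str, ClassificationOutcome]
    category_tally: Counter
    subtype_tally: Counter
    branch_yield: dict[int, Optional[float]]  # AD kept / branch kept

    @property
    def n_ad(self) -> int:
        return self.category_tally.get(Category.AD, 0)


def classify_cohort(candidates: CandidateSet, cohort: Cohort,
                    rules: Optional[ClassifierRules] = None,
                    subtype_config: SubtypeConfig = SubtypeConfig(),
                    reference_year: Optional[int] = None
                    ) -> CohortClassification:
    """Classify every candidate patient and tally categories and yields.

    Branch yield is the fraction of each branch's kept patients confirmed AD
    (``None`` for an empty branch).
    """
    by_id = cohort.by_id()
    unknown = [pid for pid in candidates.union_ids if pid not in by_id]
    if unknown:
        raise ValueError(f"candidate ids absent from cohort: {unknown[:5]}")

    outcomes: dict[str, ClassificationOutcome] = {}
    for pid in candidates.union_ids:
        case = summarize_case(by_id[pid], reference_year=reference_year)
        outcome = classify_diabetes_type(case, rules)
        if outcome.category is Category.AD:
            outcome.subtype = classify_ad_subtype(case, subtype_config)
        outcomes[pid] = outcome

    category_tally = Counter(o.category for o in outcomes.values())
    subtype_tally = Counter(o.subtype for o in outcomes.values()
                            if o.category is Category.AD)
    branch_yield: dict[int, Optional[float]] = {}
    for b in range(1, 7):
        kept = [pid for pid in candidates.union_ids
                if candidates.membership[pid][b - 1]]
        if not kept:
            branch_yield[b] = None
        else:
            n_ad = sum(outcomes[pid].category is Category.AD for pid in kept)
            branch_yield[b] = n_ad / len(kept)
    return CohortClassification(outcomes, category_tally, subtype_tally,
                                branch_yield)
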