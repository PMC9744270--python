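"""Packaged case-roster fixture: the 16 published atypical-diabetes cases.

The roster transcribes the published characteristics of the sixteen
confirmed atypical cases — sex, current age, age at diagnosis (two recorded
only as "X or earlier" upper bounds), BMI and HbA1c ranges, treatment
regimen, and family history — plus the adult-ketosis indicator, which is
true only for the single case whose narrative documents ketosis (the
antibody-negative, beta-cell-positive ketosis-prone case).  The published
phenotypic-pattern labels are carried separately so tests can hold them out.

Fixture conventions (not stated in the source table): every confirmed case
carries documented negative antibody testing (confirmation of the atypical
phenotype required antibody evidence); C-peptide is documented
normal-or-high only for the ketosis-prone case (beta-cell positive);
metabolic features at diagnosis are documented absent (all BMI ranges are
non-obese); the observation span is the interval from diagnosis to the
current age.  A family history involving a parent or uncle is coded as
multigenerational.
"""

from __future__ import annotations

import importlib.resources
from typing import Optional

import pandas as pd

from .chart_classification import AntibodyStatus, CaseSummary
from .ehr_model import CareSetting, CPeptideStatus, RaceEthnicity, Sex
from .synthetic_cohort import PlantSpec

__all__ = ["load_case_roster", "case_roster_plant_specs", "case_roster_dataframe"]


def case_roster_dataframe() -> pd.DataFrame:
    ref = importlib.resources.files("adscreen.data") / "case_roster.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, dtype=str, keep_default_na=False)


def _to_bool(raw: str) -> bool:
    return raw.strip().lower() == "true"


def _row_to_summary(row) -> CaseSummary:
    from .vocab import DIABETES_MED_CLASSES, classify_drug
    from .ehr_model import DrugClass

    drugs = [d for d in row.regimen.split(";") if d]
    classes = {classify_drug(d) for d in drugs} & DIABETES_MED_CLASSES
    n_noninsulin = len(classes - {DrugClass.insulin})

    current_age = float(row.current_age)
    age_dx = float(row.age_at_diagnosis)
    hba1c = (None if row.hba1c_min == "" else
             (float(row.hba1c_min), float(row.hba1c_max)))
    return CaseSummary(
        patient_id=row.case_id,
        sex=Sex(row.sex),
        current_age=current_age,
        age_at_diagnosis=age_dx,
        age_at_diagnosis_is_upper_bound=_to_bool(row.age_is_upper_bound),
        bmi_range=(float(row.bmi_min), float(row.bmi_max)),
        hba1c_range=hba1c,
        n_noninsulin_dm_meds=n_noninsulin,
        uses_insulin_long_term=_to_bool(row.long_term_insulin),
        antibody_status=AntibodyStatus.negative_documented,
        c_peptide_status=CPeptideStatus(row.c_peptide_status),
        ketosis_history_adult=_to_bool(row.ketosis_history_adult),
        multigenerational_family_history=_to_bool(
            row.multigenerational_family_history),
        pancreatic_disease_before_dx=False,
        chronic_steroid_exposure_at_dx=False,
        insulin_dependent_from_onset=False,
        observation_span_years=current_age - age_dx,
        metabolic_features_at_dx=False,
    )


def load_case_roster() -> tuple[list[CaseSummary], dict[str, str]]:
    """The 16 fixture cases and their held-out published pattern labels."""
    df = case_roster_dataframe()
    cases = [_row_to_summary(row) for row in df.itertuples(index=False)]
    labels = {row.case_id: row.pattern_label
              for row in df.itertuples(index=False)}
    return cases, labels


def case_roster_plant_specs() -> list[PlantSpec]:
    """The fixture cases as plantable specs with their actual regimens."""
    df = case_roster_dataframe()
    specs = []
    for row in df.itertuples(index=False):
        drugs = tuple((d, CareSetting.outpatient)
                      for d in row.regimen.split(";") if d)
        specs.append(PlantSpec(
            summary=_row_to_summary(row),
            race=RaceEthnicity(row.race),
            drugs=drugs or None,
        ))
    return specs
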