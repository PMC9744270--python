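import datetime

import pytest

from adscreen.ehr_model import (
    Analyte, Antibody, AntibodyResult, AntibodyTest, BMIMeasurement,
    CareSetting, Cohort, DrugClass, LabResult, MedicationExposure,
    MLPhenotypeFlags, PatientRecord,
)
from adscreen.synthetic_cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-patient synthetic cohort with its latent-truth table."""
    return generate_cohort(default_config(2_000, seed=7))


@pytest.fixture(scope="session")
def mid_cohort():
    """10,000-patient synthetic cohort used for oracle-equivalence checks."""
    return generate_cohort(default_config(10_000, seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """20,000-patient cohort for ML-flag calibration checks."""
    return generate_cohort(default_config(20_000, seed=3))


def make_patient(pid="P1", ml_t2d=True, ruled_out=True, high_ppv=False,
                 hdl=(), tg=(), hba1c=(), bmi=(22.0, 23.0, 24.0),
                 drugs=(), antibodies=(), codes=()):
    """Hand-rolled patient builder for predicate-level tests."""
    day = datetime.date(2018, 1, 1)
    labs = ([LabResult(Analyte.HDL, v, day) for v in hdl]
            + [LabResult(Analyte.TG, v, day) for v in tg]
            + [LabResult(Analyte.HBA1C, v, day) for v in hba1c])
    meds = [MedicationExposure(name, DrugClass(cls), CareSetting(setting), day)
            for name, cls, setting in drugs]
    abs_ = [AntibodyTest(Antibody(ab), AntibodyResult(res), day)
            for ab, res in antibodies]
    from adscreen.ehr_model import DiagnosisCode
    return PatientRecord(
        patient_id=pid,
        labs=labs,
        bmi=[BMIMeasurement(v, day) for v in bmi],
        medications=meds,
        antibodies=abs_,
        diagnoses=[DiagnosisCode(c, day) for c in codes],
        ml_flags=MLPhenotypeFlags(ml_t2d=ml_t2d, ml_t1d_high_ppv=high_ppv,
                                  ml_t1d_ruled_out=ruled_out),
    )


@pytest.fixture
def patient_factory():
    return make_patient
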