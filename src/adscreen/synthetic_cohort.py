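"""Seeded generator of biobank-like cohorts with latent diabetes types.

The generator emulates the population structure the screening algorithms
were designed for: a large, mostly non-diabetic biobank containing ~6.2%
ML-flagged T2D and ~0.6% ML-flagged T1D, with rare planted atypical cases.
Every patient is drawn from a latent *archetype* (non-diabetic, typical T2D,
typical T1D, LADA, MODY-like, or one of three atypical-diabetes phenotypes)
that fixes the distributions of its longitudinal labs, BMI trajectory,
medication exposures, antibody-testing behaviour, and chart-review facts.
Lab trajectories are i.i.d. draws around archetype means — the downstream
filters read only extrema and counts, so temporal autocorrelation would add
complexity without changing any decision.

Atypical-diabetes archetypes are generated to satisfy the base algorithm by
construction (all HDL >= 50 mg/dL, TG <= 150, BMI <= 30 with at least three
measurements, no cystic fibrosis codes, no positive antibody), so that an AD
patient with favourable ML flags is guaranteed to survive the base filter.

ML-flag error structure
-----------------------
Flags are drawn by inverting the confusion structure implied by the stated
(sensitivity, PPV/NPV) pairs against the latent truth.  Writing ``p`` for
the truth prevalence in the flag's reference population, ``s`` for
sensitivity and ``PPV`` for the positive predictive value, the
false-positive rate among truth-negatives follows from

    PPV = s*p / (s*p + fp*(1-p))   =>   fp = s*p*(1-PPV) / (PPV*(1-p)).

The T2D flag uses the whole cohort as its reference population (truth = any
clinically T2D-appearing archetype).  The two T1D flags use the *diabetic
subpopulation* as their reference population: at a whole-cohort T1D
prevalence of ~0.6%, a rule-out NPV of 0.99 would be below the no-skill
baseline of 99.4% and is unattainable, whereas among patients with diabetes
(T1D share ~9%) it is a meaningful, attainable target — matching how such
flags are validated, on charts of patients known to have diabetes.  For the
rule-out flag the coverage ``r_n`` (probability a truth-negative is ruled
out) is a free parameter and the truth-positive rule-out rate solves

    NPV = a/(a+b),  a = (1-p)*(1-fp)*r_n,  b = p*(1-s)*r_t
    =>  r_t = a*(1-NPV) / (NPV * p * (1-s)).

Non-diabetic patients trivially receive ``ml_t1d_ruled_out=True``.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .base_filters import BaseFilterConfig
from .chart_classification import AntibodyStatus, CaseSummary
from .ehr_model import (
    Analyte, Antibody, AntibodyResult, AntibodyTest, BMIMeasurement,
    CareSetting, ChartFacts, Cohort, CPeptideStatus, DiagnosisCode, DrugClass,
    GeneticTestStatus, LabResult, MedicationExposure, MLPhenotypeFlags,
    PatientRecord, RaceEthnicity, Sex,
)
from .vocab import classify_drug

__all__ = [
    "ArchetypeName", "LabDistribution", "MedicationPolicy", "AntibodyPolicy",
    "ChartFactPolicy", "ArchetypeSpec", "MLFlagSpec", "GeneratorConfig",
    "default_archetypes", "default_config", "generate_cohort",
    "PlantSpec", "plant_cases",
]


class ArchetypeName(str, enum.Enum):
    nondiabetic = "nondiabetic"
    typical_T2D = "typical_T2D"
    typical_T1D = "typical_T1D"
    LADA = "LADA"
    MODY_like = "MODY_like"
    AD_KPD = "AD_KPD"
    AD_MARD = "AD_MARD"
    AD_ISNM = "AD_ISNM"


AD_ARCHETYPES = frozenset(
    {ArchetypeName.AD_KPD, ArchetypeName.AD_MARD, ArchetypeName.AD_ISNM})

#: archetypes whose clinical picture resembles T2D (the ML T2D truth set)
T2D_LIKE = AD_ARCHETYPES | {ArchetypeName.typical_T2D, ArchetypeName.LADA,
                            ArchetypeName.MODY_like}


@dataclass(frozen=True)
class LabDistribution:
    mean: float
    sd: float
    per_year: float          # expected measurements per observation year
    clip: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.sd < 0 or self.per_year < 0:
            raise ValueError("sd and per_year must be non-negative")


@dataclass(frozen=True)
class MedicationPolicy:
    #: (drug_name, setting, probability of any exposure)
    exposures: tuple[tuple[str, CareSetting, float], ...] = ()


@dataclass(frozen=True)
class AntibodyPolicy:
    p_tested: float = 0.0
    p_positive: float = 0.0   # given tested


@dataclass(frozen=True)
class ChartFactPolicy:
    age_at_dx: Optional[tuple[float, float]] = None         # mean, sd
    age_at_dx_clip: Optional[tuple[float, float]] = None
    p_ketosis: float = 0.0
    p_c_peptide_low: float = 0.0
    p_c_peptide_tested: float = 0.0
    p_mody_positive: float = 0.0
    p_mody_tested: float = 0.0
    p_family_history: float = 0.2
    p_multigenerational: float = 0.0
    p_pancreatic: float = 0.0
    p_steroid_at_dx: float = 0.0
    p_insulin_from_onset: float = 0.0
    p_long_term_insulin: float = 0.0


@dataclass(frozen=True)
class ArchetypeSpec:
    name: ArchetypeName
    prevalence: float
    labs: dict[Analyte, LabDistribution]
    bmi: LabDistribution
    medications: MedicationPolicy = MedicationPolicy()
    antibody: AntibodyPolicy = AntibodyPolicy()
    chart: ChartFactPolicy = ChartFactPolicy()
    #: constrain draws so the patient passes the base algorithm
    constrained_base_pass: bool = False
    p_cf_code: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")


@dataclass(frozen=True)
class MLFlagSpec:
    """Stated operating characteristics of the curated-phenotype flags."""

    t1d_flag_ppv: float = 0.95
    t1d_flag_sensitivity: float = 0.78
    t1d_ruleout_npv: float = 0.99
    t1d_ruleout_coverage: float = 0.97   # r_n in the module docstring algebra
    t2d_flag_ppv: float = 0.90
    t2d_flag_sensitivity: float = 0.88

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int
    seed: int
    archetypes: tuple[ArchetypeSpec, ...]
    ml_flags: MLFlagSpec = MLFlagSpec()
    missingness: float = 0.13     # per chart-fact field nulling probability
    start_year: int = 2010
    reference_year: int = 2020

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(a.prevalence for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype prevalences must sum to 1, got {total}")
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must be in [0, 1]")


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    """Biobank-like default composition.

    ML-flagged T2D works out to ~6.2% of the cohort (matching the published
    biobank composition) given a latent clinically-T2D-appearing prevalence
    of ~6.4% and the default flag sensitivity/PPV; latent T1D is 0.63%; each
    atypical phenotype is planted at 0.014%, the order of magnitude of the
    confirmed-case rate, and can be raised for statistical power.
    """
    def labd(mean, sd, per_year, clip=None):
        return LabDistribution(mean, sd, per_year, clip)

    return (
        ArchetypeSpec(
            ArchetypeName.nondiabetic, 0.92968,
            labs={Analyte.HDL: labd(55, 14, 0.6), Analyte.TG: labd(120, 45, 0.6)},
            bmi=labd(27.5, 5.0, 1.2),
            antibody=AntibodyPolicy(0.005, 0.02),
            chart=ChartFactPolicy(p_family_history=0.25),
            p_cf_code=0.001,
        ),
        ArchetypeSpec(
            ArchetypeName.typical_T2D, 0.05860,
            labs={Analyte.HDL: labd(42, 9, 1.2), Analyte.TG: labd(190, 70, 1.2),
                  Analyte.HBA1C: labd(7.6, 1.3, 2.0, clip=(4.5, 15.0))},
            bmi=labd(32.5, 4.5, 1.8),
            medications=MedicationPolicy((
                ("metformin", CareSetting.outpatient, 0.90),
                ("glipizide", CareSetting.outpatient, 0.40),
                ("sitagliptin", CareSetting.outpatient, 0.20),
                ("insulin glargine", CareSetting.outpatient, 0.30),
            )),
            antibody=AntibodyPolicy(0.08, 0.03),
            chart=ChartFactPolicy(
                age_at_dx=(55, 10), age_at_dx_clip=(25, 85),
                p_ketosis=0.02, p_c_peptide_tested=0.10,
                p_family_history=0.5, p_multigenerational=0.15,
                p_steroid_at_dx=0.02, p_long_term_insulin=0.30),
            p_cf_code=0.001,
        ),
        ArchetypeSpec(
            ArchetypeName.typical_T1D, 0.00630,
            labs={Analyte.HDL: labd(58, 12, 1.0), Analyte.TG: labd(100, 35, 1.0),
                  Analyte.HBA1C: labd(7.9, 1.2, 2.5, clip=(4.5, 15.0))},
            bmi=labd(24.5, 3.0, 1.5),
            medications=MedicationPolicy((
                ("insulin lispro", CareSetting.outpatient, 0.97),
                ("metformin", CareSetting.outpatient, 0.05),
            )),
            antibody=AntibodyPolicy(0.60, 0.75),
            chart=ChartFactPolicy(
                age_at_dx=(15, 8), age_at_dx_clip=(1, 40),
                p_ketosis=0.30, p_c_peptide_low=0.85, p_c_peptide_tested=0.50,
                p_family_history=0.15, p_insulin_from_onset=0.90,
                p_long_term_insulin=0.97),
        ),
        ArchetypeSpec(
            ArchetypeName.LADA, 0.00400,
            labs={Analyte.HDL: labd(50, 10, 1.0), Analyte.TG: labd(130, 40, 1.0),
                  Analyte.HBA1C: labd(7.4, 1.0, 2.0, clip=(4.5, 15.0))},
            bmi=labd(26.0, 3.0, 1.5),
            medications=MedicationPolicy((
                ("metformin", CareSetting.outpatient, 0.70),
                ("insulin glargine", CareSetting.outpatient, 0.60),
            )),
            antibody=AntibodyPolicy(0.70, 0.90),
            chart=ChartFactPolicy(
                age_at_dx=(45, 10), age_at_dx_clip=(30, 75),
                p_c_peptide_low=0.40, p_c_peptide_tested=0.40,
                p_family_history=0.3, p_long_term_insulin=0.60),
        ),
        ArchetypeSpec(
            ArchetypeName.MODY_like, 0.00100,
            labs={Analyte.HDL: labd(60, 10, 1.0), Analyte.TG: labd(100, 30, 1.0),
                  Analyte.HBA1C: labd(6.8, 0.8, 2.0, clip=(4.5, 15.0))},
            bmi=labd(23.0, 2.5, 1.5),
            medications=MedicationPolicy((
                ("glipizide", CareSetting.outpatient, 0.50),
                ("metformin", CareSetting.outpatient, 0.50),
            )),
            antibody=AntibodyPolicy(0.40, 0.02),
            chart=ChartFactPolicy(
                age_at_dx=(22, 6), age_at_dx_clip=(10, 34),
                p_c_peptide_tested=0.30, p_mody_tested=0.30,
                p_mody_positive=0.60, p_family_history=0.9,
                p_multigenerational=0.85),
        ),
        ArchetypeSpec(
            ArchetypeName.AD_KPD, 0.00014,
            labs={Analyte.HDL: labd(68, 9, 1.2, clip=(50, 120)),
                  Analyte.TG: labd(95, 25, 1.2, clip=(40, 150)),
                  Analyte.HBA1C: labd(7.2, 1.4, 2.0, clip=(4.5, 12.0))},
            bmi=labd(24.5, 1.8, 1.8, clip=(17, 30)),
            medications=MedicationPolicy((
                ("metformin", CareSetting.outpatient, 0.90),
            )),
            antibody=AntibodyPolicy(0.80, 0.0),
            chart=ChartFactPolicy(
                age_at_dx=(40, 6), age_at_dx_clip=(35, 58),
                p_ketosis=1.0, p_c_peptide_tested=0.80,
                p_family_history=0.4),
            constrained_base_pass=True,
        ),
        ArchetypeSpec(
            ArchetypeName.AD_MARD, 0.00014,
            labs={Analyte.HDL: labd(72, 9, 1.2, clip=(50, 120)),
                  Analyte.TG: labd(90, 25, 1.2, clip=(40, 150)),
                  Analyte.HBA1C: labd(6.3, 0.5, 2.0, clip=(5.0, 7.8))},
            bmi=labd(23.0, 2.0, 1.8, clip=(16, 30)),
            medications=MedicationPolicy((
                ("metformin", CareSetting.outpatient, 0.70),
                ("glipizide", CareSetting.outpatient, 0.20),
            )),
            antibody=AntibodyPolicy(0.70, 0.0),
            chart=ChartFactPolicy(
                age_at_dx=(68, 5), age_at_dx_clip=(61, 85),
                p_c_peptide_tested=0.60, p_family_history=0.3),
            constrained_base_pass=True,
        ),
        ArchetypeSpec(
            ArchetypeName.AD_ISNM, 0.00014,
            labs={Analyte.HDL: labd(70, 9, 1.2, clip=(50, 120)),
                  Analyte.TG: labd(92, 25, 1.2, clip=(40, 150)),
                  Analyte.HBA1C: labd(7.1, 1.0, 2.0, clip=(4.5, 12.0))},
            bmi=labd(23.5, 2.0, 1.8, clip=(16, 30)),
            medications=MedicationPolicy((
                ("metformin", CareSetting.outpatient, 0.80),
                ("glimepiride", CareSetting.outpatient, 0.30),
            )),
            antibody=AntibodyPolicy(0.70, 0.0),
            chart=ChartFactPolicy(
                age_at_dx=(50, 8), age_at_dx_clip=(36, 60),
                p_c_peptide_tested=0.60, p_family_history=0.35),
            constrained_base_pass=True,
        ),
    )


def default_config(n_patients: int, seed: int, **overrides) -> GeneratorConfig:
    return GeneratorConfig(n_patients=n_patients, seed=seed,
                           archetypes=default_archetypes(), **overrides)


# ---------------------------------------------------------------------------
# flag-rate algebra

def _false_positive_rate(sens: float, prev: float, ppv: float) -> float:
    fp = sens * prev * (1 - ppv) / (ppv * (1 - prev))
    if fp > 1:
        raise ValueError(
            f"flag PPV {ppv} unattainable at prevalence {prev:.4f}")
    return fp


def _ruleout_rate_for_positives(sens: float, prev: float, npv: float,
                                fp: float, coverage: float) -> float:
    a = (1 - prev) * (1 - fp) * coverage
    r_t = a * (1 - npv) / (npv * prev * (1 - sens))
    if r_t > 1:
        raise ValueError(
            f"rule-out NPV {npv} unattainable at prevalence {prev:.4f} "
            f"with coverage {coverage}")
    return r_t


# ---------------------------------------------------------------------------
# generation

def _draw_labs(rng: np.random.Generator, dist: LabDistribution,
               years: float, dates: "_DateSampler") -> list[tuple[float, datetime.date]]:
    n = rng.poisson(dist.per_year * years)
    if n == 0:
        return []
    values = rng.normal(dist.mean, dist.sd, size=n)
    if dist.clip is not None:
        values = np.clip(values, dist.clip[0], dist.clip[1])
    values = np.maximum(values, 0.1)   # lab values are positive
    return [(float(v), dates.draw()) for v in values]


class _DateSampler:
    def __init__(self, rng: np.random.Generator,
                 start: datetime.date, end: datetime.date) -> None:
        self.rng = rng
        self.start = start
        self.span_days = (end - start).days

    def draw(self) -> datetime.date:
        return self.start + datetime.timedelta(
            days=int(self.rng.integers(0, self.span_days + 1)))


def _opt(rng: np.random.Generator, p_true: float,
         missing: float) -> Optional[bool]:
    if rng.random() < missing:
        return None
    return bool(rng.random() < p_true)


def _generate_patient(rng: np.random.Generator, pid: str, spec: ArchetypeSpec,
                      config: GeneratorConfig) -> PatientRecord:
    ref = datetime.date(config.reference_year, 6, 30)
    start = datetime.date(config.start_year, 1, 1) + datetime.timedelta(
        days=int(rng.integers(0, 720)))
    years = (ref - start).days / 365.25
    dates = _DateSampler(rng, start, ref)

    sex = Sex.F if rng.random() < 0.55 else Sex.M
    race = RaceEthnicity(
        str(rng.choice(["White", "Black", "Hispanic", "Asian", "Other", "Unknown"],
                       p=[0.845, 0.048, 0.025, 0.027, 0.025, 0.03])))

    chart_policy = spec.chart
    age_now = float(np.clip(rng.normal(57, 17), 20, 95))
    if chart_policy.age_at_dx is not None:
        m, s = chart_policy.age_at_dx
        age_dx = float(rng.normal(m, s))
        if chart_policy.age_at_dx_clip is not None:
            age_dx = float(np.clip(age_dx, *chart_policy.age_at_dx_clip))
        age_dx = round(age_dx)
        age_now = max(age_now, age_dx + rng.uniform(1, 15))
    else:
        age_dx = None
    birth_year = config.reference_year - int(round(age_now))

    labs: list[LabResult] = []
    for analyte, dist in spec.labs.items():
        for value, date in _draw_labs(rng, dist, years, dates):
            if analyte is Analyte.HBA1C:
                value = float(np.clip(value, 3.0, 20.0))
            labs.append(LabResult(analyte, value, date))

    bmi_pairs = _draw_labs(rng, spec.bmi, years, dates)
    if spec.constrained_base_pass:
        while len(bmi_pairs) < 3:          # engagement criterion by construction
            bmi_pairs.append(
                (float(np.clip(rng.normal(spec.bmi.mean, spec.bmi.sd),
                               *(spec.bmi.clip or (15, 30)))), dates.draw()))
    bmi = [BMIMeasurement(float(np.clip(v, 10.1, 99.9)), d)
           for v, d in bmi_pairs]

    medications: list[MedicationExposure] = []
    for drug_name, setting, p in spec.medications.exposures:
        if rng.random() < p:
            medications.append(MedicationExposure(
                drug_name, classify_drug(drug_name), setting, dates.draw()))

    diagnoses: list[DiagnosisCode] = []
    if rng.random() < spec.p_cf_code:
        diagnoses.append(DiagnosisCode("E84.0", dates.draw()))

    antibodies: list[AntibodyTest] = []
    if rng.random() < spec.antibody.p_tested:
        n_tests = int(rng.integers(1, 4))
        panel = list(Antibody)[:n_tests]
        any_pos = rng.random() < spec.antibody.p_positive
        for i, ab in enumerate(panel):
            result = (AntibodyResult.positive if any_pos and i == 0
                      else AntibodyResult.negative)
            antibodies.append(AntibodyTest(ab, result, dates.draw()))

    miss = config.missingness
    has_insulin = any(m.drug_class is DrugClass.insulin for m in medications)
    if rng.random() < chart_policy.p_c_peptide_tested and rng.random() >= miss:
        c_pep = (CPeptideStatus.low
                 if rng.random() < chart_policy.p_c_peptide_low
                 else CPeptideStatus.normal_or_high)
    else:
        c_pep = CPeptideStatus.untested
    if rng.random() < chart_policy.p_mody_tested:
        mody = (GeneticTestStatus.positive
                if rng.random() < chart_policy.p_mody_positive
                else GeneticTestStatus.negative)
    else:
        mody = GeneticTestStatus.untested
    fam = _opt(rng, chart_policy.p_family_history, miss)
    multigen = (None if fam is None
                else (fam and bool(rng.random()
                                   < chart_policy.p_multigenerational)))
    bmi_at_dx = None
    if age_dx is not None and rng.random() >= miss:
        bmi_at_dx = float(np.clip(rng.normal(spec.bmi.mean, spec.bmi.sd),
                                  *(spec.bmi.clip or (10.1, 99.9))))
    chart = ChartFacts(
        age_at_diagnosis=(None if age_dx is None or rng.random() < miss
                          else float(age_dx)),
        ketosis_history_adult=_opt(rng, chart_policy.p_ketosis, miss),
        c_peptide_status=c_pep,
        mody_genetic_test=mody,
        family_history_diabetes=fam,
        multigenerational_family_history=multigen,
        pancreatic_disease_before_dx=_opt(rng, chart_policy.p_pancreatic, miss),
        chronic_steroid_exposure_at_dx=_opt(
            rng, chart_policy.p_steroid_at_dx, miss),
        insulin_dependent_from_onset=_opt(
            rng, chart_policy.p_insulin_from_onset, miss),
        long_term_insulin_use=_opt(
            rng, chart_policy.p_long_term_insulin if not has_insulin else 0.9,
            miss),
        bmi_at_diagnosis=bmi_at_dx,
    )

    return PatientRecord(
        patient_id=pid, sex=sex, birth_year=birth_year, race_ethnicity=race,
        labs=sorted(labs, key=lambda l: (l.date, l.analyte.value, l.value)),
        bmi=sorted(bmi, key=lambda b: (b.date, b.value)),
        medications=sorted(medications,
                           key=lambda m: (m.date, m.drug_name, m.setting.value)),
        diagnoses=sorted(diagnoses, key=lambda d: (d.date, d.code)),
        antibodies=sorted(antibodies,
                          key=lambda a: (a.date, a.antibody.value, a.result.value)),
        chart=chart,
    )


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[Cohort, dict[str, ArchetypeName]]:
    """Generate a cohort and the latent-truth table (patient_id -> archetype).

    Output is fully reproducible for a given config: the same seed yields
    byte-identical bundles on disk.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    specs = list(config.archetypes)
    prevalences = np.array([a.prevalence for a in specs])
    assignments = rng.choice(len(specs), size=config.n_patients, p=prevalences)

    # flag-rate algebra against latent truth (see module docstring)
    ml = config.ml_flags
    prev_t2d_like = float(sum(a.prevalence for a in specs
                              if a.name in T2D_LIKE))
    prev_diab = float(sum(a.prevalence for a in specs
                          if a.name is not ArchetypeName.nondiabetic))
    prev_t1d_in_diab = float(sum(
        a.prevalence for a in specs
        if a.name is ArchetypeName.typical_T1D)) / prev_diab
    fp_t2d = _false_positive_rate(
        ml.t2d_flag_sensitivity, prev_t2d_like, ml.t2d_flag_ppv)
    fp_t1d = _false_positive_rate(
        ml.t1d_flag_sensitivity, prev_t1d_in_diab, ml.t1d_flag_ppv)
    ruleout_t1d = _ruleout_rate_for_positives(
        ml.t1d_flag_sensitivity, prev_t1d_in_diab, ml.t1d_ruleout_npv,
        fp_t1d, ml.t1d_ruleout_coverage)

    width = max(6, len(str(config.n_patients)))
    patients: list[PatientRecord] = []
    truth: dict[str, ArchetypeName] = {}
    for i, a_idx in enumerate(assignments):
        spec = specs[int(a_idx)]
        pid = f"SYN{i:0{width}d}"
        p = _generate_patient(rng, pid, spec, config)

        is_t2d_like = spec.name in T2D_LIKE
        is_t1d = spec.name is ArchetypeName.typical_T1D
        is_diabetic = spec.name is not ArchetypeName.nondiabetic
        ml_t2d = bool(rng.random() < (ml.t2d_flag_sensitivity if is_t2d_like
                                      else fp_t2d))
        if not is_diabetic:
            high_ppv, ruled_out = False, True
        else:
            high_ppv = bool(rng.random() < (ml.t1d_flag_sensitivity if is_t1d
                                            else fp_t1d))
            if high_ppv:
                ruled_out = False
            elif is_t1d:
                ruled_out = bool(rng.random() < ruleout_t1d)
            else:
                ruled_out = bool(rng.random() < ml.t1d_ruleout_coverage)
        p.ml_flags = MLPhenotypeFlags(ml_t2d=ml_t2d, ml_t1d_high_ppv=high_ppv,
                                      ml_t1d_ruled_out=ruled_out)
        patients.append(p)
        truth[pid] = spec.name

    cohort = Cohort(patients=patients,
                    provenance=f"synthetic(seed={config.seed}, "
                               f"n={config.n_patients})",
                    seed=config.seed)
    return cohort, truth


# ---------------------------------------------------------------------------
# case planting

@dataclass(frozen=True)
class PlantSpec:
    """A fully specified case to embed in a background cohort.

    ``summary`` is the chart-review view the materialised record must
    reproduce; ``drugs`` optionally names the regimen (name, setting pairs) —
    when omitted a representative regimen matching the medication count is
    chosen.  ``hdl_value``/``tg_value`` set the planted lipid labs.
    """

    summary: CaseSummary
    race: RaceEthnicity = RaceEthnicity.Unknown
    drugs: Optional[tuple[tuple[str, CareSetting], ...]] = None
    hdl_value: float = 70.0
    tg_value: float = 100.0
    ml_t2d: bool = True
    ml_t1d_ruled_out: bool = True
    ml_t1d_high_ppv: bool = False


_AUTO_REGIMEN = ("metformin", "glipizide", "sitagliptin", "pioglitazone",
                 "empagliflozin")


def _materialize(spec: PlantSpec, reference_year: int,
                 base_config: BaseFilterConfig) -> PatientRecord:
    s = spec.summary
    ref = datetime.date(reference_year, 6, 30)
    if s.current_age is None:
        raise ValueError(f"plant spec {s.patient_id}: current_age required")
    birth_year = reference_year - int(round(s.current_age))
    span_days = max(1, math.ceil(s.observation_span_years * 365.25))
    first = ref - datetime.timedelta(days=span_days)
    mid = first + datetime.timedelta(days=span_days // 2)

    if spec.hdl_value < base_config.hdl_floor and spec.ml_t2d:
        raise ValueError(
            f"plant spec {s.patient_id}: HDL {spec.hdl_value} would fail the "
            "base algorithm a planted candidate must pass")
    if spec.tg_value > base_config.tg_ceiling and spec.ml_t2d:
        raise ValueError(
            f"plant spec {s.patient_id}: TG {spec.tg_value} would fail the "
            "base algorithm a planted candidate must pass")

    labs = [LabResult(Analyte.HDL, spec.hdl_value, mid),
            LabResult(Analyte.TG, spec.tg_value, mid)]
    if s.hba1c_range is not None:
        labs.append(LabResult(Analyte.HBA1C, s.hba1c_range[0], first))
        labs.append(LabResult(Analyte.HBA1C, s.hba1c_range[1], mid))

    bmi_lo, bmi_hi = s.bmi_range if s.bmi_range is not None else (22.0, 24.0)
    if spec.ml_t2d and bmi_hi > base_config.bmi_ceiling:
        raise ValueError(
            f"plant spec {s.patient_id}: BMI {bmi_hi} would fail the base "
            "algorithm a planted candidate must pass")
    bmi = [BMIMeasurement(bmi_lo, first),
           BMIMeasurement((bmi_lo + bmi_hi) / 2, mid),
           BMIMeasurement(bmi_hi, ref)]

    if spec.drugs is not None:
        drugs = list(spec.drugs)
    else:
        drugs = [(name, CareSetting.outpatient)
                 for name in _AUTO_REGIMEN[:s.n_noninsulin_dm_meds]]
        if s.uses_insulin_long_term is True:
            drugs.append(("insulin glargine", CareSetting.outpatient))
    medications = [
        MedicationExposure(name, classify_drug(name), setting, mid)
        for name, setting in drugs]

    antibodies: list[AntibodyTest] = []
    if s.antibody_status is AntibodyStatus.negative_documented:
        antibodies.append(AntibodyTest(Antibody.GAD65,
                                       AntibodyResult.negative, mid))
    elif s.antibody_status is AntibodyStatus.positive:
        if spec.ml_t2d:
            raise ValueError(
                f"plant spec {s.patient_id}: positive antibody cannot pass "
                "the base algorithm")
        antibodies.append(AntibodyTest(Antibody.GAD65,
                                       AntibodyResult.positive, mid))

    if s.metabolic_features_at_dx is True:
        bmi_at_dx: Optional[float] = 33.0
    elif s.metabolic_features_at_dx is False:
        bmi_at_dx = bmi_lo
    else:
        bmi_at_dx = None

    chart = ChartFacts(
        age_at_diagnosis=s.age_at_diagnosis,
        age_at_diagnosis_is_upper_bound=s.age_at_diagnosis_is_upper_bound,
        ketosis_history_adult=s.ketosis_history_adult,
        c_peptide_status=s.c_peptide_status,
        mody_genetic_test=s.mody_genetic_test,
        family_history_diabetes=s.multigenerational_family_history,
        multigenerational_family_history=s.multigenerational_family_history,
        pancreatic_disease_before_dx=s.pancreatic_disease_before_dx,
        chronic_steroid_exposure_at_dx=s.chronic_steroid_exposure_at_dx,
        insulin_dependent_from_onset=s.insulin_dependent_from_onset,
        long_term_insulin_use=s.uses_insulin_long_term,
        bmi_at_diagnosis=bmi_at_dx,
    )

    record = PatientRecord(
        patient_id=s.patient_id, sex=s.sex, birth_year=birth_year,
        race_ethnicity=spec.race,
        labs=sorted(labs, key=lambda l: (l.date, l.analyte.value, l.value)),
        bmi=sorted(bmi, key=lambda b: (b.date, b.value)),
        medications=sorted(medications,
                           key=lambda m: (m.date, m.drug_name, m.setting.value)),
        antibodies=sorted(antibodies,
                          key=lambda a: (a.date, a.antibody.value,
                                         a.result.value)),
        ml_flags=MLPhenotypeFlags(ml_t2d=spec.ml_t2d,
                                  ml_t1d_high_ppv=spec.ml_t1d_high_ppv,
                                  ml_t1d_ruled_out=spec.ml_t1d_ruled_out),
        chart=chart,
    )

    # verify the materialised record reproduces the requested summary
    from .chart_classification import summarize_case
    derived = summarize_case(record, reference_year=reference_year)
    checks = {
        "age_at_diagnosis": (derived.age_at_diagnosis, s.age_at_diagnosis),
        "antibody_status": (derived.antibody_status, s.antibody_status),
        "n_noninsulin_dm_meds": (derived.n_noninsulin_dm_meds,
                                 s.n_noninsulin_dm_meds),
        "hba1c_range": (derived.hba1c_range, s.hba1c_range),
        "bmi_range": (derived.bmi_range,
                      s.bmi_range if s.bmi_range is not None else (22.0, 24.0)),
    }
    for name, (got, want) in checks.items():
        if got != want:
            raise ValueError(
                f"plant spec {s.patient_id} unsatisfiable: derived {name}="
                f"{got!r} != requested {want!r}")
    return record


def plant_cases(cohort: Cohort, cases: Sequence[PlantSpec],
                reference_year: int = 2020,
                base_config: BaseFilterConfig = BaseFilterConfig()) -> Cohort:
    """Embed fully materialised case records in a background cohort.

    Each planted record is built so its derived chart-review summary equals
    the requested spec; an unsatisfiable spec (e.g. an HDL below the
    metabolic floor on a record that must survive the base algorithm) raises
    ``ValueError``.  Planted ids must not collide with existing patients.
    """
    existing = {p.patient_id for p in cohort.patients}
    records = []
    for spec in cases:
        pid = spec.summary.patient_id
        if pid in existing:
            raise ValueError(f"planted id {pid!r} collides with cohort")
        existing.add(pid)
        records.append(_materialize(spec, reference_year, base_config))
    return Cohort(patients=list(cohort.patients) + records,
                  provenance=cohort.provenance + f" +{len(records)} planted",
                  seed=cohort.seed)
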