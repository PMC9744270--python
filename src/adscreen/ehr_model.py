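"""Domain types for longitudinal EHR slices and the entity-table interchange format.

A cohort is persisted as a directory ("bundle") of UTF-8 comma-delimited
tables sharing ``patient_id`` keys::

    patients.csv     patient_id, sex, birth_year, race_ethnicity
    labs.csv         patient_id, analyte, value, date
    bmi.csv          patient_id, value, date
    medications.csv  patient_id, drug_name, drug_class, setting, date
    diagnoses.csv    patient_id, code, date
    antibodies.csv   patient_id, antibody, result, date
    ml_flags.csv     patient_id, ml_t2d, ml_t1d_high_ppv, ml_t1d_ruled_out
    chart_facts.csv  patient_id, <one column per ChartFacts field>

Dates are ISO-8601 at day resolution.  The downstream filter algorithms use
only ordering and extrema, so partial dates consisting of a year alone are
accepted on read and mapped to July 1 of that year.  A JSON-lines dialect
(one patient object per line) is accepted as an alternative input format.

Empty cells in ``chart_facts.csv`` encode "not documented" (``None``), which
is semantically distinct from an explicit ``false``: the indeterminate (NMI)
classification depends on that distinction.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TypeVar, Union

import pandas as pd

__all__ = [
    "Sex",
    "RaceEthnicity",
    "Analyte",
    "DrugClass",
    "CareSetting",
    "Antibody",
    "AntibodyResult",
    "CPeptideStatus",
    "GeneticTestStatus",
    "LabResult",
    "BMIMeasurement",
    "MedicationExposure",
    "DiagnosisCode",
    "AntibodyTest",
    "MLPhenotypeFlags",
    "ChartFacts",
    "PatientRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "most_recent",
]


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    unknown = "unknown"


class RaceEthnicity(str, enum.Enum):
    White = "White"
    Black = "Black"
    Hispanic = "Hispanic"
    Asian = "Asian"
    Other = "Other"
    Unknown = "Unknown"


class Analyte(str, enum.Enum):
    HDL = "HDL"          # mg/dL
    TG = "TG"            # mg/dL
    HBA1C = "HbA1c"      # %


class DrugClass(str, enum.Enum):
    insulin = "insulin"
    metformin = "metformin"
    sulfonylurea = "sulfonylurea"
    meglitinide = "meglitinide"
    TZD = "TZD"
    DPP4i = "DPP4i"
    AGI = "AGI"
    GLP1RA = "GLP1RA"
    SGLT2i = "SGLT2i"
    systemic_steroid = "systemic_steroid"
    other = "other"


class CareSetting(str, enum.Enum):
    outpatient = "outpatient"
    inpatient = "inpatient"


class Antibody(str, enum.Enum):
    GAD65 = "GAD65"
    IA2 = "IA2"
    ZnT8 = "ZnT8"


class AntibodyResult(str, enum.Enum):
    positive = "positive"
    negative = "negative"


class CPeptideStatus(str, enum.Enum):
    low = "low"
    normal_or_high = "normal_or_high"
    untested = "untested"


class GeneticTestStatus(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    untested = "untested"


@dataclass(frozen=True)
class LabResult:
    """One dated lab value: HDL or triglycerides in mg/dL, HbA1c in %."""

    analyte: Analyte
    value: float
    date: datetime.date

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"lab value must be positive, got {self.value}")
        if self.analyte is Analyte.HBA1C and not (3.0 <= self.value <= 20.0):
            raise ValueError(f"HbA1c out of plausible range [3, 20]%: {self.value}")


@dataclass(frozen=True)
class BMIMeasurement:
    """Body-mass index in kg/m^2 on a given date."""

    value: float
    date: datetime.date

    def __post_init__(self) -> None:
        if not (10.0 <= self.value <= 100.0):
            raise ValueError(f"BMI out of plausible range [10, 100]: {self.value}")


@dataclass(frozen=True)
class MedicationExposure:
    drug_name: str
    drug_class: DrugClass
    setting: CareSetting
    date: datetime.date


@dataclass(frozen=True)
class DiagnosisCode:
    """An ICD-9 or ICD-10 code as recorded, e.g. ``E84.0`` or ``277.00``."""

    code: str
    date: datetime.date


@dataclass(frozen=True)
class AntibodyTest:
    antibody: Antibody
    result: AntibodyResult
    date: datetime.date


@dataclass(frozen=True)
class MLPhenotypeFlags:
    """Curated-phenotype ML calls consumed as inputs.

    ``ml_t2d`` marks membership in the ML type 2 diabetes group;
    ``ml_t1d_high_ppv`` is a confident T1D call (PPV 0.95) and
    ``ml_t1d_ruled_out`` a confident non-T1D call (NPV 0.99).  A patient can
    carry at most one of the two T1D flags.
    """

    ml_t2d: bool = False
    ml_t1d_high_ppv: bool = False
    ml_t1d_ruled_out: bool = False

    def __post_init__(self) -> None:
        if self.ml_t1d_high_ppv and self.ml_t1d_ruled_out:
            raise ValueError(
                "ml_t1d_high_ppv and ml_t1d_ruled_out are mutually exclusive"
            )


@dataclass(frozen=True)
class ChartFacts:
    """Chart-review facts abstracted from notes.

    ``None`` means "not documented" and is distinct from ``False``
    ("documented absent"); the NMI category depends on that distinction.
    """

    age_at_diagnosis: Optional[float] = None
    age_at_diagnosis_is_upper_bound: bool = False
    ketosis_history_adult: Optional[bool] = None
    c_peptide_status: CPeptideStatus = CPeptideStatus.untested
    mody_genetic_test: GeneticTestStatus = GeneticTestStatus.untested
    family_history_diabetes: Optional[bool] = None
    multigenerational_family_history: Optional[bool] = None
    pancreatic_disease_before_dx: Optional[bool] = None
    chronic_steroid_exposure_at_dx: Optional[bool] = None
    insulin_dependent_from_onset: Optional[bool] = None
    long_term_insulin_use: Optional[bool] = None
    bmi_at_diagnosis: Optional[float] = None


@dataclass
class PatientRecord:
    """One person's longitudinal EHR slice."""

    patient_id: str
    sex: Sex = Sex.unknown
    birth_year: int = 1950
    race_ethnicity: RaceEthnicity = RaceEthnicity.Unknown
    labs: list[LabResult] = field(default_factory=list)
    bmi: list[BMIMeasurement] = field(default_factory=list)
    medications: list[MedicationExposure] = field(default_factory=list)
    diagnoses: list[DiagnosisCode] = field(default_factory=list)
    antibodies: list[AntibodyTest] = field(default_factory=list)
    ml_flags: MLPhenotypeFlags = field(default_factory=MLPhenotypeFlags)
    chart: ChartFacts = field(default_factory=ChartFacts)


@dataclass
class Cohort:
    patients: list[PatientRecord]
    provenance: str = "unspecified"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be nonempty")
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}


_Dated = TypeVar("_Dated", LabResult, BMIMeasurement)


def most_recent(values: Sequence[_Dated]) -> Optional[_Dated]:
    """Entry with the latest date, or ``None`` for an empty list.

    Same-day ties are broken toward the larger value so that summary reports
    are reproducible regardless of input order.
    """
    if not values:
        return None
    return max(values, key=lambda m: (m.date, m.value))


# ---------------------------------------------------------------------------
# persistence

_ENTITY_TABLES = (
    "patients", "labs", "bmi", "medications",
    "diagnoses", "antibodies", "ml_flags", "chart_facts",
)

_CHART_BOOL_FIELDS = (
    "ketosis_history_adult", "family_history_diabetes",
    "multigenerational_family_history", "pancreatic_disease_before_dx",
    "chronic_steroid_exposure_at_dx", "insulin_dependent_from_onset",
    "long_term_insulin_use",
)

_YEAR_ONLY = re.compile(r"^\d{4}$")


def _parse_date(raw: str) -> datetime.date:
    raw = str(raw).strip()
    if _YEAR_ONLY.match(raw):
        # year-only partial date: only ordering matters downstream
        return datetime.date(int(raw), 7, 1)
    try:
        return datetime.date.fromisoformat(raw)
    except ValueError as exc:
        raise ValueError(f"unparseable date {raw!r}") from exc


def _fmt_bool(value: Optional[bool]) -> str:
    return "" if value is None else ("true" if value else "false")


def _parse_opt_bool(raw: object) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    text = str(raw).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def write_cohort(cohort: Cohort, path_bundle: Union[str, Path]) -> None:
    """Write a cohort as an entity-table bundle.

    Rows are ordered by (patient_id, date, ...) so two writes of the same
    cohort are byte-identical.  Empty entity lists still produce header-only
    tables, keeping the bundle schema self-describing.
    """
    out = Path(path_bundle)
    out.mkdir(parents=True, exist_ok=True)
    patients = sorted(cohort.patients, key=lambda p: p.patient_id)

    rows: dict[str, list[dict]] = {name: [] for name in _ENTITY_TABLES}
    for p in patients:
        rows["patients"].append({
            "patient_id": p.patient_id, "sex": p.sex.value,
            "birth_year": p.birth_year, "race_ethnicity": p.race_ethnicity.value,
        })
        for lab in sorted(p.labs, key=lambda r: (r.date, r.analyte.value, r.value)):
            rows["labs"].append({
                "patient_id": p.patient_id, "analyte": lab.analyte.value,
                "value": repr(lab.value), "date": lab.date.isoformat(),
            })
        for b in sorted(p.bmi, key=lambda r: (r.date, r.value)):
            rows["bmi"].append({
                "patient_id": p.patient_id, "value": repr(b.value),
                "date": b.date.isoformat(),
            })
        for m in sorted(p.medications,
                        key=lambda r: (r.date, r.drug_name, r.setting.value)):
            rows["medications"].append({
                "patient_id": p.patient_id, "drug_name": m.drug_name,
                "drug_class": m.drug_class.value, "setting": m.setting.value,
                "date": m.date.isoformat(),
            })
        for d in sorted(p.diagnoses, key=lambda r: (r.date, r.code)):
            rows["diagnoses"].append({
                "patient_id": p.patient_id, "code": d.code,
                "date": d.date.isoformat(),
            })
        for a in sorted(p.antibodies,
                        key=lambda r: (r.date, r.antibody.value, r.result.value)):
            rows["antibodies"].append({
                "patient_id": p.patient_id, "antibody": a.antibody.value,
                "result": a.result.value, "date": a.date.isoformat(),
            })
        f = p.ml_flags
        rows["ml_flags"].append({
            "patient_id": p.patient_id, "ml_t2d": _fmt_bool(f.ml_t2d),
            "ml_t1d_high_ppv": _fmt_bool(f.ml_t1d_high_ppv),
            "ml_t1d_ruled_out": _fmt_bool(f.ml_t1d_ruled_out),
        })
        c = p.chart
        chart_row = {"patient_id": p.patient_id}
        chart_row["age_at_diagnosis"] = (
            "" if c.age_at_diagnosis is None else repr(c.age_at_diagnosis))
        chart_row["age_at_diagnosis_is_upper_bound"] = _fmt_bool(
            c.age_at_diagnosis_is_upper_bound)
        for name in _CHART_BOOL_FIELDS:
            chart_row[name] = _fmt_bool(getattr(c, name))
        chart_row["c_peptide_status"] = c.c_peptide_status.value
        chart_row["mody_genetic_test"] = c.mody_genetic_test.value
        chart_row["bmi_at_diagnosis"] = (
            "" if c.bmi_at_diagnosis is None else repr(c.bmi_at_diagnosis))
        rows["chart_facts"].append(chart_row)

    headers = {
        "patients": ["patient_id", "sex", "birth_year", "race_ethnicity"],
        "labs": ["patient_id", "analyte", "value", "date"],
        "bmi": ["patient_id", "value", "date"],
        "medications": ["patient_id", "drug_name", "drug_class", "setting", "date"],
        "diagnoses": ["patient_id", "code", "date"],
        "antibodies": ["patient_id", "antibody", "result", "date"],
        "ml_flags": ["patient_id", "ml_t2d", "ml_t1d_high_ppv", "ml_t1d_ruled_out"],
        "chart_facts": ["patient_id", "age_at_diagnosis",
                        "age_at_diagnosis_is_upper_bound", *_CHART_BOOL_FIELDS,
                        "c_peptide_status", "mody_genetic_test", "bmi_at_diagnosis"],
    }
    for name in _ENTITY_TABLES:
        df = pd.DataFrame(rows[name], columns=headers[name])
        df.to_csv(out / f"{name}.csv", index=False, lineterminator="\n")

    meta = {"provenance": cohort.provenance, "seed": cohort.seed,
            "n_patients": len(cohort.patients)}
    (out / "cohort.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_cohort(path_bundle: Union[str, Path]) -> Cohort:
    """Read an entity-table bundle (or a ``.jsonl`` file) back into a Cohort.

    Every child-table row must reference a patient present in the patients
    table; unknown ids raise ``ValueError``.
    """
    path = Path(path_bundle)
    if path.is_file() and path.suffix == ".jsonl":
        return _read_jsonl(path)
    patients_path = path / "patients.csv"
    if not patients_path.exists():
        raise FileNotFoundError(f"bundle {path} has no patients table")

    pdf = _read_table(patients_path)
    records: dict[str, PatientRecord] = {}
    for row in pdf.itertuples(index=False):
        pid = row.patient_id
        if pid in records:
            raise ValueError(f"duplicate patient_id {pid!r} in patients table")
        records[pid] = PatientRecord(
            patient_id=pid,
            sex=Sex(row.sex),
            birth_year=int(row.birth_year),
            race_ethnicity=RaceEthnicity(row.race_ethnicity),
        )

    def patient(pid: str, table: str) -> PatientRecord:
        try:
            return records[pid]
        except KeyError:
            raise ValueError(
                f"{table} row references unknown patient_id {pid!r}") from None

    for name in ("labs", "bmi", "medications", "diagnoses", "antibodies",
                 "ml_flags", "chart_facts"):
        tbl = path / f"{name}.csv"
        if not tbl.exists():
            continue
        df = _read_table(tbl)
        for row in df.itertuples(index=False):
            p = patient(row.patient_id, name)
            if name == "labs":
                p.labs.append(LabResult(Analyte(row.analyte),
                                        float(row.value), _parse_date(row.date)))
            elif name == "bmi":
                p.bmi.append(BMIMeasurement(float(row.value), _parse_date(row.date)))
            elif name == "medications":
                p.medications.append(MedicationExposure(
                    row.drug_name, DrugClass(row.drug_class),
                    CareSetting(row.setting), _parse_date(row.date)))
            elif name == "diagnoses":
                p.diagnoses.append(DiagnosisCode(row.code, _parse_date(row.date)))
            elif name == "antibodies":
                p.antibodies.append(AntibodyTest(
                    Antibody(row.antibody), AntibodyResult(row.result),
                    _parse_date(row.date)))
            elif name == "ml_flags":
                p.ml_flags = MLPhenotypeFlags(
                    ml_t2d=bool(_parse_opt_bool(row.ml_t2d)),
                    ml_t1d_high_ppv=bool(_parse_opt_bool(row.ml_t1d_high_ppv)),
                    ml_t1d_ruled_out=bool(_parse_opt_bool(row.ml_t1d_ruled_out)))
            elif name == "chart_facts":
                p.chart = ChartFacts(
                    age_at_diagnosis=(None if row.age_at_diagnosis == ""
                                      else float(row.age_at_diagnosis)),
                    age_at_diagnosis_is_upper_bound=bool(
                        _parse_opt_bool(row.age_at_diagnosis_is_upper_bound)),
                    c_peptide_status=CPeptideStatus(row.c_peptide_status),
                    mody_genetic_test=GeneticTestStatus(row.mody_genetic_test),
                    bmi_at_diagnosis=(None if row.bmi_at_diagnosis == ""
                                      else float(row.bmi_at_diagnosis)),
                    **{f: _parse_opt_bool(getattr(row, f))
                       for f in _CHART_BOOL_FIELDS},
                )

    meta_path = path / "cohort.json"
    provenance, seed = str(path), None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        provenance = meta.get("provenance") or provenance
        seed = meta.get("seed")
    return Cohort(patients=list(records.values()), provenance=provenance, seed=seed)


# --- JSON-lines dialect -----------------------------------------------------

def _patient_to_obj(p: PatientRecord) -> dict:
    return {
        "patient_id": p.patient_id, "sex": p.sex.value,
        "birth_year": p.birth_year, "race_ethnicity": p.race_ethnicity.value,
        "labs": [[l.analyte.value, l.value, l.date.isoformat()] for l in p.labs],
        "bmi": [[b.value, b.date.isoformat()] for b in p.bmi],
        "medications": [[m.drug_name, m.drug_class.value, m.setting.value,
                         m.date.isoformat()] for m in p.medications],
        "diagnoses": [[d.code, d.date.isoformat()] for d in p.diagnoses],
        "antibodies": [[a.antibody.value, a.result.value, a.date.isoformat()]
                       for a in p.antibodies],
        "ml_flags": dataclasses.asdict(p.ml_flags),
        "chart": {k: (v.value if isinstance(v, enum.Enum) else v)
                  for k, v in dataclasses.asdict(p.chart).items()},
    }


def _patient_from_obj(obj: dict) -> PatientRecord:
    chart = dict(obj.get("chart", {}))
    if "c_peptide_status" in chart:
        chart["c_peptide_status"] = CPeptideStatus(chart["c_peptide_status"])
    if "mody_genetic_test" in chart:
        chart["mody_genetic_test"] = GeneticTestStatus(chart["mody_genetic_test"])
    return PatientRecord(
        patient_id=obj["patient_id"],
        sex=Sex(obj.get("sex", "unknown")),
        birth_year=int(obj.get("birth_year", 1950)),
        race_ethnicity=RaceEthnicity(obj.get("race_ethnicity", "Unknown")),
        labs=[LabResult(Analyte(a), float(v), _parse_date(d))
              for a, v, d in obj.get("labs", [])],
        bmi=[BMIMeasurement(float(v), _parse_date(d))
             for v, d in obj.get("bmi", [])],
        medications=[MedicationExposure(n, DrugClass(c), CareSetting(s),
                                        _parse_date(d))
                     for n, c, s, d in obj.get("medications", [])],
        diagnoses=[DiagnosisCode(c, _parse_date(d))
                   for c, d in obj.get("diagnoses", [])],
        antibodies=[AntibodyTest(Antibody(a), AntibodyResult(r), _parse_date(d))
                    for a, r, d in obj.get("antibodies", [])],
        ml_flags=MLPhenotypeFlags(**obj.get("ml_flags", {})),
        chart=ChartFacts(**chart),
    )


def write_cohort_jsonl(cohort: Cohort, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in sorted(cohort.patients, key=lambda p: p.patient_id):
            fh.write(json.dumps(_patient_to_obj(p), sort_keys=True) + "\n")


def _read_jsonl(path: Path) -> Cohort:
    patients = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                patients.append(_patient_from_obj(json.loads(line)))
    return Cohort(patients=patients, provenance=str(path))
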