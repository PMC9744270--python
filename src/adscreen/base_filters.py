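"""Base exclusion algorithm: prune "typical" T2D from the ML T2D group.

Starting from patients flagged by the curated-phenotype ML algorithm as
likely T2D, the base algorithm removes anyone with EHR evidence of metabolic
syndrome (HDL ever < 50 mg/dL, triglycerides ever > 150 mg/dL, or BMI ever
> 30 kg/m^2 — the criteria need not be met concurrently), anyone with fewer
than three normal-range BMI measurements (a healthcare-engagement proxy
ensuring the phenotype data can be trusted), anyone with cystic fibrosis
codes (CF-related diabetes), and anyone with a positive islet autoantibody
(laboratory-demonstrated autoimmune diabetes).

All threshold comparisons are strict, matching the "less than"/"greater
than" phrasing of the criteria, so boundary values survive.  Missing HDL or
triglyceride data passes the metabolic criteria — absence of evidence is not
exclusion; only the BMI-count criterion enforces data sufficiency.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from . import vocab
from .ehr_model import (
    Analyte, Antibody, AntibodyTest, BMIMeasurement, Cohort, DiagnosisCode,
    LabResult, PatientRecord,
)

__all__ = [
    "BaseFilterConfig", "FilterResult", "CRITERIA_ORDER",
    "ever_outside", "has_engagement", "has_cf", "has_positive_antibody",
    "apply_base_algorithm",
]


@dataclass(frozen=True)
class BaseFilterConfig:
    hdl_floor: float = 50.0          # mg/dL; exclude if ever strictly below
    tg_ceiling: float = 150.0        # mg/dL; exclude if ever strictly above
    bmi_ceiling: float = 30.0        # kg/m^2; exclude if ever strictly above
    min_bmi_count: int = 3           # "fewer than three normal BMI values"
    bmi_normal_ceiling: float = 30.0  # what counts as a "normal" BMI record
    bmi_normal_floor: float = 0.0     # optional stricter normality window
    cf_code_prefixes: tuple[str, ...] = vocab.CF_CODE_PREFIXES
    antibody_panel: frozenset[Antibody] = frozenset(Antibody)

    def __post_init__(self) -> None:
        if min(self.hdl_floor, self.tg_ceiling, self.bmi_ceiling) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_bmi_count < 1:
            raise ValueError("min_bmi_count must be >= 1")


#: Fixed exclusion-criterion evaluation/reporting order.
CRITERIA_ORDER = (
    "metabolic-HDL", "metabolic-TG", "metabolic-BMI",
    "engagement", "CF", "antibody",
)


@dataclass
class FilterResult:
    """Kept/excluded partition with per-criterion attrition accounting.

    A patient may appear under several exclusion criteria; ``kept`` and the
    union of the ``excluded`` sets partition the input.
    """

    kept: list[str]
    excluded: dict[str, set[str]]
    input_size: int

    @property
    def excluded_any(self) -> set[str]:
        out: set[str] = set()
        for ids in self.excluded.values():
            out |= ids
        return out

    def attrition_rows(self) -> list[tuple[str, int, int]]:
        """(criterion, n excluded at this step, n remaining) in fixed order.

        Counts are sequential: a patient is charged to the first criterion
        (in ``CRITERIA_ORDER``) that excludes it.
        """
        remaining = set(self.kept) | self.excluded_any
        rows = []
        for crit in CRITERIA_ORDER:
            hit = self.excluded.get(crit, set()) & remaining
            remaining -= hit
            rows.append((crit, len(hit), len(remaining)))
        return rows


def ever_outside(
    labs: Sequence[LabResult],
    analyte: Analyte,
    threshold: float,
    direction: Literal["below", "above"],
) -> bool:
    """True iff any value of ``analyte`` strictly violates the threshold.

    An empty list, or one with no values of that analyte, returns False.
    """
    for lab in labs:
        if lab.analyte is not analyte:
            continue
        if direction == "below" and lab.value < threshold:
            return True
        if direction == "above" and lab.value > threshold:
            return True
    return False


def has_engagement(bmi: Sequence[BMIMeasurement],
                   config: BaseFilterConfig = BaseFilterConfig()) -> bool:
    """True iff the record holds enough normal-range BMI measurements.

    "Normal" defaults to value <= 30 kg/m^2 (the obesity-range records are
    handled by the metabolic criterion); a stricter window can be configured
    via ``bmi_normal_floor``/``bmi_normal_ceiling``.
    """
    n = sum(1 for b in bmi
            if config.bmi_normal_floor <= b.value <= config.bmi_normal_ceiling)
    return n >= config.min_bmi_count


def has_cf(diagnoses: Sequence[DiagnosisCode],
           prefixes: tuple[str, ...] = vocab.CF_CODE_PREFIXES) -> bool:
    return any(vocab.is_cf_code(d.code, prefixes) for d in diagnoses)


def has_positive_antibody(antibodies: Sequence[AntibodyTest],
                          panel: Iterable[Antibody] = frozenset(Antibody)) -> bool:
    panel = frozenset(panel)
    return any(a.antibody in panel and a.result.value == "positive"
               for a in antibodies)


def _exclusion_criteria(p: PatientRecord, config: BaseFilterConfig) -> list[str]:
    hit = []
    if ever_outside(p.labs, Analyte.HDL, config.hdl_floor, "below"):
        hit.append("metabolic-HDL")
    if ever_outside(p.labs, Analyte.TG, config.tg_ceiling, "above"):
        hit.append("metabolic-TG")
    if any(b.value > config.bmi_ceiling for b in p.bmi):
        hit.append("metabolic-BMI")
    if not has_engagement(p.bmi, config):
        hit.append("engagement")
    if has_cf(p.diagnoses, config.cf_code_prefixes):
        hit.append("CF")
    if has_positive_antibody(p.antibodies, config.antibody_panel):
        hit.append("antibody")
    return hit


def apply_base_algorithm(cohort: Cohort,
                         config: BaseFilterConfig = BaseFilterConfig()
                         ) -> FilterResult:
    """Run the base exclusion algorithm over the ML T2D members of a cohort.

    The six criteria are evaluated as a joint predicate, with every violated
    criterion recorded per patient, which subsumes both a sequential and a
    joint reading of the flow diagram.  ``kept`` is ordered by patient_id.
    """
    input_ids = [p.patient_id for p in cohort.patients if p.ml_flags.ml_t2d]
    excluded: dict[str, set[str]] = {c: set() for c in CRITERIA_ORDER}
    kept: list[str] = []
    by_id = cohort.by_id()
    for pid in sorted(input_ids):
        hits = _exclusion_criteria(by_id[pid], config)
        if hits:
            for crit in hits:
                excluded[crit].add(pid)
        else:
            kept.append(pid)
    return FilterResult(kept=kept, excluded=excluded, input_size=len(input_ids))
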