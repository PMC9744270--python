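"""End-to-end orchestration: simulate -> filter -> classify -> report.

Every stage writes plain delimited files into the run directory so any stage
can be re-run standalone; a manifest records the seed and a hash of the
configuration, and repeated runs with the same configuration are identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .base_filters import BaseFilterConfig, FilterResult, apply_base_algorithm
from .branch_algorithms import (
    BRANCH_NAMES, BranchResult, CandidateSet, assemble_candidates,
    run_all_branches,
)
from .chart_classification import (
    Category, ClassifierRules, CohortClassification, Subtype, SubtypeConfig,
    classify_cohort,
)
from .ehr_model import Cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AttritionReport", "run_pipeline", "yield_summary"]


@dataclass
class RunConfig:
    output_dir: Union[str, Path]
    cohort_bundle: Optional[Union[str, Path]] = None  # None: simulate
    n_patients: int = 20_000
    seed: int = 0
    base: BaseFilterConfig = field(default_factory=BaseFilterConfig)
    subtype: SubtypeConfig = field(default_factory=SubtypeConfig)
    plant_roster_cases: bool = False   # embed the packaged 16-case roster
    log_level: str = "INFO"


@dataclass
class AttritionReport:
    """CONSORT-style stage rows plus per-branch yield rows."""

    stage_rows: list[tuple[str, int, int, int]]       # stage, in, excluded, out
    branch_yield_rows: list[tuple[int, int, int, Optional[float]]]
    # (branch, n kept, n AD, yield fraction or None)

    def __post_init__(self) -> None:
        for stage, n_in, n_exc, n_out in self.stage_rows:
            if n_out != n_in - n_exc or min(n_in, n_exc, n_out) < 0:
                raise ValueError(f"inconsistent attrition row {stage}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_rows,
                            columns=["stage", "n_in", "n_excluded", "n_out"])


def yield_summary(candidates: CandidateSet,
                  outcomes: CohortClassification
                  ) -> list[tuple[int, int, int, Optional[float]]]:
    """Per-branch (n kept, n confirmed AD, yield) plus the overall row 0."""
    rows = []
    for b in range(1, 7):
        kept = [pid for pid in candidates.union_ids
                if candidates.membership[pid][b - 1]]
        n_ad = sum(outcomes.outcomes[pid].category is Category.AD
                   for pid in kept)
        rows.append((b, len(kept), n_ad,
                     (n_ad / len(kept)) if kept else None))
    n_union = len(candidates.union_ids)
    n_ad_total = outcomes.n_ad
    rows.append((0, n_union, n_ad_total,
                 (n_ad_total / n_union) if n_union else None))
    return rows


def _config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)   # where results land is not part of
    payload.pop("log_level", None)    # the scientific configuration
    blob = json.dumps(payload, default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig,
                 rules: Optional[ClassifierRules] = None) -> AttritionReport:
    """Run every stage in order and persist each stage's outputs.

    Stages: obtain cohort (read a bundle or simulate), base algorithm,
    six branch algorithms, candidate assembly, chart classification and
    subtype assignment, attrition/yield reporting.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_bundle is not None:
        cohort = read_cohort(config.cohort_bundle)
        logger.info("stage=load n=%d bundle=%s", len(cohort),
                    config.cohort_bundle)
    else:
        from .synthetic_cohort import default_config, generate_cohort
        cohort, truth = generate_cohort(
            default_config(config.n_patients, config.seed))
        pd.DataFrame(sorted(truth.items()),
                     columns=["patient_id", "archetype"]).to_csv(
            out / "truth.csv", index=False, lineterminator="\n")
        logger.info("stage=simulate n=%d seed=%d", len(cohort), config.seed)

    if config.plant_roster_cases:
        from .fixtures import case_roster_plant_specs
        from .synthetic_cohort import plant_cases
        cohort = plant_cases(cohort, case_roster_plant_specs(),
                             base_config=config.base)
        logger.info("stage=plant n=%d", len(cohort))
    write_cohort(cohort, out / "cohort")

    base = apply_base_algorithm(cohort, config.base)
    pd.DataFrame(base.attrition_rows(),
                 columns=["criterion", "n_excluded", "n_remaining"]).to_csv(
        out / "base_attrition.csv", index=False, lineterminator="\n")
    (out / "base_kept.txt").write_text("\n".join(base.kept) + "\n")
    logger.info("stage=base n_in=%d n_kept=%d", base.input_size, len(base.kept))

    by_id = cohort.by_id()
    base_patients = [by_id[pid] for pid in base.kept]
    branches = run_all_branches(base_patients)
    candidates = assemble_candidates(branches)
    cand_rows = [{"patient_id": pid,
                  **{f"branch_{b}": int(candidates.membership[pid][b - 1])
                     for b in range(1, 7)},
                  "n_branches": candidates.n_branches(pid)}
                 for pid in candidates.union_ids]
    pd.DataFrame(cand_rows, columns=["patient_id",
                                     *[f"branch_{b}" for b in range(1, 7)],
                                     "n_branches"]).to_csv(
        out / "candidates.csv", index=False, lineterminator="\n")
    logger.info("stage=branches union=%d", len(candidates.union_ids))

    outcomes = classify_cohort(candidates, cohort, rules=rules,
                               subtype_config=config.subtype)
    pd.DataFrame(
        [{"patient_id": pid, "category": o.category.value,
          "subtype": o.subtype.value,
          "fired_rules": "|".join(o.fired_rules),
          "nmi_reasons": "|".join(o.nmi_reasons)}
         for pid, o in sorted(outcomes.outcomes.items())]).to_csv(
        out / "classification.csv", index=False, lineterminator="\n")
    logger.info("stage=classify n_ad=%d", outcomes.n_ad)

    yields = yield_summary(candidates, outcomes)
    pd.DataFrame(yields, columns=["branch", "n_kept", "n_ad", "yield"]).to_csv(
        out / "branch_yield.csv", index=False, lineterminator="\n")

    n_excluded_base = base.input_size - len(base.kept)
    stage_rows = [
        ("cohort", len(cohort), len(cohort) - base.input_size,
         base.input_size),
        ("base_algorithm", base.input_size, n_excluded_base, len(base.kept)),
        ("branch_union", len(base.kept),
         len(base.kept) - len(candidates.union_ids),
         len(candidates.union_ids)),
        ("confirmed_ad", len(candidates.union_ids),
         len(candidates.union_ids) - outcomes.n_ad, outcomes.n_ad),
    ]
    report = AttritionReport(stage_rows=stage_rows, branch_yield_rows=yields)
    report.to_frame().to_csv(out / "attrition.csv", index=False,
                             lineterminator="\n")

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "n_patients": len(cohort),
        "n_candidates": len(candidates.union_ids),
        "n_ad": outcomes.n_ad,
        "subtype_tally": {s.value: outcomes.subtype_tally.get(s, 0)
                          for s in (Subtype.KPD, Subtype.MARD, Subtype.ISNM)},
        "category_tally": {c.value: outcomes.category_tally.get(c, 0)
                           for c in Category},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
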