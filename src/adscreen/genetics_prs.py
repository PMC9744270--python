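"""Polygenic score computation, transforms, centiles, and variant QC.

Scores follow the standard allele-dosage convention: a patient's raw score
is the sum over variants of effect-allele dosage (in [0, 2]) times the
published per-allele weight.  Missing dosages contribute the cohort-mean
dosage for that variant (the usual scoring-software behaviour), switchable
to zero contribution.  T2D genome-wide scores are reported after a linear
shift that places the cohort minimum at zero, purely for readability — the
shift preserves ordering and is idempotent.

Variant QC implements the four standard threshold filters: per-variant
missing call rate, minor allele frequency, the Hardy-Weinberg exact
(conditional) test on hard-called genotypes, and case/control differential
missingness.  The exact HWE test follows the standard conditional
formulation: given the observed minor-allele count, the probability of each
possible heterozygote count is computed and the p-value is the total
probability of configurations no more likely than the observed one.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ScoreType", "VariantWeight", "DosageMatrix", "PRSResult",
    "VariantQCConfig", "QCReport", "compute_prs", "shift_nonnegative",
    "centiles", "variant_qc", "hwe_exact_test",
    "read_weights", "read_dosages",
]


class ScoreType(str, enum.Enum):
    T1D_rsPS = "T1D_rsPS"   # restricted-to-significant score
    T2D_gePS = "T2D_gePS"   # global extended (genome-wide) score


@dataclass(frozen=True)
class VariantWeight:
    variant_id: str
    effect_allele: str
    weight: float


@dataclass
class DosageMatrix:
    """Patients x variants grid of effect-allele dosages in [0, 2].

    Missing calls are NaN.
    """

    patient_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray   # shape (n_patients, n_variants), float, NaN=missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.patient_ids), len(self.variant_ids)):
            raise ValueError("dosage grid shape inconsistent with id lists")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or \
               np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)]


@dataclass
class PRSResult:
    patient_id: str
    score_type: ScoreType
    raw_score: float
    transformed_score: Optional[float] = None
    centile: Optional[int] = None


@dataclass(frozen=True)
class VariantQCConfig:
    max_missing_rate: float = 0.05
    hwe_p_floor: float = 1e-6
    maf_floor: float = 0.01
    max_differential_missingness: float = 0.02

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    kept: list[str]
    dropped: dict[str, list[str]]   # variant_id -> reason codes


def compute_prs(dosages: DosageMatrix, weights: Sequence[VariantWeight],
                score_type: ScoreType,
                missing_policy: str = "mean") -> list[PRSResult]:
    """Score every patient: raw = sum over variants of dosage x weight.

    Every weight's variant must be a matrix column.  Missing cells
    contribute the cohort-mean dosage of their variant (``missing_policy=
    "mean"``) or nothing (``"zero"``).
    """
    if not weights:
        raise ValueError("empty weight list")
    ids = {w.variant_id for w in weights}
    if len(ids) != len(weights):
        raise ValueError("duplicate variant_id in weight set")
    missing = ids - set(dosages.variant_ids)
    if missing:
        raise ValueError(f"weights reference variants absent from matrix: "
                         f"{sorted(missing)[:5]}")
    if missing_policy not in ("mean", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    order = [dosages.variant_ids.index(w.variant_id) for w in weights]
    grid = dosages.dosages[:, order]
    w = np.array([w.weight for w in weights])
    if np.isnan(grid).any():
        col_means = np.nanmean(np.where(np.isnan(grid), np.nan, grid), axis=0)
        col_means = np.nan_to_num(col_means)   # all-missing column scores 0
        fill = col_means if missing_policy == "mean" else np.zeros_like(col_means)
        grid = np.where(np.isnan(grid), fill, grid)
    raw = grid @ w
    return [PRSResult(pid, score_type, float(r))
            for pid, r in zip(dosages.patient_ids, raw)]


def shift_nonnegative(scores: Sequence[PRSResult]) -> list[PRSResult]:
    """Linearly shift scores so the minimum is exactly 0 (order-preserving).

    Applied to already-transformed scores the shift is a no-op, so the
    operation is idempotent.
    """
    if not scores:
        raise ValueError("empty score list")
    base = [s.transformed_score if s.transformed_score is not None
            else s.raw_score for s in scores]
    lo = min(base)
    return [PRSResult(s.patient_id, s.score_type, s.raw_score,
                      transformed_score=b - lo, centile=s.centile)
            for s, b in zip(scores, base)]


def centiles(scores: Sequence[PRSResult],
             reference_scores: Sequence[float]) -> list[PRSResult]:
    """Attach a 0-100 centile against a reference score distribution.

    centile = round(100 * fraction of reference strictly below the score);
    a score tied with reference values counts none of its ties, so the
    reference maximum maps to round(100 * (n-1)/n) and anything above the
    maximum to 100.
    """
    ref = np.sort(np.asarray(list(reference_scores), dtype=float))
    if ref.size == 0:
        raise ValueError("empty reference")
    out = []
    for s in scores:
        value = (s.transformed_score if s.transformed_score is not None
                 else s.raw_score)
        frac = np.searchsorted(ref, value, side="left") / ref.size
        out.append(PRSResult(s.patient_id, s.score_type, s.raw_score,
                             transformed_score=s.transformed_score,
                             centile=int(round(100 * float(frac)))))
    return out


# ---------------------------------------------------------------------------
# variant QC

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value on genotype counts.

    Conditions on the observed minor-allele count; the p-value sums the
    probabilities of all heterozygote counts whose conditional probability
    does not exceed that of the observed count.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # P(het = h | n, n_rare) via log factorials, h same parity as n_rare
    logfac = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, 2 * n + 1)))])

    def logp(h: int) -> float:
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        return (h * math.log(2) + logfac[n] - logfac[h] - logfac[hom_rare]
                - logfac[hom_common] + logfac[n_rare] + logfac[2 * n - n_rare]
                - logfac[2 * n])

    hs = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logps = np.array([logp(int(h)) for h in hs])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[np.where(hs == n_het)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hard_calls(column: np.ndarray) -> tuple[int, int, int]:
    called = column[~np.isnan(column)]
    g = np.rint(called).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def variant_qc(dosages: DosageMatrix,
               case_control_labels: Optional[Sequence[bool]] = None,
               config: VariantQCConfig = VariantQCConfig()) -> QCReport:
    """Apply threshold filters per variant, recording every failure reason.

    ``case_control_labels`` (True = case) enables the differential-
    missingness check; without labels that check is skipped.  The HWE test
    rounds dosages to hard calls, which is robust at the small sample sizes
    where the exact test matters.
    """
    labels = None
    if case_control_labels is not None:
        labels = np.asarray(list(case_control_labels), dtype=bool)
        if labels.size != len(dosages.patient_ids):
            raise ValueError("labels length != number of patients")

    kept, dropped = [], {}
    for j, vid in enumerate(dosages.variant_ids):
        col = dosages.dosages[:, j]
        reasons = []
        is_missing = np.isnan(col)
        miss_rate = float(is_missing.mean()) if col.size else 1.0
        if miss_rate > config.max_missing_rate:
            reasons.append("missingness")
        n0, n1, n2 = _hard_calls(col)
        n_called = n0 + n1 + n2
        if n_called == 0:
            if "missingness" not in reasons:
                reasons.append("missingness")
        else:
            af = (2 * n2 + n1) / (2 * n_called)
            maf = min(af, 1 - af)
            if maf < config.maf_floor:
                reasons.append("maf")
            if hwe_exact_test(n0, n1, n2) < config.hwe_p_floor:
                reasons.append("hwe")
        if labels is not None and labels.any() and (~labels).any():
            diff = abs(float(is_missing[labels].mean())
                       - float(is_missing[~labels].mean()))
            if diff > config.max_differential_missingness:
                reasons.append("differential_missingness")
        if reasons:
            dropped[vid] = reasons
        else:
            kept.append(vid)
    return QCReport(kept=kept, dropped=dropped)


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_weights(path: Union[str, Path]) -> list[VariantWeight]:
    """Read a three-column (variant_id, effect_allele, weight) weight table."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"variant_id", "effect_allele", "weight"}
    if not required <= set(df.columns):
        raise ValueError(f"weight table must have columns {sorted(required)}")
    return [VariantWeight(str(r.variant_id), str(r.effect_allele),
                          float(r.weight))
            for r in df.itertuples(index=False)]


def read_dosages(path: Union[str, Path],
                 variants_in_rows: bool = False) -> DosageMatrix:
    """Read a dosage table (patients in rows by default; NaN = missing)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if variants_in_rows:
        df = df.T
    return DosageMatrix(patient_ids=[str(i) for i in df.index],
                        variant_ids=[str(c) for c in df.columns],
                        dosages=df.to_numpy(dtype=float))
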