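"""Descriptive summaries and nonparametric group comparisons.

Continuous variables are summarised as median and interquartile range using
the linear-interpolation quantile convention at positions 1 + (n-1)p (the
default of most statistical environments, numpy's "linear" / R's type 7),
and compared between two groups with the Wilcoxon rank-sum test; categorical
variables are integer-coded and compared with the Kruskal-Wallis rank test.
That rank-test treatment of categoricals is unconventional but deliberate —
it reproduces the published comparison tables this module's output mirrors;
a chi-square/Fisher alternative is available behind a flag.  No
multiple-testing correction is applied by default.

The Wilcoxon implementation switches to exact full enumeration of the
rank-sum null distribution (midranks for ties) when the combined sample size
is at most 12, and otherwise uses the normal approximation with tie and
continuity corrections via scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chart_classification import CaseSummary  # noqa: F401  (API surface)
from .ehr_model import Analyte, Cohort, most_recent

__all__ = [
    "GroupComparison", "median_iqr", "wilcoxon_rank_sum", "kruskal_wallis",
    "compare_groups", "COMPARISON_VARIABLES",
]


@dataclass
class GroupComparison:
    variable: str
    group_summaries: dict[str, tuple[float, float, float]]  # median, q1, q3
    test: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value out of [0, 1]")


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation at positions 1 + (n-1)p."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by enumerating all group assignments of the ranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)       # midranks for ties
    nx = len(x)
    observed = ranks[:nx].sum()
    mean = ranks.sum() * nx / len(pooled)
    obs_dev = abs(observed - mean)
    total = more_extreme = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(ranks[list(combo)].sum() - mean) >= obs_dev - 1e-9:
            more_extreme += 1
    return float(observed), more_extreme / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      exact: Optional[bool] = None) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    Exact enumeration (midranks, combined n <= 12 by default) or the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if exact is None:
        exact = (x.size + y.size) <= 12
    if exact:
        return _rank_sum_exact(x, y)
    # scipy's asymptotic Mann-Whitney U applies midrank ties, the tie-variance
    # correction and a continuity correction; convert U back to the rank sum.
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    rank_sum = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return rank_sum, float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with a chi-square(k-1) reference."""
    cleaned = [np.asarray(list(g), dtype=float) for g in groups]
    if len(cleaned) < 2 or any(g.size == 0 for g in cleaned):
        raise ValueError("need >= 2 nonempty groups")
    if np.ptp(np.concatenate(cleaned)) == 0:
        return 0.0, 1.0     # all observations identical: H is 0 by definition
    res = sps.kruskal(*cleaned)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort-level comparison table

#: variable name -> extractor over a PatientRecord (most-recent convention)
def _recent_lab(analyte: Analyte):
    def extract(patient):
        entry = most_recent([l for l in patient.labs if l.analyte is analyte])
        return None if entry is None else entry.value
    return extract


def _recent_bmi(patient):
    entry = most_recent(patient.bmi)
    return None if entry is None else entry.value


def _age(patient):
    last_dates = ([l.date for l in patient.labs] + [b.date for b in patient.bmi])
    ref_year = max(d.year for d in last_dates) if last_dates else 2020
    return float(ref_year - patient.birth_year)


COMPARISON_VARIABLES = {
    "age_years": ("continuous", _age),
    "sex_female": ("categorical", lambda p: 1.0 if p.sex.value == "F" else 0.0),
    "most_recent_bmi": ("continuous", _recent_bmi),
    "most_recent_hba1c": ("continuous", _recent_lab(Analyte.HBA1C)),
    "most_recent_hdl": ("continuous", _recent_lab(Analyte.HDL)),
    "most_recent_tg": ("continuous", _recent_lab(Analyte.TG)),
}


def compare_groups(ad_ids: Sequence[str], t1d_ids: Sequence[str],
                   t2d_ids: Sequence[str], cohort: Cohort,
                   variables: Optional[dict] = None,
                   categorical_test: str = "rank") -> list[GroupComparison]:
    """Pairwise comparison table: AD vs ML-T1D and AD vs ML-T2D per variable.

    The three id sets must be disjoint (algorithm-identified patients are
    removed from the ML groups before comparison).  Continuous variables use
    the Wilcoxon rank-sum test; categorical variables use the Kruskal-Wallis
    rank test on integer codes by default (``categorical_test="chi2"``
    switches to a chi-square test of independence).
    """
    groups = {"AD": list(ad_ids), "ML_T1D": list(t1d_ids),
              "ML_T2D": list(t2d_ids)}
    all_ids = sum(groups.values(), [])
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("group id sets must be disjoint")
    by_id = cohort.by_id()
    unknown = [i for i in all_ids if i not in by_id]
    if unknown:
        raise ValueError(f"unknown ids: {unknown[:5]}")
    variables = variables or COMPARISON_VARIABLES

    rows: list[GroupComparison] = []
    for name, (kind, extract) in variables.items():
        series = {g: np.array([v for v in (extract(by_id[i]) for i in ids)
                               if v is not None], dtype=float)
                  for g, ids in groups.items()}
        summaries = {g: median_iqr(vals) for g, vals in series.items()
                     if vals.size}
        for other in ("ML_T1D", "ML_T2D"):
            a, b = series["AD"], series[other]
            if a.size == 0 or b.size == 0:
                continue
            if kind == "continuous":
                stat, p = wilcoxon_rank_sum(a, b)
                test = "wilcoxon_rank_sum"
            elif categorical_test == "rank":
                stat, p = kruskal_wallis([a, b])
                test = "kruskal_wallis"
            else:
                tbl = pd.crosstab(
                    np.concatenate([np.zeros(a.size), np.ones(b.size)]),
                    np.concatenate([a, b]))
                stat, p, *_ = sps.chi2_contingency(tbl)
                test = "chi2"
            rows.append(GroupComparison(
                variable=f"{name}:AD_vs_{other}",
                group_summaries={"AD": summaries["AD"],
                                 other: summaries[other]},
                test=test, statistic=float(stat), p_value=float(p)))
    return rows
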