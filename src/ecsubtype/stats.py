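"""Cohort-level statistics: contingency tests, rank tests for mutational
load, Kaplan-Meier estimation and the k-group log-rank test.

Backed by scipy (Pearson chi-square, Kruskal-Wallis, rank-sum) and
lifelines (product-limit estimator, log-rank); this module adds the input
validation, conventions (median survival = first time the estimator drops
to <= 0.5) and degenerate-input handling the pipeline relies on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contingency

@dataclass(frozen=True)
class ContingencyTable:
    """r x c non-negative integer counts with row/column labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @classmethod
    def from_lists(cls, counts, row_labels=(), col_labels=()) -> "ContingencyTable":
        return cls(tuple(tuple(int(x) for x in row) for row in counts),
                   tuple(row_labels), tuple(col_labels))


def chi_square_test(
    table: ContingencyTable | Sequence[Sequence[int]],
    correction: Literal["none", "yates"] = "none",
) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table: (statistic, df, p).

    Default is the uncorrected Pearson form; Yates continuity correction
    available by flag.  A zero row/column margin is a named error, not a
    silent NaN.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_lists(table)
    arr = table.array
    row_m = arr.sum(axis=1)
    col_m = arr.sum(axis=0)
    for i, m in enumerate(row_m):
        if m == 0:
            name = table.row_labels[i] if table.row_labels else f"row {i}"
            raise ValueError(f"zero margin in {name}")
    for j, m in enumerate(col_m):
        if m == 0:
            name = table.col_labels[j] if table.col_labels else f"column {j}"
            raise ValueError(f"zero margin in {name}")
    res = sps.chi2_contingency(arr, correction=(correction == "yates"))
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# rank tests on mutational load

def rank_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Nonparametric location test across k groups of per-sample loads.

    k = 2: Mann-Whitney/Wilcoxon rank-sum (exact for small tie-free
    samples, tie-corrected normal approximation otherwise); k > 2:
    Kruskal-Wallis with the chi-square approximation.  Returns
    (statistic, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("rank_test requires at least 2 groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if len(groups) == 2:
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                               method="auto")
        return float(res.statistic), float(res.pvalue)
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# survival

@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float              # months since diagnosis
    event: int               # 1 = event observed, 0 = censored
    endpoint: Literal["DFS", "OS"] = "DFS"
    group: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"non-positive survival time for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


@dataclass
class KmCurve:
    """Product-limit estimate: right-continuous non-increasing step
    function with S(0) = 1."""

    times: np.ndarray          # event times where the estimate steps
    survival: np.ndarray       # S(t) just after each step
    median: float | None       # first t with S(t) <= 0.5; None if unreached

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier product-limit estimator (lifelines backend).

    Subjects censored at t leave the risk set after the events at t.
    Median survival is the earliest time at which S(t) <= 0.5, absent
    (None) when the curve never reaches 0.5.
    """
    from lifelines import KaplanMeierFitter

    if not records:
        raise ValueError("km_estimate requires at least one subject")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    t, s = t[keep], s[keep]
    median_candidates = t[s <= 0.5]
    median = float(median_candidates[0]) if median_candidates.size else None
    return KmCurve(times=t, survival=s, median=median)


def logrank_test(records: Sequence[SurvivalRecord]) -> LogRankResult:
    """k-group log-rank test with hypergeometric expectations at each
    distinct event time (lifelines backend); df = k - 1.

    All-censored input returns (statistic 0, p 1) with a warning.
    """
    from lifelines.statistics import multivariate_logrank_test

    if not records:
        raise ValueError("logrank_test requires subjects")
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("logrank_test requires at least 2 groups")
    df = len(groups) - 1
    if all(r.event == 0 for r in records):
        logger.warning("log-rank on fully censored data: statistic 0, p 1")
        return LogRankResult(statistic=0.0, df=df, p=1.0)
    frame = pd.DataFrame({
        "time": [r.time for r in records],
        "event": [r.event for r in records],
        "group": [r.group for r in records],
    })
    res = multivariate_logrank_test(frame["time"], frame["group"], frame["event"])
    return LogRankResult(statistic=float(res.test_statistic), df=df,
                         p=float(res.p_value))


def survival_records_from_frame(
    frame: pd.DataFrame, endpoint: str = "DFS"
) -> list[SurvivalRecord]:
    """Rows of the survival TSV (sample_id, endpoint, time_months, event,
    group) for one endpoint."""
    sub = frame[frame["endpoint"] == endpoint]
    return [
        SurvivalRecord(sample_id=str(r.sample_id), time=float(r.time_months),
                       event=int(r.event), endpoint=endpoint, group=str(r.group))
        for r in sub.itertuples()
    ]


__all__ = [
    "ContingencyTable", "chi_square_test", "rank_test",
    "SurvivalRecord", "KmCurve", "LogRankResult",
    "km_estimate", "logrank_test", "survival_records_from_frame",
]
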