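"""Per-biomarker significance thresholds for the stage-2 interaction tests.

Three allocation schemes convert stage-1 information into a
``ThresholdSchedule``:

* ``bonferroni_schedule`` — the single-step baseline, alpha/m everywhere.
* ``subset_schedule``     — Bonferroni over the m* biomarkers passing the
  stage-1 threshold alpha1; unselected biomarkers are not tested at all.
* ``weighted_schedule``   — rank-weighted buckets: the B best-ranked
  biomarkers are tested at (alpha/2)/B, the next 2B at (alpha/4)/(2B), the
  next 2^k*B at (alpha/2^(k+1))/(2^k*B), and so on.  The total allocated
  alpha is the geometric sum alpha/2 + alpha/4 + ... <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .interaction import InteractionResult
from .screening import ScreeningResult

__all__ = [
    "ThresholdSchedule",
    "DecisionSet",
    "bonferroni_schedule",
    "subset_schedule",
    "weighted_schedule",
    "apply_schedule",
]

_BUDGET_TOL = 1e-12


@dataclass
class ThresholdSchedule:
    """Per-biomarker stage-2 significance thresholds (0 = not tested)."""

    alpha: float
    thresholds: np.ndarray
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"overall level alpha must be in (0,1), got {self.alpha}")
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if ((self.thresholds < 0.0) | (self.thresholds > 1.0)).any():
            raise ConfigurationError("thresholds must lie in [0, 1]")
        if self.thresholds.sum() > self.alpha + _BUDGET_TOL:
            raise ConfigurationError(
                f"allocated alpha {self.thresholds.sum():.6g} exceeds target {self.alpha}"
            )

    @property
    def m(self) -> int:
        return self.thresholds.shape[0]

    @property
    def tested(self) -> np.ndarray:
        """1-based indices of biomarkers with a positive threshold."""
        return np.flatnonzero(self.thresholds > 0.0) + 1

    def to_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        names = names or [f"X{j}" for j in range(1, self.m + 1)]
        return pd.DataFrame(
            {"biomarker": names, "threshold": self.thresholds, "scheme": self.scheme}
        )


@dataclass
class DecisionSet:
    """Stage-2 rejection decisions for one procedure on one dataset."""

    rejected: np.ndarray  # 1-based biomarker indices, ascending
    table: pd.DataFrame  # biomarker, p_value, threshold, rejected
    procedure: str = ""

    @property
    def any_rejection(self) -> bool:
        return self.rejected.size > 0


def bonferroni_schedule(alpha: float, m: int) -> ThresholdSchedule:
    """Single-step Bonferroni: every biomarker tested at alpha/m."""
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return ThresholdSchedule(
        alpha=alpha,
        thresholds=np.full(m, alpha / m),
        scheme="bonferroni",
        params={"m": m},
    )


def subset_schedule(alpha: float, screening: ScreeningResult, alpha1: float) -> ThresholdSchedule:
    """Bonferroni over the stage-1 selected subset.

    Selection keeps biomarkers with stage-1 p-value strictly below
    ``alpha1`` (m* of them); each is tested at alpha/m*.  If nothing is
    selected the schedule is all-zero and no stage-2 test is performed.
    """
    if screening.method != "univariate":
        raise ConfigurationError("subset_schedule requires univariate (p-value) screening")
    pvals = np.asarray(screening.scores, dtype=float)
    if np.isnan(pvals).any():
        raise ConfigurationError("stage-1 p-values contain NaN")
    selected = pvals < alpha1
    m_star = int(selected.sum())
    thresholds = np.zeros(screening.m)
    if m_star:
        thresholds[selected] = alpha / m_star
    return ThresholdSchedule(
        alpha=alpha,
        thresholds=thresholds,
        scheme="subset",
        params={"alpha1": alpha1, "m_star": m_star},
    )


def weighted_bucket_thresholds(alpha: float, m: int, B: int) -> np.ndarray:
    """Per-rank thresholds for the geometric bucket scheme (rank order)."""
    out = np.empty(m)
    start, k = 0, 0
    while start < m:
        size = (2**k) * B
        out[start : min(start + size, m)] = (alpha / 2 ** (k + 1)) / size
        start += size
        k += 1
    return out


def weighted_schedule(alpha: float, ranking: np.ndarray, B: int = 5) -> ThresholdSchedule:
    """Rank-weighted bucket thresholds from a stage-1 ranking (best first).

    The final bucket is truncated at m but keeps its full per-test
    threshold (unused alpha mass is not redistributed), so the scheme stays
    conservative.
    """
    ranking = np.asarray(ranking, dtype=int)
    m = ranking.shape[0]
    if B < 1:
        raise ConfigurationError("bucket size B must be >= 1")
    if not np.array_equal(np.sort(ranking), np.arange(1, m + 1)):
        raise ConfigurationError("ranking must be a permutation of 1..m")
    per_rank = weighted_bucket_thresholds(alpha, m, B)
    thresholds = np.empty(m)
    thresholds[ranking - 1] = per_rank
    return ThresholdSchedule(
        alpha=alpha,
        thresholds=thresholds,
        scheme="weighted",
        params={"B": B},
    )


def apply_schedule(interactions: InteractionResult, schedule: ThresholdSchedule) -> DecisionSet:
    """Reject biomarker j iff its stage-2 p-value is strictly below its
    (positive) threshold.  ``interactions`` may cover a subset of the
    schedule; every biomarker it covers must be inside the schedule, and
    every biomarker the schedule wants tested must be covered."""
    idx = interactions.indices
    if idx.size and idx.max() > schedule.m:
        raise ConfigurationError("interaction results refer to biomarkers outside the schedule")
    missing = np.setdiff1d(schedule.tested, idx)
    if missing.size:
        raise ConfigurationError(
            f"schedule requires stage-2 tests for untested biomarkers: {missing.tolist()}"
        )
    thr = schedule.thresholds[idx - 1]
    reject = (interactions.p_value < thr) & (thr > 0.0)
    table = pd.DataFrame(
        {
            "biomarker": interactions.names,
            "index": idx,
            "p_value": interactions.p_value,
            "threshold": thr,
            "rejected": reject,
        }
    )
    return DecisionSet(rejected=np.sort(idx[reject]), table=table, procedure=schedule.scheme)
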