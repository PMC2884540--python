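"""Relating alignment uncertainty to tree inference accuracy.

Four per-sample measures: tree accuracy TA (one minus the normalised
Robinson-Foulds distance to the accepted topology), tree support BS (the
fraction of bootstrap replicates agreeing with the inferred topology),
tree variability TV (average Robinson-Foulds distance among trees from
different alignment methods) and alignment variability AV (average
distance among the alignments themselves).  The question asked here is
which of BS and AV better predicts TA; the answer is given by comparing
the two Spearman rank correlations through the Fisher Z-transform, under
the null r_s(BS, TA) = −r_s(AV, TA) of equal predictive power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .trees import Tree, robinson_foulds

__all__ = [
    "UndefinedCorrelationError",
    "UncertaintySample",
    "CorrelationComparison",
    "tree_variability",
    "spearman_rank_correlation",
    "compare_correlations",
    "uncertainty_analysis",
]


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance or |r| = 1)."""


@dataclass
class UncertaintySample:
    """Per-sample uncertainty measures."""

    sample_id: str
    tree_accuracy: float  # TA in [0, 1]
    bootstrap_support: float  # BS in [0, 1]
    tree_variability: float  # TV >= 0
    alignment_variability: float  # AV in [0, 1]

    def __post_init__(self) -> None:
        for name in (
            "tree_accuracy",
            "bootstrap_support",
            "tree_variability",
            "alignment_variability",
        ):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite")
        if not 0 <= self.tree_accuracy <= 1:
            raise ValueError("tree accuracy must be in [0, 1]")
        if not 0 <= self.bootstrap_support <= 1:
            raise ValueError("bootstrap support must be in [0, 1]")
        if not 0 <= self.alignment_variability <= 1:
            raise ValueError("alignment variability must be in [0, 1]")
        if self.tree_variability < 0:
            raise ValueError("tree variability must be >= 0")


@dataclass
class CorrelationComparison:
    """Result of comparing the two predictors of tree accuracy."""

    r_support: float  # r_s(BS, TA)
    r_variability: float  # r_s(AV, TA)
    n: int
    statistic: float
    p_two_sided: float
    p_one_sided: float  # alternative: r_s(BS, TA) > -r_s(AV, TA)


def tree_variability(trees: Sequence[Tree]) -> float:
    """Mean pairwise Robinson-Foulds distance among trees of one sample."""
    if len(trees) < 2:
        raise ValueError("need >= 2 trees")
    dists = [robinson_foulds(a, b) for a, b in combinations(trees, 2)]
    return sum(dists) / len(dists)


def spearman_rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks on ties)."""
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 4:
        raise ValueError("need >= 4 observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise UndefinedCorrelationError("zero variance in an input vector")
    r = stats.spearmanr(x, y).statistic
    return float(r)


def compare_correlations(
    r1: float,
    r2: float,
    n: int,
    dependent: bool = False,
    r12: Optional[float] = None,
) -> Tuple[float, float, float]:
    """Test the null r1 = −r2 via Fisher Z-transformed correlations.

    Returns (statistic, two-sided p, one-sided p); the one-sided
    alternative is r1 > −r2.  The default treats the two transformed
    correlations as independent with variance 1/(n−3) each.  With
    ``dependent=True`` (requires ``r12``, the correlation between the two
    predictor variables) the variance accounts for the covariance induced
    by the shared outcome variable, following the classic dependent-
    correlation adjustment.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise UndefinedCorrelationError(
                "|r| = 1 makes the Fisher transform infinite"
            )
    z1 = math.atanh(r1)
    z2 = math.atanh(-r2)
    if not dependent:
        var = 2.0 / (n - 3)
    else:
        if r12 is None:
            raise ValueError("dependent comparison requires r12")
        # covariance of the two Fisher-transformed correlations sharing a
        # variable (Steiger's approximation), with r2 sign-flipped to match
        # the null; rbar is the mean of the compared correlations.
        ra, rb, rc = r1, -r2, -r12
        rbar = (ra + rb) / 2.0
        num = rc * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - rc**2)
        cov = num / ((1 - rbar**2) ** 2)
        var = (2.0 - 2.0 * cov) / (n - 3)
        var = max(var, 1e-12)
    statistic = (z1 - z2) / math.sqrt(var)
    p_two = 2.0 * stats.norm.sf(abs(statistic))
    p_one = stats.norm.sf(statistic)
    return statistic, float(p_two), float(p_one)


def uncertainty_analysis(
    samples: Sequence[UncertaintySample],
    dependent: bool = False,
) -> CorrelationComparison:
    """Compare bootstrap support and alignment variability as predictors of
    tree accuracy over a set of samples."""
    if len(samples) < 10:
        raise ValueError("need >= 10 samples")
    ta = [s.tree_accuracy for s in samples]
    bs = [s.bootstrap_support for s in samples]
    av = [s.alignment_variability for s in samples]
    r_support = spearman_rank_correlation(bs, ta)
    r_variability = spearman_rank_correlation(av, ta)
    r12 = spearman_rank_correlation(bs, av) if dependent else None
    statistic, p_two, p_one = compare_correlations(
        r_support, r_variability, len(samples), dependent=dependent, r12=r12
    )
    return CorrelationComparison(
        r_support=r_support,
        r_variability=r_variability,
        n=len(samples),
        statistic=statistic,
        p_two_sided=p_two,
        p_one_sided=p_one,
    )
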