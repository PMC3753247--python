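"""Exact binomial tests, Bonferroni correction, significance boundaries for
learning curves, and group t-tests against chance.

Individual performance over n games with k wins is tested one-sided against
chance 1/3 with the exact binomial upper tail

    p = sum_{k <= i <= n} C(n, i) (1/3)^i (2/3)^(n-i),

one-sided because learning can only be expected to improve performance.
With 10 players per condition, a result is called significant below
alpha = 0.05 / 10 = 0.005 (Bonferroni).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .game import SessionResult

__all__ = [
    "BinomialTestResult",
    "SignificanceBoundary",
    "GroupTestResult",
    "LearningCurveResult",
    "binomial_tail",
    "bonferroni",
    "significance_boundary",
    "learning_curve",
    "t_tests",
]

CHANCE = 1.0 / 3.0


@dataclass(frozen=True)
class BinomialTestResult:
    n: int
    k: int
    p_chance: float
    p_value: float
    alpha: float
    alpha_corrected: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_corrected

    @property
    def p_rounded(self) -> float:
        """3-decimal presentation value."""
        return round(self.p_value, 3)


def binomial_tail(
    n: int,
    k: int,
    p_chance: float = CHANCE,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> BinomialTestResult:
    """Exact one-sided upper-tail binomial probability of >= k wins in n games.

    Computed through the regularized incomplete beta function
    (``scipy.stats.binom.sf``), which agrees with direct term-by-term
    summation to better than 1e-12 relative error.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p_chance < 1.0:
        raise ValueError("p_chance must lie strictly inside (0, 1)")
    p = float(sps.binom.sf(k - 1, n, p_chance))
    return BinomialTestResult(
        n=n, k=k, p_chance=p_chance, p_value=p,
        alpha=alpha, alpha_corrected=bonferroni(alpha, n_comparisons),
    )


def bonferroni(alpha: float, m: int) -> float:
    """Corrected per-test level alpha / m for m simultaneous tests."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


@dataclass
class SignificanceBoundary:
    """Per-n minimal win count whose upper-tail probability is below alpha.

    ``k_min[n-1]`` is the boundary for n games, or -1 where even k = n does
    not reach significance (small n).
    """

    alpha: float
    p_chance: float
    k_min: np.ndarray

    def as_dataframe(self) -> pd.DataFrame:
        n = np.arange(1, self.k_min.size + 1)
        return pd.DataFrame({"n": n, "k_min": self.k_min})

    def boundary_fraction(self) -> np.ndarray:
        """k_min / n with NaN where no k qualifies."""
        n = np.arange(1, self.k_min.size + 1)
        frac = self.k_min / n
        frac[self.k_min < 0] = np.nan
        return frac


def significance_boundary(
    n_max: int, alpha: float = 0.05, p_chance: float = CHANCE
) -> SignificanceBoundary:
    """Least k with tail probability < alpha, for every n in 1..n_max."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    k_min = np.full(n_max, -1, dtype=np.int64)
    for n in range(1, n_max + 1):
        ks = np.arange(0, n + 1)
        tails = sps.binom.sf(ks - 1, n, p_chance)
        hits = np.nonzero(tails < alpha)[0]
        if hits.size:
            k_min[n - 1] = ks[hits[0]]
    return SignificanceBoundary(alpha=alpha, p_chance=p_chance, k_min=k_min)


@dataclass
class LearningCurveResult:
    cumulative_wins: np.ndarray
    p_values: np.ndarray  # tail probability considering all preceding games
    alpha_corrected: float
    first_significant_game: int | None  # 1-based, None if never


def learning_curve(
    session: SessionResult,
    alpha: float = 0.05,
    m_comparisons: int = 10,
    p_chance: float = CHANCE,
) -> LearningCurveResult:
    """Cumulative wins after each game and the first game at which the
    running exact binomial tail (all preceding games included) drops below
    the Bonferroni-corrected level."""
    if session.n_games == 0:
        raise ValueError("empty session")
    cum = session.cumulative_wins
    ns = np.arange(1, session.n_games + 1)
    p_values = sps.binom.sf(cum - 1, ns, p_chance)
    level = bonferroni(alpha, m_comparisons)
    sig = np.nonzero(p_values < level)[0]
    first = int(sig[0]) + 1 if sig.size else None
    return LearningCurveResult(
        cumulative_wins=cum,
        p_values=p_values,
        alpha_corrected=level,
        first_significant_game=first,
    )


@dataclass(frozen=True)
class GroupTestResult:
    kind: str  # one_sample | paired | unpaired
    t: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float  # the constant for one-sample tests


def t_tests(
    group_a,
    group_b=None,
    kind: str = "one_sample",
    popmean: float = CHANCE,
    equal_var: bool = True,
) -> GroupTestResult:
    """Two-sided t-tests on win fractions.

    one_sample compares a group against a constant (chance = 1/3 by
    default); paired and unpaired compare two groups (pooled-variance
    Student's t for unpaired unless ``equal_var=False``).  Zero-variance
    inputs are degenerate: equal means report t = 0, p = 1; unequal means
    report p = 0 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two observations per group")
    if kind == "one_sample":
        if group_b is not None:
            raise ValueError("one_sample takes a constant popmean, not a second group")
        diffs = a - popmean
        mean_b = popmean
        df = a.size - 1
    elif kind in ("paired", "unpaired"):
        b = np.asarray(group_b, dtype=float)
        if b.size < 2:
            raise ValueError("need at least two observations per group")
        if kind == "paired":
            if a.size != b.size:
                raise ValueError("paired groups must have equal sizes")
            diffs = a - b
            df = a.size - 1
        else:
            df = a.size + b.size - 2 if equal_var else None
        mean_b = float(b.mean())
    else:
        raise ValueError(f"unknown test kind: {kind!r}")

    if kind in ("one_sample", "paired"):
        if np.allclose(np.std(diffs, ddof=1), 0.0):
            if np.isclose(diffs.mean(), 0.0):
                return GroupTestResult(kind, 0.0, df, 1.0, float(a.mean()), mean_b)
            warnings.warn(
                "zero within-group variance with unequal means: t is infinite, "
                "reporting p = 0", RuntimeWarning, stacklevel=2,
            )
            t = np.inf if diffs.mean() > 0 else -np.inf
            return GroupTestResult(kind, float(t), df, 0.0, float(a.mean()), mean_b)
        if kind == "one_sample":
            res = sps.ttest_1samp(a, popmean)
        else:
            res = sps.ttest_rel(a, b)
    else:
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            if np.isclose(a.mean(), b.mean()):
                return GroupTestResult(kind, 0.0, df, 1.0, float(a.mean()), mean_b)
            warnings.warn(
                "zero variance in both groups with unequal means: t is infinite, "
                "reporting p = 0", RuntimeWarning, stacklevel=2,
            )
            t = np.inf if a.mean() > b.mean() else -np.inf
            return GroupTestResult(kind, float(t), df, 0.0, float(a.mean()), mean_b)
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        if not equal_var:
            df = int(round(res.df))
    return GroupTestResult(
        kind=kind,
        t=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=mean_b,
    )
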