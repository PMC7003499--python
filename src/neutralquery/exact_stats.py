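"""Exact and classical tests for small contingency tables and proportions.

Everything here operates on desk-scale integer counts: Fisher's exact test
on 2x2 tables, cross-product odds ratios, exact binomial tests against a
null proportion, Pearson chi-square tests of independence and goodness of
fit, and the point-biserial correlation.  Numerics are delegated to
:mod:`scipy.stats`; this module fixes the conventions:

* Fisher's test requires an explicit ``alternative`` — the directional
  hypothesis "group 1 switches more" is ``greater`` on a table whose first
  row is group 1 (switched, stayed).
* The two-sided exact binomial p-value is the doubled smaller tail, capped
  at 1 (identical to the minimum-likelihood method at p0 = 0.5, the only
  null used here).
* Chi-square tests apply no continuity correction unless asked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import (
    DegenerateTableError,
    ParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "Counts2x2",
    "TestResult",
    "PointBiserialResult",
    "fisher_exact",
    "odds_ratio",
    "binomial_test",
    "chi2_contingency",
    "chi2_goodness_of_fit",
    "point_biserial",
]

_ALTERNATIVES = ("two_sided", "greater", "less")
_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class Counts2x2:
    """A 2x2 table of nonnegative integer counts.

    Row 1 is group 1 (e.g. knowledgeable: switched, stayed) and row 2 is
    group 2.  Layout::

        a  b
        c  d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and not isinstance(v, bool)) or v < 0:
                raise ParameterError(f"cell {name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.total == 0:
            raise ParameterError("table must contain at least one observation")

    @classmethod
    def from_rows(cls, row1: Sequence[int], row2: Sequence[int]) -> "Counts2x2":
        (a, b), (c, d) = row1, row2
        return cls(a, b, c, d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a significance test.

    ``statistic``/``df`` are ``None`` where the test has no natural
    test statistic or degrees of freedom (exact tests).
    """

    statistic: float | None
    df: int | None
    p_value: float
    method: str
    alternative: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p_value out of [0, 1]: {self.p_value!r}")


def _check_alternative(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ParameterError(
            f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}"
        )
    return alternative


def fisher_exact(table: Counts2x2, alternative: str) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The p-value is the exact hypergeometric tail (one-sided) or the sum of
    all tables with probability no greater than the observed one
    (two-sided).  ``alternative`` is deliberately required: directional
    predictions must be stated, not defaulted.  A table with a zero margin
    carries no information; it yields p = 1 flagged as degenerate.
    """
    _check_alternative(alternative)
    if 0 in table.row_totals or 0 in table.col_totals:
        return TestResult(
            statistic=None,
            df=None,
            p_value=1.0,
            method="fisher_exact (degenerate margin)",
            alternative=alternative,
        )
    _, p = _sps.fisher_exact(table.to_array(), alternative=_SCIPY_ALT[alternative])
    return TestResult(
        statistic=None,
        df=None,
        p_value=float(min(1.0, p)),
        method="fisher_exact",
        alternative=alternative,
    )


def odds_ratio(table: Counts2x2) -> float:
    """Cross-product (sample) odds ratio a*d / (b*c).

    Returns ``inf`` when only the denominator product is zero; a 0/0 table
    has no defined odds ratio and raises :class:`UndefinedStatisticError`.
    """
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        if num == 0:
            raise UndefinedStatisticError("odds ratio undefined: both cross-products are zero")
        return math.inf
    return num / den


def binomial_test(
    k: int, n: int, p0: float = 0.5, alternative: str = "two_sided"
) -> TestResult:
    """Exact binomial test of ``k`` successes in ``n`` trials against ``p0``.

    Two-sided p = min(1, 2 * min(lower tail, upper tail)).
    """
    _check_alternative(alternative)
    if not (isinstance(n, (int, np.integer)) and n > 0):
        raise ParameterError(f"n must be a positive integer, got {n!r}")
    if not (isinstance(k, (int, np.integer)) and 0 <= k <= n):
        raise ParameterError(f"k must be an integer in [0, n], got {k!r}")
    if not (0.0 < p0 < 1.0):
        raise ParameterError(f"p0 must lie strictly inside (0, 1), got {p0!r}")
    lower = float(_sps.binom.cdf(k, n, p0))
    upper = float(_sps.binom.sf(k - 1, n, p0))
    if alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    else:
        p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(
        statistic=k / n,
        df=None,
        p_value=min(1.0, p),
        method="exact_binomial",
        alternative=alternative,
    )


def chi2_contingency(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 (or r x k) table.

    ``correction`` (Yates) defaults to off.  All expected cells must be
    positive; otherwise the statistic is undefined.
    """
    obs = table.to_array() if isinstance(table, Counts2x2) else np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ParameterError("table must be a 2-D array of nonnegative counts")
    total = obs.sum()
    if total == 0:
        raise DegenerateTableError("all-zero table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        raise DegenerateTableError("zero expected cell (empty row or column margin)")
    stat, p, dof, _ = _sps.chi2_contingency(obs, correction=correction)
    return TestResult(
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        method="pearson_chi2" + ("_yates" if correction else ""),
        alternative="two_sided",
    )


def chi2_goodness_of_fit(
    observed: Sequence[int], expected: Sequence[float] | None = None
) -> TestResult:
    """Pearson goodness-of-fit test of observed counts against expected
    proportions (default: uniform).  df = k - 1."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or len(obs) < 2 or np.any(obs < 0):
        raise ParameterError("observed must be a 1-D vector of >= 2 nonnegative counts")
    n = obs.sum()
    if n == 0:
        raise DegenerateTableError("all-zero observed counts")
    if expected is None:
        props = np.full(len(obs), 1.0 / len(obs))
    else:
        props = np.asarray(expected, dtype=float)
        if props.shape != obs.shape:
            raise ParameterError("observed and expected lengths differ")
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ParameterError("expected proportions must be nonnegative and sum to 1")
    exp_counts = n * props
    if np.any(exp_counts == 0):
        raise DegenerateTableError("zero expected count")
    stat, p = _sps.chisquare(obs, f_exp=exp_counts)
    return TestResult(
        statistic=float(stat),
        df=len(obs) - 1,
        p_value=float(p),
        method="pearson_chi2_gof",
        alternative="two_sided",
    )


@dataclass(frozen=True)
class PointBiserialResult:
    r: float
    t: float
    df: int
    p_value: float


def point_biserial(binary: Sequence[int], x: Sequence[float]) -> PointBiserialResult:
    """Point-biserial correlation between a 0/1 outcome and a covariate.

    Equivalent to the Pearson correlation of the indicator with ``x``;
    t = r * sqrt(df / (1 - r^2)) with df = n - 2, two-sided p.  Perfectly
    separated groups give |r| = 1 with an infinite t and p = 0.
    """
    b = np.asarray(binary, dtype=float)
    v = np.asarray(x, dtype=float)
    if b.shape != v.shape or b.ndim != 1:
        raise ParameterError("binary and x must be 1-D vectors of equal length")
    if len(b) < 3:
        raise ParameterError("need at least 3 observations")
    if not set(np.unique(b)) <= {0.0, 1.0}:
        raise ParameterError("binary vector must contain only 0s and 1s")
    if len(np.unique(b)) < 2:
        raise UndefinedStatisticError("both outcome groups must be non-empty")
    if np.ptp(v) == 0:
        raise UndefinedStatisticError("covariate is constant; correlation undefined")
    r, p = _sps.pointbiserialr(b, v)
    r = float(r)
    df = len(b) - 2
    if abs(r) >= 1.0 - 1e-15:
        return PointBiserialResult(r=math.copysign(1.0, r), t=math.copysign(math.inf, r), df=df, p_value=0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    return PointBiserialResult(r=r, t=t, df=df, p_value=float(p))
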