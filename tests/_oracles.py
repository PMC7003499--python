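"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation paths they check: posterior
beliefs come from enumerating the joint over {world state} x {statement},
exact tests from direct enumeration of the hypergeometric / binomial
supports with integer combinatorics, and the model fit from a dense grid
search.
"""

from __future__ import annotations

import math
from math import comb


def enumerate_posterior(
    prior: float,
    statement: str,
    knowledgeable: bool,
    alpha_c: float,
    beta_i: float,
    beta_c: float = 0.0,
    alpha_i: float = 0.0,
) -> float:
    """P(initial guess correct | statement) by joint enumeration.

    Builds the joint distribution over {guess correct, guess incorrect} x
    {correct, incorrect, neutral} and conditions on the statement column.
    For an ignorant informant the statement column is constant across world
    states (taken as all-neutral), so conditioning returns the prior.
    """
    if knowledgeable:
        rows = {
            True: {"correct": alpha_c, "incorrect": beta_c, "neutral": 1 - alpha_c - beta_c},
            False: {"correct": alpha_i, "incorrect": beta_i, "neutral": 1 - alpha_i - beta_i},
        }
    else:
        rows = {
            True: {"correct": 0.0, "incorrect": 0.0, "neutral": 1.0},
            False: {"correct": 0.0, "incorrect": 0.0, "neutral": 1.0},
        }
    joint_correct = prior * rows[True][statement]
    joint_incorrect = (1.0 - prior) * rows[False][statement]
    total = joint_correct + joint_incorrect
    if total == 0.0:
        raise ZeroDivisionError("statement impossible under both hypotheses")
    return joint_correct / total


def hypergeom_pmf(k: int, total: int, row1: int, col1: int) -> float:
    """P(cell a = k) for fixed margins, as an exact ratio of binomials."""
    if k < max(0, row1 + col1 - total) or k > min(row1, col1):
        return 0.0
    return comb(row1, k) * comb(total - row1, col1 - k) / comb(total, col1)


def fisher_enumeration(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """Fisher exact p by full enumeration of the conditional support."""
    total, row1, col1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    pmf = {k: hypergeom_pmf(k, total, row1, col1) for k in range(lo, hi + 1)}
    if alternative == "greater":
        return min(1.0, sum(p for k, p in pmf.items() if k >= a))
    if alternative == "less":
        return min(1.0, sum(p for k, p in pmf.items() if k <= a))
    cutoff = pmf[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in pmf.values() if p <= cutoff))


def binomial_enumeration(k: int, n: int, p0: float, alternative: str) -> float:
    """Exact binomial tail(s) by direct summation of the pmf."""
    pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    if alternative == "greater":
        return min(1.0, upper)
    if alternative == "less":
        return min(1.0, lower)
    return min(1.0, 2.0 * min(lower, upper))


def grid_fit_lambda(k_k: int, n_k: int, lapse: float,
                    lam_lo: float = 0.01, lam_hi: float = 5.0, n_grid: int = 5000) -> float:
    """Dense log-grid maximizer of the knowledgeable-arm binomial likelihood."""
    best_lam, best_ll = None, -math.inf
    for i in range(n_grid):
        lam = math.exp(
            math.log(lam_lo) + (math.log(lam_hi) - math.log(lam_lo)) * i / (n_grid - 1)
        )
        p = (1.0 - lapse) / (1.0 + lam) + lapse / 2.0
        if p <= 0.0 or p >= 1.0:
            continue
        ll = k_k * math.log(p) + (n_k - k_k) * math.log(1.0 - p)
        if ll > best_ll:
            best_lam, best_ll = lam, ll
    return best_lam
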