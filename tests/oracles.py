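"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity through a route deliberately
different from the package implementation: exhaustive enumeration for
the Fisher exact test, the closed-form hypergeometric mean for the
resampling null, and explicit normal equations for ordinary least
squares.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (central hypergeometric enumeration)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(x: int) -> float:
        # table [[x, row1-x], [col1-x, row2-(col1-x)]]
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = table_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def hypergeometric_mean(list_size: int, n_damaged: int, universe: int) -> float:
    """Expected overlap of a uniform size-N gene set with a damaged set."""
    return list_size * n_damaged / universe


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Slope estimates and standard errors via explicit normal equations."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se
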