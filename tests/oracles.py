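"""Independent oracles used by the tests.

Deliberately naive implementations (linear-system solves, rank arithmetic,
classical OLS stepwise) kept separate from the package code paths they
cross-check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def partition_direct_solve(r2_by_subset: dict[frozenset, float], groups: list[str]):
    """Solve the Venn-region system directly: r2(S) = sum of regions T with
    T intersecting S, one equation per non-empty subset S."""
    subsets = [frozenset(c) for r in range(1, len(groups) + 1)
               for c in combinations(sorted(groups), r)]
    a = np.zeros((len(subsets), len(subsets)))
    b = np.zeros(len(subsets))
    for i, s in enumerate(subsets):
        b[i] = r2_by_subset[s]
        for j, t in enumerate(subsets):
            if s & t:
                a[i, j] = 1.0
    x = np.linalg.solve(a, b)
    return dict(zip(subsets, x))


def ranksum_chi2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared standardized Wilcoxon rank-sum statistic (tie-corrected),
    which equals the two-group Kruskal-Wallis H."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, na = len(pooled), len(a)
    w = ranks[:na].sum()
    ew = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_w = na * (n - na) / 12.0 * ((n + 1) - tie_term)
    return float((w - ew) ** 2 / var_w)


def ols_aic(y: np.ndarray, x: np.ndarray) -> float:
    """Gaussian AIC with sigma^2 = RSS/n and the dispersion counted."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    n = len(y)
    rss = float(resid @ resid)
    sigma2 = rss / n
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return -2 * llf + 2 * (x.shape[1] + 1)


def ols_stepwise(y: np.ndarray, cols: dict[str, np.ndarray],
                 start: list[str] | None = None) -> list[str]:
    """Classical least-squares bidirectional AIC stepwise (intercept always
    in; ties broken drop-first then lexicographically)."""
    current = list(start or [])
    n = len(y)

    def design(terms):
        mats = [np.ones((n, 1))] + [cols[t][:, None] for t in terms]
        return np.hstack(mats)

    aic = ols_aic(y, design(current))
    while True:
        cand = []
        for t in current:
            cand.append((ols_aic(y, design([u for u in current if u != t])), 0, t, "drop"))
        for t in sorted(set(cols) - set(current)):
            cand.append((ols_aic(y, design(current + [t])), 1, t, "add"))
        if not cand:
            break
        cand.sort(key=lambda c: (c[0], c[1], c[2]))
        best, _, term, move = cand[0]
        if not best < aic - 1e-10:
            break
        current = [u for u in current if u != term] if move == "drop" else current + [term]
        aic = best
    return sorted(current)
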