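"""Binomial-based local-FDR estimator (BBE) and the nonlocal FDR it modifies.

The nonlocal FDR at significance level ``alpha`` estimates the expected
proportion of false discoveries among categories with p <= alpha as
min(m*alpha / #{p_j <= alpha}, 1).  BBE converts this into a per-category
local estimate by a rank-doubling device: the category with the i-th
smallest p-value receives min(m * p_(2i) / (2i), 1) where p_(k) is the k-th
order statistic, and categories in the upper half of the ranking receive 1.
The estimator is deliberately conservative (it tends to overestimate the
local FDR) and is the only one in this package besides the histogram
estimators that consumes p-values rather than counts.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nonlocal_fdr", "bbe_lfdr"]


def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p-values must form a non-empty 1-d vector")
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def nonlocal_fdr(p: np.ndarray, alpha: float) -> float:
    """Estimated nonlocal (Bayesian) FDR at significance level ``alpha``.

    Returns 1 when there are no discoveries (the conservative closure of
    the 0/0 case).
    """
    p = _check_pvalues(p)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    discoveries = int(np.sum(p <= alpha))
    if discoveries == 0:
        return 1.0
    return min(p.size * alpha / discoveries, 1.0)


def bbe_lfdr(p: np.ndarray) -> np.ndarray:
    """Binomial-based local-FDR estimates, one per input p-value.

    Ranks are assigned stably, so tied p-values keep their input order and
    the result is deterministic.  Outputs lie in [0, 1]; any category
    ranked above m/2 gets 1, so with a single category the estimate is the
    conservative 1.
    """
    p = _check_pvalues(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=np.int64)
    ranks[order] = np.arange(1, m + 1)
    p_sorted = p[order]
    out = np.ones(m)
    for i in range(m):
        r = ranks[i]
        if 2 * r <= m:
            out[i] = min(m * p_sorted[2 * r - 1] / (2 * r), 1.0)
    return out
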