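"""Normalized maximum likelihood (NML) Bayes-factor approximation and NMLE.

For a single category with statistic t on support {max(0,s+n-N)..min(s,n)},
the NML predictive pmf under a hypothesis set H of log-odds ratios is the
minimax-regret distribution

    f_dagger(t|s; H) = max_{theta in H} f_theta(t|s) / K_dagger(H),
    K_dagger(H)     = sum_y max_{theta in H} f_theta(y|s),

whose regret log[f_{theta_hat(t)}(t|s) / fbar(t|s)] is constant over the
support and equal to log K_dagger (the equalizer property).  The NML ratio

    BF_dagger = f_dagger(t|s; alt) / f_dagger(t|s; null)

approximates the Bayes factor of enrichment; combined with a supplied null
prior Pi0 it yields the NMLE local-FDR estimate
[1 + BF_dagger*(1-Pi0)/Pi0]^{-1}.  Unlike the mixture estimators this works
for a single category, at the price of requiring Pi0.

The alternative set excludes theta = 0 but is open, so its supremum equals
the supremum over all reals by continuity; outcomes at the support
endpoints have supremum pmf exactly 1 (the theta -> +/-inf limit), handled
analytically rather than by evaluating a large theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import optimize

from .contingency import conditional_log_pmf, support

__all__ = [
    "HypothesisSet",
    "NMLResult",
    "constrained_mle_theta",
    "nml_constant",
    "nml_predictive",
    "regret",
    "nml_ratio",
    "nmle_lfdr",
]

THETA_BOUND = 50.0  # interior score roots always lie well inside this box


class HypothesisSet(Enum):
    """Log-odds-ratio hypothesis sets: {0}, R \\ {0}, or all of R."""

    NULL = "null"
    ALTERNATIVE = "alternative"
    FULL = "full"


def _max_log_pmf_unrestricted(y: int, s: int, n: int, N: int
                              ) -> tuple[float, float]:
    """(theta_hat, max log f) over all reals; +/-inf sentinel at endpoints."""
    lo, hi = support(s, n, N)
    if lo == hi:
        return 0.0, 0.0  # degenerate support: pmf is 1 for every theta
    if y == hi:
        return np.inf, 0.0  # sup f = 1 as theta -> +inf
    if y == lo:
        return -np.inf, 0.0
    # interior outcome: log f is concave in theta, unique stationary point
    res = optimize.minimize_scalar(
        lambda th: -conditional_log_pmf(y, s, n, N, th),
        bounds=(-THETA_BOUND, THETA_BOUND), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)


def constrained_mle_theta(y: int, s: int, n: int, N: int,
                          H: HypothesisSet) -> float:
    """argmax over H of f_theta(y|s).

    Returns 0 for the null set; for the alternative / full sets solves the
    score equation numerically for interior outcomes and returns +/-inf
    sentinels at the support endpoints, where the supremum is a limit.
    """
    lo, hi = support(s, n, N)
    if not lo <= y <= hi:
        raise ValueError(f"y={y} outside support [{lo}, {hi}]")
    if H is HypothesisSet.NULL:
        return 0.0
    theta_hat, _ = _max_log_pmf_unrestricted(y, s, n, N)
    return theta_hat


def _sup_log_pmf(y: int, s: int, n: int, N: int, H: HypothesisSet) -> float:
    if H is HypothesisSet.NULL:
        return float(conditional_log_pmf(y, s, n, N, 0.0))
    return _max_log_pmf_unrestricted(y, s, n, N)[1]


def nml_constant(s: int, n: int, N: int, H: HypothesisSet) -> float:
    """Normalizer K_dagger(H) = sum over the support of sup_{theta in H} f_theta(y|s)."""
    lo, hi = support(s, n, N)
    return float(sum(np.exp(_sup_log_pmf(y, s, n, N, H))
                     for y in range(lo, hi + 1)))


def nml_predictive(t: int, s: int, n: int, N: int, H: HypothesisSet) -> float:
    """Optimal (minimax-regret) predictive pmf f_dagger(t|s; H)."""
    lo, hi = support(s, n, N)
    if not lo <= t <= hi:
        raise ValueError(f"t={t} outside support [{lo}, {hi}]")
    return float(np.exp(_sup_log_pmf(t, s, n, N, H))
                 / nml_constant(s, n, N, H))


@dataclass
class NMLResult:
    """NML summary for one observed table: normalizer, predictive mass, ratio."""

    K: float
    f_nml: float
    bf: float
    theta_hat_per_outcome: np.ndarray


def regret(fbar_at_t: float, t: int, s: int, n: int, N: int,
           H: HypothesisSet) -> float:
    """Regret in nats of a predictive mass fbar(t|s) against hindsight.

    log[f_{theta_hat(t)}(t|s) / fbar(t|s)]; the NML predictive achieves
    regret log K_dagger uniformly over the support.
    """
    if fbar_at_t < 0.0:
        raise ValueError("predictive mass must be non-negative")
    if fbar_at_t == 0.0:
        return np.inf
    return _sup_log_pmf(t, s, n, N, H) - float(np.log(fbar_at_t))


def nml_ratio(t: int, s: int, n: int, N: int,
              full_result: bool = False) -> float | NMLResult:
    """NML ratio BF_dagger approximating the Bayes factor of enrichment."""
    lo, hi = support(s, n, N)
    if not lo <= t <= hi:
        raise ValueError(f"t={t} outside support [{lo}, {hi}]")
    K_alt = nml_constant(s, n, N, HypothesisSet.ALTERNATIVE)
    f_alt = float(np.exp(_sup_log_pmf(t, s, n, N, HypothesisSet.ALTERNATIVE))) / K_alt
    f_null = float(np.exp(conditional_log_pmf(t, s, n, N, 0.0)))  # K_null = 1
    bf = f_alt / f_null
    if not full_result:
        return bf
    theta_hats = np.array([
        constrained_mle_theta(y, s, n, N, HypothesisSet.ALTERNATIVE)
        for y in range(lo, hi + 1)
    ])
    return NMLResult(K=K_alt, f_nml=f_alt, bf=bf,
                     theta_hat_per_outcome=theta_hats)


def nmle_lfdr(bf: float, pi0: float) -> float:
    """NMLE local-FDR estimate [1 + (1-Pi0)/Pi0 * BF_dagger]^{-1}.

    Strictly increasing in ``pi0``, strictly decreasing in ``bf``; the
    closures pi0 = 0 and pi0 = 1 return 0 and 1.
    """
    if bf < 0.0:
        raise ValueError("Bayes factor must be non-negative")
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    if pi0 == 0.0:
        return 0.0
    if pi0 == 1.0:
        return 1.0
    return 1.0 / (1.0 + (1.0 - pi0) / pi0 * bf)
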