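"""Conditional likelihood for 2x2 enrichment tables.

A category-enrichment table cross-classifies genes by membership in a
category (e.g. a GO term) and by selection status (differentially expressed
vs. equivalently expressed).  Writing ``x1`` for selected genes in the
category, ``x2`` for unselected genes in the category, ``n`` for the total
number of selected genes and ``N`` for the reference-set size, the joint
binomial model has a nuisance parameter (the baseline log-odds of category
membership) which is eliminated by conditioning on the category size
``s = x1 + x2``.  The conditional law of ``t = x1`` given ``s`` is Fisher's
noncentral hypergeometric distribution with natural-log odds ratio ``theta``:

    f_theta(t | s) = C(n, t) C(N-n, s-t) e^{t theta} / sum_j C(n, j) C(N-n, s-j) e^{j theta}

with the sum over the support ``max(0, s+n-N) <= j <= min(s, n)``.  At
``theta = 0`` this is the central hypergeometric pmf underlying Fisher's
exact test.  All evaluation is in log-space (log-gamma binomial
coefficients, log-sum-exp normalizer) so reference sets of 10,000+ genes
are handled without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyTable",
    "EnrichmentDataset",
    "OddsRatioSpec",
    "conditional_pmf",
    "conditional_log_pmf",
    "symmetrized_pmf",
    "fisher_exact_two_sided",
    "pi2_from_pi1_phi",
    "support",
    "read_counts_tsv",
]

LN2 = float(np.log(2.0))

#: relative tie tolerance for the two-sided exact test ("at most as
#: probable" includes outcomes up to a factor 1+1e-7 above the observed
#: mass, so floating-point ties are counted deterministically).
FISHER_TIE_RTOL = 1e-7


def _validate_totals(n: int, N: int) -> None:
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if N < 1:
        raise ValueError("reference set must contain at least one gene")


def support(s: int, n: int, N: int) -> tuple[int, int]:
    """Inclusive support bounds of T given S=s: [max(0, s+n-N), min(s, n)]."""
    _validate_totals(n, N)
    if not 0 <= s <= N:
        raise ValueError(f"category size s={s} outside [0, N={N}]")
    return max(0, s + n - N), min(s, n)


@dataclass(frozen=True)
class ContingencyTable:
    """One category's 2x2 enrichment counts.

    Parameters
    ----------
    x1 : selected (DE) genes in the category.
    x2 : unselected (EE) genes in the category.
    n : total selected genes in the study.
    N : total reference genes.
    """

    x1: int
    x2: int
    n: int
    N: int

    def __post_init__(self) -> None:
        _validate_totals(self.n, self.N)
        if not 0 <= self.x1 <= self.n:
            raise ValueError(f"x1={self.x1} outside [0, n={self.n}]")
        if not 0 <= self.x2 <= self.N - self.n:
            raise ValueError(f"x2={self.x2} outside [0, N-n={self.N - self.n}]")

    @property
    def t(self) -> int:
        """Number of selected genes in the category (the test statistic)."""
        return self.x1

    @property
    def s(self) -> int:
        """Category size (the conditioning statistic)."""
        return self.x1 + self.x2


@dataclass
class EnrichmentDataset:
    """Per-category counts (t_i, s_i) sharing study totals n and N."""

    t: np.ndarray
    s: np.ndarray
    n: int
    N: int
    category_ids: list[str] | None = None
    _prep: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.s = np.asarray(self.s, dtype=np.int64)
        if self.t.shape != self.s.shape or self.t.ndim != 1:
            raise ValueError("t and s must be 1-d arrays of equal length")
        if self.m < 1:
            raise ValueError("dataset needs at least one category")
        for ti, si in zip(self.t, self.s):
            ContingencyTable(int(ti), int(si - ti), self.n, self.N)
        if self.category_ids is None:
            self.category_ids = [f"cat{i + 1}" for i in range(self.m)]
        elif len(self.category_ids) != self.m:
            raise ValueError("category_ids length mismatch")

    @property
    def m(self) -> int:
        return int(self.t.shape[0])

    def tables(self) -> list[ContingencyTable]:
        return [
            ContingencyTable(int(t), int(s - t), self.n, self.N)
            for t, s in zip(self.t, self.s)
        ]

    def prepared(self) -> "PreparedSupport":
        """Cached padded-support representation for vectorized pmf sums."""
        if "prep" not in self._prep:
            self._prep["prep"] = PreparedSupport.from_dataset(self)
        return self._prep["prep"]


@dataclass(frozen=True)
class OddsRatioSpec:
    """Log-odds-ratio parametrization linking the two binomial arms.

    ``phi`` is the log2 odds ratio, ``theta = phi * ln 2`` the natural-log
    one; ``pi1``/``pi2`` are the binomial success probabilities of the
    selected and unselected arms.
    """

    phi: float
    theta: float
    pi1: float
    pi2: float

    def __post_init__(self) -> None:
        if not np.isclose(self.theta, self.phi * LN2, rtol=0, atol=1e-9):
            raise ValueError("theta must equal phi * ln(2)")
        for name, p in (("pi1", self.pi1), ("pi2", self.pi2)):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name}={p} must lie strictly in (0, 1)")

    @classmethod
    def from_pi1_phi(cls, pi1: float, phi: float) -> "OddsRatioSpec":
        return cls(phi=phi, theta=phi * LN2, pi1=pi1, pi2=pi2_from_pi1_phi(pi1, phi))


def _log_weights(s: int, n: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Support values j and log[C(n,j) C(N-n, s-j)] over the support."""
    lo, hi = support(s, n, N)
    j = np.arange(lo, hi + 1)
    logw = (
        gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        + gammaln(N - n + 1) - gammaln(s - j + 1) - gammaln(N - n - s + j + 1)
    )
    return j, logw


def conditional_log_pmf(t, s: int, n: int, N: int, theta: float) -> np.ndarray:
    """log f_theta(t|s); -inf outside the support. Vectorized in ``t``."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    j, logw = _log_weights(s, n, N)
    logz = logsumexp(logw + j * theta)
    t_arr = np.asarray(t)
    out = np.full(t_arr.shape, -np.inf, dtype=float)
    lo, hi = int(j[0]), int(j[-1])
    ok = (t_arr >= lo) & (t_arr <= hi)
    idx = np.clip(t_arr - lo, 0, hi - lo)
    out = np.where(ok, logw[idx] + t_arr * theta - logz, out)
    return out[()] if out.ndim == 0 else out


def conditional_pmf(t, s: int, n: int, N: int, theta: float):
    """Fisher noncentral hypergeometric pmf f_theta(t|s).

    Returns 0 for ``t`` outside the support (not an error); raises for
    invalid table dimensions.
    """
    return np.exp(conditional_log_pmf(t, s, n, N, theta))


def symmetrized_pmf(t, s: int, n: int, N: int, theta: float):
    """Sign-symmetrized pmf g_theta(t|s) = [f_theta(t|s) + f_{-theta}(t|s)] / 2.

    The mixture components of the parametric mixture model use this family
    so a single non-negative magnitude covers enrichment in both directions;
    g_0 = f_0.
    """
    if theta == 0.0:
        return conditional_pmf(t, s, n, N, 0.0)
    return 0.5 * (
        conditional_pmf(t, s, n, N, theta) + conditional_pmf(t, s, n, N, -theta)
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for one enrichment table.

    Sums the central hypergeometric mass of every outcome at most as
    probable as the observed one (relative tie tolerance 1+1e-7, fixed so
    results are bit-reproducible).
    """
    j, logw = _log_weights(table.s, table.n, table.N)
    logz = logsumexp(logw)
    logp = logw - logz
    obs = logp[table.t - int(j[0])]
    keep = logp <= obs + np.log1p(FISHER_TIE_RTOL)
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


def fisher_pvalues(dataset: EnrichmentDataset) -> np.ndarray:
    """Two-sided Fisher exact p-value for every category in a dataset."""
    return np.array([fisher_exact_two_sided(tb) for tb in dataset.tables()])


def pi2_from_pi1_phi(pi1: float, phi: float) -> float:
    """Solve phi = log2[pi1/(1-pi1)] - log2[pi2/(1-pi2)] for pi2.

    Gives pi2 = pi1 / (pi1 + (1-pi1) * 2**phi), the unselected-arm success
    probability consistent with a selected-arm probability ``pi1`` and a
    log2 odds ratio ``phi``.
    """
    if not 0.0 < pi1 < 1.0:
        raise ValueError(f"pi1={pi1} must lie strictly in (0, 1)")
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    return pi1 / (pi1 + (1.0 - pi1) * 2.0 ** phi)


class PreparedSupport:
    """Padded per-category support matrices for fast mixture likelihoods.

    Rows are categories; columns index the support of T_i given S_i, padded
    to the longest support with -inf log-weights so a whole dataset's pmf
    values at one theta reduce to a single log-sum-exp over axis 1.
    """

    def __init__(self, J: np.ndarray, logW: np.ndarray, t: np.ndarray,
                 t_col: np.ndarray) -> None:
        self.J = J
        self.logW = logW
        self.t = t
        self.t_col = t_col
        self._cache: dict[float, np.ndarray] = {}

    @classmethod
    def from_dataset(cls, dataset: EnrichmentDataset) -> "PreparedSupport":
        rows = [_log_weights(int(s), dataset.n, dataset.N) for s in dataset.s]
        lmax = max(len(j) for j, _ in rows)
        m = dataset.m
        J = np.zeros((m, lmax))
        logW = np.full((m, lmax), -np.inf)
        t_col = np.empty(m, dtype=np.int64)
        for i, (j, w) in enumerate(rows):
            L = len(j)
            J[i, :L] = j
            logW[i, :L] = w
            t_col[i] = int(dataset.t[i]) - int(j[0])
        return cls(J, logW, np.asarray(dataset.t), t_col)

    def log_pmf_obs(self, theta: float) -> np.ndarray:
        """log f_theta(t_i|s_i) for every category, one vectorized pass.

        Results are memoized per theta (grid scans and optimizer restarts
        revisit the same values); the returned array must not be mutated.
        """
        theta = float(theta)
        hit = self._cache.get(theta)
        if hit is not None:
            return hit
        a = self.logW + self.J * theta
        logz = logsumexp(a, axis=1)
        rows = np.arange(a.shape[0])
        out = a[rows, self.t_col] - logz
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[theta] = out
        return out

    def log_sym_pmf_obs(self, theta: float) -> np.ndarray:
        """log g_theta(t_i|s_i) with the sign-symmetrized family."""
        if theta == 0.0:
            return self.log_pmf_obs(0.0)
        stacked = np.stack([self.log_pmf_obs(theta), self.log_pmf_obs(-theta)])
        return logsumexp(stacked, axis=0) - np.log(2.0)


def read_counts_tsv(path: str | Path, n: int | None = None,
                    N: int | None = None) -> EnrichmentDataset:
    """Read per-category counts from TSV.

    Expects columns ``category_id``, ``t``, ``s``; the study totals may be
    supplied as arguments or as ``# n=...`` / ``# N=...`` comment lines in
    the header. Rows are validated against the table invariants.
    """
    path = Path(path)
    meta: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key in ("n", "N"):
                    meta[key] = int(val.strip())
    n = meta.get("n") if n is None else n
    N = meta.get("N") if N is None else N
    if n is None or N is None:
        raise ValueError(
            "study totals n and N must be given as arguments or as "
            "'# n=...' / '# N=...' header lines"
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"category_id", "t", "s"} - set(df.columns)
    if missing:
        raise ValueError(f"missing TSV columns: {sorted(missing)}")
    return EnrichmentDataset(
        t=df["t"].to_numpy(),
        s=df["s"].to_numpy(),
        n=int(n),
        N=int(N),
        category_ids=[str(c) for c in df["category_id"]],
    )
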