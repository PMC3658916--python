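import math

import numpy as np
import pytest

from enrichlfdr import EnrichmentDataset


def oracle_pmf(t: int, s: int, n: int, N: int, theta: float) -> float:
    """Brute-force noncentral hypergeometric pmf via exact binomial coefficients.

    Independent of the package's log-space path; safe for N up to ~100.
    """
    lo, hi = max(0, s + n - N), min(s, n)
    if not lo <= t <= hi:
        return 0.0
    den = sum(
        math.comb(n, j) * math.comb(N - n, s - j) * math.exp(j * theta)
        for j in range(lo, hi + 1)
    )
    num = math.comb(n, t) * math.comb(N - n, s - t) * math.exp(t * theta)
    return num / den


def oracle_hypergeom(t: int, s: int, n: int, N: int) -> float:
    """Central hypergeometric mass from exact integer arithmetic."""
    if t < max(0, s + n - N) or t > min(s, n):
        return 0.0
    return math.comb(n, t) * math.comb(N - n, s - t) / math.comb(N, s)


def random_table(rng: np.random.Generator, n_max: int = 40):
    """A uniformly random valid (t, s, n, N) with N <= n_max."""
    N = int(rng.integers(2, n_max + 1))
    n = int(rng.integers(1, N))
    s = int(rng.integers(0, N + 1))
    lo, hi = max(0, s + n - N), min(s, n)
    t = int(rng.integers(lo, hi + 1))
    return t, s, n, N


def random_dataset(rng: np.random.Generator, m_max: int = 20,
                   n_max: int = 100) -> EnrichmentDataset:
    m = int(rng.integers(2, m_max + 1))
    N = int(rng.integers(10, n_max + 1))
    n = int(rng.integers(1, N))
    s = rng.integers(0, N + 1, size=m)
    t = np.array([
        int(rng.integers(max(0, si + n - N), min(si, n) + 1)) for si in s
    ])
    return EnrichmentDataset(t=t, s=s, n=n, N=N)


@pytest.fixture
def toy_dataset() -> EnrichmentDataset:
    """The two-category worked example: N=6, n=3, s=(2,2), t=(1,2)."""
    return EnrichmentDataset(t=[1, 2], s=[2, 2], n=3, N=6)
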