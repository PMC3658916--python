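"""Conditional pmf, symmetrization, Fisher test and odds-ratio algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enrichlfdr import (
    ContingencyTable,
    EnrichmentDataset,
    conditional_pmf,
    fisher_exact_two_sided,
    pi2_from_pi1_phi,
    read_counts_tsv,
    symmetrized_pmf,
)
from enrichlfdr.contingency import support

from conftest import oracle_hypergeom, oracle_pmf, random_table


class TestConditionalPmf:
    def test_collapses_to_hypergeometric_at_theta_zero(self):
        assert conditional_pmf(1, 2, 3, 6, 0.0) == pytest.approx(9 / 15, abs=1e-14)

    @pytest.mark.parametrize("theta", [0.0, 1.7, -2.3])
    def test_normalizes_over_support(self, theta):
        total = sum(conditional_pmf(t, 2, 3, 6, theta) for t in range(3))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_worked_value_theta_two(self):
        e2, e4 = math.e ** 2, math.e ** 4
        expected = 3 * e4 / (3 + 9 * e2 + 3 * e4)
        assert conditional_pmf(2, 2, 3, 6, 2.0) == pytest.approx(expected, abs=1e-14)
        assert expected == pytest.approx(0.7021, abs=5e-5)

    def test_outside_support_returns_zero(self):
        assert conditional_pmf(3, 2, 3, 6, 1.0) == 0.0
        assert conditional_pmf(-1, 2, 3, 6, 1.0) == 0.0

    def test_invalid_table_raises(self):
        with pytest.raises(ValueError):
            conditional_pmf(1, 7, 3, 6, 0.0)
        with pytest.raises(ValueError):
            conditional_pmf(1, 2, 7, 6, 0.0)
        with pytest.raises(ValueError):
            conditional_pmf(1, 2, 3, 6, np.inf)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            t, s, n, N = random_table(rng)
            theta = float(rng.normal(0, 2))
            assert conditional_pmf(t, s, n, N, theta) == pytest.approx(
                oracle_pmf(t, s, n, N, theta), abs=1e-12)

    def test_matches_scipy_noncentral_hypergeometric(self):
        # independent library cross-check of the same distribution
        rng = np.random.default_rng(5)
        for _ in range(100):
            t, s, n, N = random_table(rng)
            theta = float(rng.normal(0, 1.5))
            ref = stats.nchypergeom_fisher.pmf(t, N, n, s, np.exp(theta))
            assert conditional_pmf(t, s, n, N, theta) == pytest.approx(
                ref, rel=1e-9, abs=1e-12)

    def test_monotone_in_theta_at_upper_endpoint(self):
        # likelihood-ratio ordering: mass at t = min(s, n) grows with theta
        grid = np.linspace(-3, 3, 25)
        vals = [conditional_pmf(2, 2, 3, 6, th) for th in grid]
        assert np.all(np.diff(vals) > 0)

    def test_large_table_no_overflow(self):
        p = conditional_pmf(150, 5000, 200, 10_000, 1.5)
        assert 0.0 < p <= 1.0


class TestSymmetrizedPmf:
    def test_equals_plain_pmf_at_zero(self):
        assert symmetrized_pmf(1, 2, 3, 6, 0.0) == pytest.approx(0.6, abs=1e-14)

    def test_sign_symmetric(self):
        for t in range(3):
            assert symmetrized_pmf(t, 2, 3, 6, 2.0) == symmetrized_pmf(
                t, 2, 3, 6, -2.0)

    def test_worked_value(self):
        f_plus = oracle_pmf(2, 2, 3, 6, 2.0)
        f_minus = oracle_pmf(2, 2, 3, 6, -2.0)
        assert symmetrized_pmf(2, 2, 3, 6, 2.0) == pytest.approx(
            0.5 * (f_plus + f_minus), abs=1e-14)
        assert 0.5 * (f_plus + f_minus) == pytest.approx(0.3575, abs=5e-5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 400), st.floats(0.0, 6.0))
    def test_normalizes_for_any_category_size(self, s, theta):
        n, N = 30, 400
        lo, hi = support(s, n, N)
        total = sum(symmetrized_pmf(t, s, n, N, theta) for t in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestFisherExact:
    def test_worked_examples(self):
        assert fisher_exact_two_sided(
            ContingencyTable(2, 0, 3, 6)) == pytest.approx(0.4, abs=1e-12)
        assert fisher_exact_two_sided(
            ContingencyTable(1, 1, 3, 6)) == pytest.approx(1.0, abs=1e-12)

    def test_singleton_support_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 0, 3, 6)) == 1.0

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(150):
            t, s, n, N = random_table(rng)
            tab = ContingencyTable(t, s - t, n, N)
            ref = stats.fisher_exact(
                [[t, s - t], [n - t, N - n - s + t]], alternative="two-sided")[1]
            assert fisher_exact_two_sided(tab) == pytest.approx(ref, rel=1e-6)

    def test_endpoints_no_larger_than_mode(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            _, s, n, N = random_table(rng)
            lo, hi = support(s, n, N)
            probs = {t: oracle_hypergeom(t, s, n, N) for t in range(lo, hi + 1)}
            mode = max(probs, key=probs.get)
            p_mode = fisher_exact_two_sided(ContingencyTable(mode, s - mode, n, N))
            for edge in (lo, hi):
                p_edge = fisher_exact_two_sided(
                    ContingencyTable(edge, s - edge, n, N))
                assert p_edge <= p_mode + 1e-12


class TestOddsRatioAlgebra:
    def test_zero_odds_ratio_identity(self):
        assert pi2_from_pi1_phi(0.3, 0.0) == pytest.approx(0.3, abs=1e-15)

    def test_halved_odds(self):
        assert pi2_from_pi1_phi(0.5, 1.0) == pytest.approx(1 / 3, abs=1e-15)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(1e-6, 1 - 1e-6), st.floats(-8.0, 8.0))
    def test_round_trip_recovers_phi(self, pi1, phi):
        pi2 = pi2_from_pi1_phi(pi1, phi)
        back = math.log2(pi1 / (1 - pi1)) - math.log2(pi2 / (1 - pi2))
        assert back == pytest.approx(phi, abs=1e-9)

    def test_degenerate_pi1_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                pi2_from_pi1_phi(bad, 1.0)


class TestDatasetAndIO:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(4, 0, 3, 6)   # x1 > n
        with pytest.raises(ValueError):
            ContingencyTable(0, 4, 3, 6)   # x2 > N - n
        with pytest.raises(ValueError):
            EnrichmentDataset(t=[5], s=[2], n=3, N=6)

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "# n=3\n# N=6\ncategory_id\tt\ts\nGO:1\t1\t2\nGO:2\t2\t2\n")
        ds = read_counts_tsv(path)
        assert ds.m == 2 and ds.n == 3 and ds.N == 6
        assert list(ds.t) == [1, 2] and list(ds.s) == [2, 2]
        assert ds.category_ids == ["GO:1", "GO:2"]

    def test_tsv_missing_totals_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("category_id\tt\ts\nGO:1\t1\t2\n")
        with pytest.raises(ValueError, match="n and N"):
            read_counts_tsv(path)

    def test_tsv_invalid_row_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("# n=3\n# N=6\ncategory_id\tt\ts\nGO:1\t5\t2\n")
        with pytest.raises(ValueError):
            read_counts_tsv(path)
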