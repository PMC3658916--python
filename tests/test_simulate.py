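"""Generator configurations, determinism, truth oracle, bias harness."""

import math

import numpy as np
import pytest
from scipy import stats

from enrichlfdr import (
    SimulationConfig,
    TrueLFDRModel,
    bias_experiment,
    odds_ratio_config,
    simulate_dataset,
    summarize_bias,
    true_lfdr,
    true_lfdr_dataset,
)

from conftest import oracle_hypergeom, oracle_pmf


class TestOddsRatioConfig:
    def test_asymmetric_ramp_m100(self):
        phi = odds_ratio_config(100, 0.5, "asymmetric")
        assert phi[0] == pytest.approx(0.1)
        assert phi[49] == pytest.approx(5.0)
        assert np.all(phi[50:] == 0.0)

    def test_symmetric_ramp_is_sign_balanced(self):
        phi = odds_ratio_config(100, 0.5, "symmetric")
        pos, neg = phi[phi > 0], phi[phi < 0]
        assert pos.size == neg.size == 25
        assert np.allclose(np.sort(pos), np.sort(-neg))
        assert np.all(phi[50:] == 0.0)

    def test_catalogue_rows(self):
        assert list(odds_ratio_config(8, 0.75, "catalogue")) == [
            2.0, -2.0, 0, 0, 0, 0, 0, 0]
        assert list(odds_ratio_config(2, 1.0, "catalogue")) == [0.0, 0.0]
        assert list(odds_ratio_config(4, 0.5, "catalogue")) == [3.0, -3.0, 0, 0]

    def test_catalogue_m32_half(self):
        phi = odds_ratio_config(32, 0.5, "catalogue")
        assert phi[0] == pytest.approx(0.32)
        assert phi[7] == pytest.approx(4.8)
        assert phi[8] == pytest.approx(-0.32)
        assert np.all(phi[16:] == 0.0)

    def test_unknown_configuration_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_config(5, 0.5, "catalogue")
        with pytest.raises(ValueError):
            odds_ratio_config(100, 0.5, "zigzag")
        with pytest.raises(ValueError):
            odds_ratio_config(100, 0.999, "asymmetric")


class TestGenerator:
    def test_deterministic_given_seed_and_rep(self):
        cfg = SimulationConfig(m=20, pi0=0.5, seed=4)
        phi = cfg.phi()
        a = simulate_dataset(cfg, phi, rep_index=3)
        b = simulate_dataset(cfg, phi, rep_index=3)
        c = simulate_dataset(cfg, phi, rep_index=4)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.s, b.s)
        assert not np.array_equal(a.t, c.t)

    def test_category_substreams_stable_under_m(self):
        # growing m must not reshuffle earlier categories' draws
        small = simulate_dataset(SimulationConfig(m=5, pi0=1.0, seed=8),
                                 np.zeros(5), 0)
        big = simulate_dataset(SimulationConfig(m=10, pi0=1.0, seed=8),
                               np.zeros(10), 0)
        assert np.array_equal(small.t, big.t[:5])
        assert np.array_equal(small.s, big.s[:5])

    def test_mean_selected_fraction_near_half(self):
        # pi1 ~ Uniform(0,1) so x1/n averages to about 1/2
        cfg = SimulationConfig(m=400, pi0=1.0, n=200, N=10_000, seed=12)
        ds = simulate_dataset(cfg, np.zeros(400), 0)
        assert ds.t.mean() / cfg.n == pytest.approx(0.5, abs=0.05)

    def test_null_conditional_distribution_is_hypergeometric(self):
        # pooled chi-square goodness of fit of t | s against the
        # central hypergeometric across many null draws
        cfg = SimulationConfig(m=100, pi0=1.0, n=10, N=60, seed=30)
        obs, exp = [], []
        for rep in range(20):
            ds = simulate_dataset(cfg, np.zeros(100), rep)
            for t, s in zip(ds.t, ds.s):
                obs.append(int(t))
                exp.append([oracle_hypergeom(y, int(s), 10, 60)
                            for y in range(11)])
        counts = np.bincount(obs, minlength=11)
        expected = np.sum(exp, axis=0)
        keep = expected > 5
        chi2 = float(np.sum(
            (counts[keep] - expected[keep]) ** 2 / expected[keep]))
        p = 1 - stats.chi2.cdf(chi2, df=int(keep.sum()) - 1)
        assert p > 0.01


class TestTruthOracle:
    def test_all_null_prior_forces_one(self):
        model = TrueLFDRModel(theta_list=[], pi0=1.0)
        assert true_lfdr(2, 2, model, 3, 6) == 1.0

    def test_toy_worked_value(self):
        model = TrueLFDRModel(theta_list=[math.log(2)], pi0=0.5)
        f0 = oracle_hypergeom(2, 2, 3, 6)
        f1 = oracle_pmf(2, 2, 3, 6, math.log(2))
        expected = 1.0 / (1.0 + (f1 / f0))
        assert true_lfdr(2, 2, model, 3, 6) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3548, abs=1e-4)

    def test_vanishing_theta_limit_approaches_pi0(self):
        model = TrueLFDRModel(theta_list=[1e-9], pi0=0.7)
        assert true_lfdr(2, 2, model, 3, 6) == pytest.approx(0.7, abs=1e-6)

    def test_monotone_in_pi0(self):
        vals = [true_lfdr(2, 2, TrueLFDRModel(theta_list=[1.0], pi0=p), 3, 6)
                for p in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(vals) > 0)

    def test_vectorized_oracle_matches_scalar(self):
        cfg = SimulationConfig(m=30, pi0=0.5, seed=2, n=20, N=300)
        phi = cfg.phi()
        ds = simulate_dataset(cfg, phi, 0)
        model = TrueLFDRModel.from_phi(phi)
        vec = true_lfdr_dataset(ds, model)
        for i in range(ds.m):
            assert vec[i] == pytest.approx(
                true_lfdr(int(ds.t[i]), int(ds.s[i]), model, 20, 300),
                abs=1e-10)
        assert np.all((vec >= 0) & (vec <= 1))

    def test_pi0_below_one_needs_enriched_component(self):
        with pytest.raises(ValueError):
            TrueLFDRModel(theta_list=[], pi0=0.5)


class TestBiasHarness:
    def test_truth_oracle_estimator_has_zero_bias(self, monkeypatch):
        import enrichlfdr.pipeline as pl
        cfg = SimulationConfig(m=10, pi0=0.5, scheme="asymmetric",
                               n=20, N=300, seed=6)
        model = TrueLFDRModel.from_phi(cfg.phi())

        def cheat(dataset, method, **kw):
            return true_lfdr_dataset(dataset, model)

        monkeypatch.setattr(pl, "estimate_lfdr", cheat)
        tab = bias_experiment(cfg, ["bbe"], reps=3)
        assert tab["abs_bias"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_one_estimator_unbiased_when_all_null(self, monkeypatch):
        import enrichlfdr.pipeline as pl
        monkeypatch.setattr(pl, "estimate_lfdr",
                            lambda ds, method, **kw: np.ones(ds.m))
        cfg = SimulationConfig(m=8, pi0=1.0, scheme="catalogue", n=20,
                               N=300, seed=6)
        tab = bias_experiment(cfg, ["bbe"], reps=3)
        assert tab["abs_bias"].iloc[0] == 0.0

    def test_mae_aggregation_bounds_signed_bias(self):
        cfg = SimulationConfig(m=8, pi0=0.75, scheme="catalogue", n=20,
                               N=300, seed=1)
        signed = bias_experiment(cfg, ["bbe"], reps=3, aggregate="bias")
        mae = bias_experiment(cfg, ["bbe"], reps=3, aggregate="mae")
        assert mae["abs_bias"].iloc[0] >= signed["abs_bias"].iloc[0] - 1e-12

    def test_summary_tables(self):
        import pandas as pd
        rows = pd.DataFrame({
            "estimator": ["a", "b", "a", "b"],
            "m": [8, 8, 8, 8],
            "pi0": [0.5, 0.5, 1.0, 1.0],
            "abs_bias": [0.1, 0.2, 0.4, 0.3],
        })
        winners, maxima = summarize_bias(rows)
        assert set(winners["winner"]) == {"a", "b"}
        assert maxima.loc[maxima["estimator"] == "a",
                          "max_abs_bias"].iloc[0] == 0.4
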