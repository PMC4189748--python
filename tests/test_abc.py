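"""Rejection sampling, regression adjustment and posterior summarisation."""

import math

import numpy as np
import pandas as pd
import pytest

from imabc import (PriorSpec, SimTable, abc_reject, posterior_summary,
                   regression_adjust, run_simulations, sample_prior)


class TestPriorSampling:
    def test_uniform_moments(self):
        draws = sample_prior(PriorSpec({"s": (0.0, 1.0)}), 100_000, seed=1)
        assert draws["s"].mean() == pytest.approx(0.5, abs=0.005)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec({"theta_A": (2.0, 2.0)})

    def test_same_seed_identical(self):
        ps = PriorSpec.default_im()
        a = sample_prior(ps, 50, seed=9)
        b = sample_prior(ps, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_log_scale_prior(self):
        ps = PriorSpec({"rho_per_locus": (1e-8, 1e-2, "log")})
        draws = sample_prior(ps, 20_000, seed=2)["rho_per_locus"]
        assert draws.min() >= 1e-8 and draws.max() <= 1e-2
        # log-uniform: median is the geometric midpoint 1e-5
        assert np.median(np.log10(draws)) == pytest.approx(-5.0, abs=0.1)


class TestRunSimulations:
    def test_shape_and_determinism(self, small_design):
        ps = PriorSpec.default_im()
        draws = sample_prior(ps, 30, seed=4)
        t1 = run_simulations(draws, small_design, seed=5)
        t2 = run_simulations(draws, small_design, seed=5)
        assert len(t1) == 30
        pd.testing.assert_frame_equal(t1.stats, t2.stats)

    def test_tiny_theta_rows_have_few_sites(self, small_design):
        ps = PriorSpec({"theta_A": (1e-6, 1e-5), "theta1": (1e-6, 1e-5),
                        "theta2": (1e-6, 1e-5), "T": (0.0, 1e-6),
                        "M1": (0.0, 1e-6), "M2": (0.0, 1e-6), "s": (0.4, 0.6)})
        draws = sample_prior(ps, 20, seed=6)
        table = run_simulations(draws, small_design, seed=7)
        assert table.stats["mean_S_pooled"].max() <= 0.5

    def test_tsv_round_trip(self, small_design, tmp_path):
        draws = sample_prior(PriorSpec.default_im(), 10, seed=8)
        table = run_simulations(draws, small_design, seed=9)
        p = tmp_path / "table.tsv"
        table.to_tsv(p)
        back = SimTable.from_tsv(p)
        assert np.allclose(back.stats.fillna(-1), table.stats.fillna(-1))


def toy_table(n=1000, seed=0, n_stats=2):
    rng = np.random.default_rng(seed)
    stats = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(n_stats)})
    params = pd.DataFrame({"p": rng.uniform(1, 3, size=n)})
    return SimTable(params, stats)


class TestRejection:
    def test_exact_match_always_retained(self):
        table = toy_table()
        obs = {f"x{i}": table.stats[f"x{i}"].iloc[137] for i in range(2)}
        post = abc_reject(obs, table, retention=0.01)
        assert 137 in post.retained_index
        assert post.distances.min() == 0.0

    def test_bottom_one_percent_equals_sort_oracle(self):
        table = toy_table(n=1000, seed=3)
        obs = {"x0": 0.1, "x1": -0.4}
        post = abc_reject(obs, table, retention=0.01)
        assert len(post.params) == 10
        # independent oracle: full sort of independently standardized distances
        from scipy.stats import median_abs_deviation
        d = np.zeros(1000)
        for name, o in obs.items():
            col = table.stats[name].to_numpy()
            sc = median_abs_deviation(col, scale="normal")
            d += ((col - o) / sc) ** 2
        oracle = np.argsort(np.sqrt(d), kind="stable")[:10]
        assert sorted(post.retained_index) == sorted(oracle)

    def test_all_identical_rows_tie_break_by_row_order(self):
        rng = np.random.default_rng(1)
        stats = pd.DataFrame({"x0": np.zeros(200), "x1": rng.normal(size=200)})
        stats["x1"] = 0.0
        # constant stats are uninformative -> rejected; add one varying stat
        stats["x2"] = np.concatenate([np.zeros(100), rng.normal(size=100)])
        params = pd.DataFrame({"p": np.arange(200.0)})
        obs = {"x2": 0.0}
        post = abc_reject(obs, SimTable(params, stats), retention=0.01)
        assert post.retained_index.tolist() == [0, 1]

    def test_statistic_mismatch_reported(self):
        table = toy_table()
        with pytest.raises(ValueError, match="missing"):
            abc_reject({"nope": 1.0}, table, stats=["nope"])

    def test_undefined_rows_never_retained(self):
        table = toy_table(n=300, seed=5)
        table.stats.loc[:49, "x0"] = np.nan
        post = abc_reject({"x0": 0.0, "x1": 0.0}, table, retention=0.05)
        assert not set(post.retained_index) & set(range(50))


class TestRegressionAdjust:
    def test_identity_when_retained_stats_equal_obs(self):
        rng = np.random.default_rng(2)
        n = 60
        stats = pd.DataFrame({"x0": np.zeros(n), "x1": np.zeros(n)})
        stats.iloc[40:] = rng.normal(size=(20, 2))  # spread so MAD > 0
        params = pd.DataFrame({"p": rng.uniform(0, 1, n)})
        post = abc_reject({"x0": 0.0, "x1": 0.0}, SimTable(params, stats),
                          retention=0.5)
        adj = regression_adjust(post)
        kept = post.retained_index[post.distances == 0]
        mask = post.distances == 0
        assert np.allclose(adj.adjusted["p"].to_numpy()[mask],
                           post.params["p"].to_numpy()[mask], atol=1e-10)

    def test_matches_weighted_least_squares_oracle(self):
        # constructed linear relation: p = 2 + 3 * x0 + noise
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.normal(size=n)
        p = 2.0 + 3.0 * x + rng.normal(scale=0.1, size=n)
        table = SimTable(pd.DataFrame({"p": p}), pd.DataFrame({"x0": x}))
        post = abc_reject({"x0": 0.25}, table, retention=0.05)
        adj = regression_adjust(post)

        import statsmodels.api as sm
        d = post.distances
        w = 1 - (d / d.max()) ** 2
        X = post.retained_stats_std - post.obs_std
        fit = sm.WLS(post.params["p"].to_numpy(), sm.add_constant(X),
                     weights=w).fit()
        oracle = post.params["p"].to_numpy() - X[:, 0] * fit.params[1]
        assert np.allclose(adj.adjusted["p"].to_numpy(), oracle, atol=1e-8)

    def test_epanechnikov_weight_vanishes_at_bandwidth(self):
        table = toy_table(n=500, seed=11)
        post = abc_reject({"x0": 0.0, "x1": 0.0}, table, retention=0.02)
        adj = regression_adjust(post)
        assert adj.weights[np.argmax(adj.distances)] == pytest.approx(0.0)
        assert np.all(adj.weights >= 0)

    def test_adjusted_draws_respect_prior_support(self, small_design):
        priors = PriorSpec.default_im()
        draws = sample_prior(priors, 600, seed=13)
        table = run_simulations(draws, small_design, seed=14)
        obs = table.stats.iloc[7].to_dict()
        post = regression_adjust(
            abc_reject(obs, table, retention=0.05, priors=priors))
        for name in priors.names:
            lo, hi = priors.range(name)
            v = post.adjusted[name].to_numpy()
            assert np.all(v >= lo) and np.all(v <= hi)

    def test_too_few_retained_rejected(self):
        table = toy_table(n=100, seed=15)
        post = abc_reject({"x0": 0.0, "x1": 0.0}, table, retention=0.03)
        with pytest.raises(ValueError, match="retained"):
            regression_adjust(post)


class TestPosteriorSummary:
    def test_point_mass(self):
        s = posterior_summary(None, "p", draws=np.full(100, 7.0))
        assert (s.mode, s.hpd_low, s.hpd_high) == (7.0, 7.0, 7.0)

    def test_standard_normal_quantiles(self):
        x = np.random.default_rng(0).normal(size=100_000)
        s = posterior_summary(None, "p", draws=x)
        assert s.mode == pytest.approx(0.0, abs=0.05)
        assert s.hpd_low == pytest.approx(-1.645, abs=0.05)
        assert s.hpd_high == pytest.approx(1.645, abs=0.05)
        assert not s.boundary_flag

    def test_uniform_support_flat_density(self):
        x = np.random.default_rng(1).uniform(size=5000)
        s = posterior_summary(None, "p", draws=x, support=(0.0, 1.0))
        # any 90% region of a flat density is an HPD set; the enclosing
        # interval must span at least that mass and flag the boundaries
        assert 0.85 <= s.hpd_high - s.hpd_low <= 1.0
        assert s.boundary_flag

    def test_hpd_contains_mode(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-2, 0.3, 400), rng.normal(2, 0.3, 300)])
        s = posterior_summary(None, "p", draws=x)
        assert s.hpd_low <= s.mode <= s.hpd_high
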