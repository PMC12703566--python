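"""Distribution fitting, Monte-Carlo propagation and acceptability curves."""

import numpy as np
import pandas as pd
import pytest

from asthmace import (
    ceac,
    fit_beta_probability,
    fit_gamma_disutility,
    fit_lognormal_count,
    run_base_case,
    run_psa,
)


class TestGammaDisutility:
    def test_moment_identities(self):
        spec = fit_gamma_disutility(0.96, sd=0.2)
        shape, rate, _ = spec.params
        assert shape == pytest.approx((0.04 / 0.2) ** 2, abs=1e-12)  # 0.04
        assert rate == pytest.approx(0.04 / 0.2**2, abs=1e-12)  # 1.0
        # analytic moments of the fitted gamma round-trip the inputs
        assert shape / rate == pytest.approx(0.04, abs=1e-9)
        assert np.sqrt(shape) / rate == pytest.approx(0.2, abs=1e-9)

    def test_sampled_mean_matches(self, rng):
        spec = fit_gamma_disutility(0.96, sd=0.2, floor=-np.inf)
        draws = spec.sample(rng, 200_000)
        se = 0.2 / np.sqrt(draws.size)
        assert abs((1.0 - draws.mean()) - 0.04) < 3 * se

    def test_zero_sd_is_point_mass(self, rng):
        spec = fit_gamma_disutility(0.9, sd=0.0)
        assert spec.kind == "point"
        assert spec.sample(rng) == 0.9

    def test_floor_truncation(self, rng):
        spec = fit_gamma_disutility(0.5, sd=3.0, floor=0.0)
        draws = spec.sample(rng, 10_000)
        assert (draws >= 0.0).all()


class TestLognormalCount:
    def test_sigma_from_published_gp_visits(self):
        # 0.75 visits/year with SD 1.65
        spec = fit_lognormal_count(0.75, 1.65)
        mu, sigma = spec.params
        assert sigma**2 == pytest.approx(np.log(1 + (1.65 / 0.75) ** 2), abs=1e-12)
        assert mu == pytest.approx(np.log(0.75) - sigma**2 / 2, abs=1e-12)
        # analytic lognormal moments round-trip
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(0.75, abs=1e-9)
        var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert np.sqrt(var) == pytest.approx(1.65, abs=1e-9)

    def test_degenerate_cases(self, rng):
        assert fit_lognormal_count(0.75, 0.0).sample(rng) == 0.75
        assert fit_lognormal_count(0.0, 0.5).sample(rng) == 0.0

    def test_sampled_mean_matches(self, rng):
        spec = fit_lognormal_count(0.75, 1.65)
        draws = spec.sample(rng, 400_000)
        se = 1.65 / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.75) < 3 * se


class TestBetaProbability:
    def test_uniform_from_matching_moments(self):
        spec = fit_beta_probability(0.5, sd=np.sqrt(1.0 / 12.0))
        a, b = spec.params
        assert a == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(1.0, abs=1e-9)

    def test_moment_identities(self):
        spec = fit_beta_probability(0.2, sd=0.05)
        a, b = spec.params
        assert a == pytest.approx(12.6, abs=1e-9)
        assert b == pytest.approx(50.4, abs=1e-9)
        # analytic mean / sd round-trip
        assert a / (a + b) == pytest.approx(0.2, abs=1e-9)
        sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert sd == pytest.approx(0.05, abs=1e-9)

    def test_infeasible_sd_reports_bound(self):
        with pytest.raises(ValueError, match="mean\\(1-mean\\)"):
            fit_beta_probability(0.2, sd=0.5)

    def test_interval_fit_reproduces_quantiles(self):
        from scipy import stats

        target = stats.beta(8.0, 24.0)
        lo, hi = target.ppf([0.025, 0.975])
        spec = fit_beta_probability(0.25, interval=(lo, hi))
        a, b = spec.params
        q = stats.beta.ppf([0.025, 0.975], a, b)
        assert q[0] == pytest.approx(lo, abs=1e-3)
        assert q[1] == pytest.approx(hi, abs=1e-3)


def _point_mass_config(example_config):
    cfg = example_config.copy()
    cfg.psa.utility_gamma_sd = 0.0
    cfg.transition_matrix.sds[:] = 0.0
    for state, items in cfg.resource_use.items():
        for item in items:
            item.sd = 0.0
    return cfg


class TestRunPsa:
    def test_point_mass_psa_equals_deterministic_exactly(self, example_config):
        cfg = _point_mass_config(example_config)
        det = run_base_case(cfg)
        res = run_psa(cfg, n=1, seed=11)
        for s in det.strategies:
            row = res.samples[res.samples.strategy == s.name].iloc[0]
            assert row.cost == s.outcomes.total_cost
            assert row.qaly == s.outcomes.total_qaly

    def test_same_seed_bitwise_identical(self, example_config):
        a = run_psa(example_config, n=30, seed=42)
        b = run_psa(example_config, n=30, seed=42)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_different_seed_differs(self, example_config):
        a = run_psa(example_config, n=10, seed=1)
        b = run_psa(example_config, n=10, seed=2)
        assert not a.samples.cost.equals(b.samples.cost)

    def test_mean_near_deterministic_for_narrow_distributions(self, example_config):
        cfg = example_config.copy()
        cfg.psa.utility_gamma_sd = 0.002
        cfg.transition_matrix.sds *= 0.02
        for items in cfg.resource_use.values():
            for item in items:
                item.sd = item.mean * 0.02
        det = run_base_case(cfg)
        res = run_psa(cfg, n=400, seed=5)
        for s in det.strategies:
            sub = res.samples[res.samples.strategy == s.name]
            assert sub.cost.mean() == pytest.approx(s.outcomes.total_cost, rel=0.02)
            assert sub.qaly.mean() == pytest.approx(s.outcomes.total_qaly, rel=0.005)

    def test_summary_shape(self, example_config):
        res = run_psa(example_config, n=20, seed=9)
        assert set(res.summary.strategy) == set(example_config.strategy_names)
        assert (res.summary.cost_lo <= res.summary.mean_cost).all()
        assert (res.summary.cost_hi >= res.summary.mean_cost).all()


class TestCeac:
    def test_single_strategy_probability_one(self):
        samples = pd.DataFrame(
            {
                "replicate": [0, 1, 2],
                "strategy": ["only"] * 3,
                "cost": [10.0, 12.0, 9.0],
                "qaly": [0.9, 0.8, 0.95],
            }
        )
        curves = ceac(samples, [0, 20000])
        assert (curves["only"] == 1.0).all()

    def test_cheapest_wins_at_zero_wtp(self, example_config):
        res = run_psa(example_config, n=50, seed=21)
        curves = ceac(res, [0.0])
        cost = res.pivot("cost").to_numpy()
        strategies = list(res.pivot("cost").columns)
        wins = np.zeros(len(strategies))
        for row in cost:
            winners = row == row.min()
            wins += winners / winners.sum()
        np.testing.assert_allclose(
            curves.iloc[0, 1:].to_numpy(dtype=float), wins / cost.shape[0], atol=1e-12
        )

    def test_probabilities_sum_to_one_everywhere(self, example_config):
        res = run_psa(example_config, n=60, seed=33)
        curves = ceac(res, example_config.wtp_grid)
        sums = curves.drop(columns="wtp").sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        probs = curves.drop(columns="wtp").to_numpy()
        assert ((probs >= 0) & (probs <= 1)).all()
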