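import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transgen import bayes
from transgen.errors import ConfigError, DesignError

from conftest import two_group_frame


# ---------------------------------------------------------------------------
# hpd_interval
# ---------------------------------------------------------------------------


class TestHpdInterval:
    def test_uniform_grid_first_narrowest(self):
        samples = np.arange(1, 101, dtype=float)
        low, high = bayes.hpd_interval(samples, prob=0.95)
        assert (low, high) == (1.0, 95.0)

    def test_mass_concentration(self):
        low, high = bayes.hpd_interval([0, 0, 0, 0, 10], prob=0.8)
        assert (low, high) == (0.0, 0.0)

    def test_normal_closed_form(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        low, high = bayes.hpd_interval(x, prob=0.95)
        assert abs(low - (-1.96)) < 0.05
        assert abs(high - 1.96) < 0.05

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            bayes.hpd_interval([1.0, 2.0], prob=0.95)

    def test_bad_prob(self):
        with pytest.raises(ValueError):
            bayes.hpd_interval(np.arange(100.0), prob=1.0)

    def test_order_invariance(self, rng):
        x = rng.standard_normal(500)
        assert bayes.hpd_interval(x) == bayes.hpd_interval(rng.permutation(x))


# ---------------------------------------------------------------------------
# mc_se_batch_means
# ---------------------------------------------------------------------------


class TestMcSeBatchMeans:
    def test_iid_closed_form(self, rng):
        x = rng.standard_normal(5000)
        se = bayes.mc_se_batch_means(x)
        expected = 1.0 / math.sqrt(5000)
        assert expected / 1.5 < se < expected * 1.5

    @pytest.mark.parametrize("c", [-3.0, 0.5, 10.0])
    def test_homogeneity(self, rng, c):
        x = rng.standard_normal(2000)
        assert bayes.mc_se_batch_means(c * x) == pytest.approx(
            abs(c) * bayes.mc_se_batch_means(x)
        )

    def test_ar1_inflation(self):
        rng = np.random.default_rng(3)
        n, rho = 5000, 0.9
        e = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = e[0]
        for i in range(1, n):
            x[i] = rho * x[i - 1] + e[i] * math.sqrt(1 - rho**2)
        se = bayes.mc_se_batch_means(x)
        expected = math.sqrt((1 + rho) / (1 - rho)) / math.sqrt(n)
        assert expected / 2 < se < expected * 2
        # clearly above the naive iid value
        assert se > 2.0 / math.sqrt(n)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            bayes.mc_se_batch_means(np.arange(80.0))


# ---------------------------------------------------------------------------
# geweke_z
# ---------------------------------------------------------------------------


class TestGewekeZ:
    def test_constant_chain_flagged(self):
        assert math.isnan(bayes.geweke_z(np.full(1000, 3.14)))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_iid_bounded(self, seed):
        x = np.random.default_rng(seed).standard_normal(5000)
        assert abs(bayes.geweke_z(x)) < 3.0

    def test_forced_drift(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 2500), rng.normal(5, 1, 2500)])
        assert abs(bayes.geweke_z(x)) > 10.0

    def test_window_size_precondition(self):
        with pytest.raises(ValueError):
            bayes.geweke_z(np.arange(50.0))  # first 10% window would hold 5


# ---------------------------------------------------------------------------
# relevant_value / decide_relevance
# ---------------------------------------------------------------------------


class TestRelevanceRule:
    def test_sd_three(self):
        # values with sample SD exactly 3 -> R = 1
        x = np.array([-3.0, 0.0, 3.0])
        assert np.std(x, ddof=1) == pytest.approx(3.0)
        assert bayes.relevant_value(x) == pytest.approx(1.0)

    def test_two_point(self):
        assert bayes.relevant_value([0.0, 2.0]) == pytest.approx(math.sqrt(2) / 3)

    def test_sampling_distribution(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3700.0, 450.0, 60)
        r = bayes.relevant_value(x)
        tol = 3 * 450.0 / (3 * math.sqrt(2 * 59))
        assert abs(r - 150.0) < tol

    def test_constant_values_warn(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert bayes.relevant_value([2.0, 2.0, 2.0]) == 0.0
        assert any("R = 0" in rec.message for rec in caplog.records)

    def _summary(self, d_mean, p0):
        return bayes.PosteriorSummary(
            D_mean=d_mean, P0=p0, hpd_low=d_mean - 1, hpd_high=d_mean + 1,
            mcse=0.1, geweke_z=0.0, n_saved=5000,
        )

    def test_relevant_true(self):
        decision = bayes.decide_relevance(self._summary(-437.4, 0.99), R=150.0)
        assert decision.relevant
        assert decision.criterion_trace["abs_D"] == pytest.approx(437.4)

    def test_magnitude_fails(self):
        assert not bayes.decide_relevance(self._summary(100.0, 0.99), R=150.0).relevant

    def test_p0_boundary_strict(self):
        assert not bayes.decide_relevance(self._summary(500.0, 0.80), R=150.0).relevant

    def test_negative_R_rejected(self):
        with pytest.raises(ValueError):
            bayes.decide_relevance(self._summary(1.0, 0.9), R=-1.0)


# ---------------------------------------------------------------------------
# summarize_posterior
# ---------------------------------------------------------------------------


def _chain_from(samples):
    samples = np.asarray(samples, dtype=float)
    return bayes.PosteriorChain(
        samples_D=samples,
        samples_sigma2=np.ones_like(samples),
        samples_beta=None,
        config_used=bayes.GibbsConfig(n_iter=2000, burn_in=0, thin=1),
    )


class TestSummarizePosterior:
    def test_symmetric_p0_half(self):
        s = bayes.summarize_posterior(_chain_from(np.tile([-1.0, 1.0], 100)))
        assert s.P0 == pytest.approx(0.5)

    def test_all_positive_p0_one(self):
        s = bayes.summarize_posterior(_chain_from(np.linspace(0.1, 5, 200)))
        assert s.P0 == 1.0

    def test_normal_closed_form(self, rng):
        draws = rng.normal(2.0, 1.0, 5000)
        s = bayes.summarize_posterior(_chain_from(draws))
        assert abs(s.hpd_low - (2 - 1.96)) < 0.1
        assert abs(s.hpd_high - (2 + 1.96)) < 0.1
        assert abs(s.P0 - stats.norm.cdf(2.0)) < 0.01

    def test_zero_draws_excluded_from_numerator(self):
        s = bayes.summarize_posterior(_chain_from([0.0] * 50 + [1.0] * 50))
        assert s.P0 == pytest.approx(0.5)

    def test_constant_chain(self):
        s = bayes.summarize_posterior(_chain_from(np.full(200, 2.5)))
        assert s.mcse == 0.0
        assert math.isnan(s.geweke_z)
        assert s.hpd_low == s.hpd_high == 2.5


# ---------------------------------------------------------------------------
# GibbsConfig / fit_two_group_model
# ---------------------------------------------------------------------------


class TestGibbsConfig:
    def test_default_bookkeeping(self):
        assert bayes.GibbsConfig().n_saved == 5000

    def test_invalid_thin(self):
        with pytest.raises(ConfigError):
            bayes.GibbsConfig(thin=0)

    def test_burnin_must_precede(self):
        with pytest.raises(ConfigError):
            bayes.GibbsConfig(n_iter=100, burn_in=100, thin=1)

    def test_divisibility_enforced(self):
        with pytest.raises(ConfigError):
            bayes.GibbsConfig(n_iter=105, burn_in=10, thin=10)


def _quick_config(seed=0):
    return bayes.GibbsConfig(n_iter=12_000, burn_in=2_000, thin=2, seed=seed)


class TestFitTwoGroupModel:
    def test_matches_analytic_t_posterior(self):
        rng = np.random.default_rng(7)
        y1 = rng.normal(0.5, 1.0, 20)
        y2 = rng.normal(0.0, 1.0, 20)
        df = two_group_frame(y1, y2)
        chain = bayes.fit_two_group_model(
            df, "t", "F1",
            config=bayes.GibbsConfig(n_iter=60_000, burn_in=10_000, thin=1, seed=5),
        )
        s = bayes.summarize_posterior(chain)
        # independent oracle: flat-prior posterior of the contrast is
        # location-scale t with n - p df around the OLS contrast
        d_hat = y1.mean() - y2.mean()
        sse = ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
        scale = math.sqrt(sse / 38 * (1 / 20 + 1 / 20))
        assert abs(s.D_mean - d_hat) < 3 * s.mcse
        assert abs(s.P0 - stats.t.cdf(abs(d_hat) / scale, df=38)) < 0.01
        q = stats.t.ppf(0.975, df=38)
        assert abs(s.hpd_low - (d_hat - q * scale)) < 0.05 * scale
        assert abs(s.hpd_high - (d_hat + q * scale)) < 0.05 * scale

    def test_label_antisymmetry(self):
        rng = np.random.default_rng(21)
        y1 = rng.normal(1.0, 1.0, 15)
        y2 = rng.normal(0.0, 1.0, 15)
        df = two_group_frame(y1, y2)
        swapped = df.copy()
        swapped["group"] = swapped["group"].map({"NC": "VT", "VT": "NC"})
        s_a = bayes.summarize_posterior(
            bayes.fit_two_group_model(df, "t", "F1", config=_quick_config(9))
        )
        s_b = bayes.summarize_posterior(
            bayes.fit_two_group_model(swapped, "t", "F1", config=_quick_config(9))
        )
        assert abs(s_a.D_mean + s_b.D_mean) < 3 * (s_a.mcse + s_b.mcse)

    def test_covariate_slope_recovery(self):
        rng = np.random.default_rng(13)
        n = 40
        slope = 0.02
        bw = rng.normal(3700.0, 300.0, 2 * n)
        organ = 95.0 + slope * (bw - 3700.0) + rng.normal(0, 3.0, 2 * n)
        organ[n:] -= 8.0  # VT deficit
        df = two_group_frame(organ[:n], organ[n:], covariate=bw)
        chain = bayes.fit_two_group_model(
            df, "t", "F1", use_covariate=True, config=_quick_config(2)
        )
        beta = np.asarray(chain.samples_beta)
        assert abs(beta.mean() - slope) < 3 * beta.std(ddof=1)

    def test_reproducible_bit_identical(self):
        rng = np.random.default_rng(3)
        df = two_group_frame(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        c1 = bayes.fit_two_group_model(df, "t", "F1", config=_quick_config(4))
        c2 = bayes.fit_two_group_model(df, "t", "F1", config=_quick_config(4))
        assert np.array_equal(c1.samples_D, c2.samples_D)
        assert np.array_equal(c1.samples_sigma2, c2.samples_sigma2)

    def test_chain_length_bookkeeping(self):
        rng = np.random.default_rng(3)
        df = two_group_frame(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        cfg = bayes.GibbsConfig(n_iter=8_000, burn_in=3_000, thin=5, seed=0)
        chain = bayes.fit_two_group_model(df, "t", "F1", config=cfg)
        assert len(chain.samples_D) == cfg.n_saved == 1000

    def test_bounded_path_respects_bounds(self):
        rng = np.random.default_rng(8)
        df = two_group_frame(rng.normal(0, 1, 12), rng.normal(0, 1, 12))
        cfg = bayes.GibbsConfig(
            n_iter=2_000, burn_in=500, thin=1, seed=1,
            prior_bounds={"location": (-0.25, 0.25)},
        )
        chain = bayes.fit_two_group_model(df, "t", "F1", config=cfg)
        # D = mu_NC - mu_VT with both locations in [-0.25, 0.25]
        assert np.all(np.abs(chain.samples_D) <= 0.5 + 1e-12)

    def test_missing_group_rejected(self):
        df = two_group_frame([1.0, 2.0, 3.0], [])
        with pytest.raises(DesignError):
            bayes.fit_two_group_model(df, "t", "F1", config=_quick_config())

    def test_covariate_required_when_requested(self):
        df = two_group_frame([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        with pytest.raises(DesignError):
            bayes.fit_two_group_model(
                df, "t", "F1", use_covariate=True, config=_quick_config()
            )

    def test_unknown_trait_rejected(self):
        df = two_group_frame([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DesignError):
            bayes.fit_two_group_model(df, "nope", "F1", config=_quick_config())
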