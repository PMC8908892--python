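import numpy as np
import pytest

from raylife.inference import (
    MCMCConfig,
    PosteriorDraws,
    Prior,
    PriorSpec,
    SamplerError,
    ess,
    rhat,
    sample_posterior,
    summarize,
)


def std_normal(theta):
    return -0.5 * float(theta[0] ** 2)


class TestSampler:
    def test_recovers_standard_normal_mean(self):
        draws = sample_posterior(std_normal, [0.5], MCMCConfig(seed=1))
        x = draws.flat("theta_0")
        mcse = x.std() / np.sqrt(ess(draws, "theta_0"))
        assert abs(x.mean()) < 3 * mcse
        assert x.std() == pytest.approx(1.0, rel=0.1)

    def test_recovers_correlated_gaussian_covariance(self):
        cov = np.array([[1.0, 0.8], [0.8, 2.0]])
        prec = np.linalg.inv(cov)

        def log_post(theta):
            return -0.5 * float(theta @ prec @ theta)

        draws = sample_posterior(log_post, [0.0, 0.0], MCMCConfig(seed=2))
        sample_cov = np.cov(draws.array.reshape(-1, 2).T)
        assert np.allclose(sample_cov, cov, rtol=0.10, atol=0.05)

    def test_same_seed_bit_identical(self):
        a = sample_posterior(std_normal, [0.0], MCMCConfig(seed=7, n_chains=2, n_iter=600, n_warmup=200))
        b = sample_posterior(std_normal, [0.0], MCMCConfig(seed=7, n_chains=2, n_iter=600, n_warmup=200))
        assert np.array_equal(a.array, b.array)

    def test_different_seed_differs(self):
        a = sample_posterior(std_normal, [0.0], MCMCConfig(seed=7, n_chains=2, n_iter=600, n_warmup=200))
        b = sample_posterior(std_normal, [0.0], MCMCConfig(seed=8, n_chains=2, n_iter=600, n_warmup=200))
        assert not np.array_equal(a.array, b.array)

    def test_retained_draw_count(self):
        cfg = MCMCConfig()
        draws = sample_posterior(std_normal, [0.0], cfg)
        assert draws.array.shape[:2] == (4, 2500)
        assert draws.n_chains * draws.n_draws == 10_000

    def test_nan_at_init_rejected(self):
        with pytest.raises(SamplerError):
            sample_posterior(lambda t: float("nan"), [0.0], MCMCConfig(seed=1))

    def test_all_rejected_warmup_raises(self):
        # point mass at the initial point: every proposal falls outside
        def spike(theta):
            return 0.0 if theta[0] == 0.0 else -np.inf

        with pytest.raises(SamplerError):
            sample_posterior(spike, [0.0], MCMCConfig(seed=1, n_chains=2, n_iter=600, n_warmup=200))

    def test_prior_only_sampling_recovers_prior_quantiles(self):
        # flat likelihood: the posterior is the prior itself
        prior = Prior("lognormal", np.log(10.0), 1.0)

        def log_post(theta):
            return prior.logpdf(float(np.exp(theta[0]))) + float(theta[0])

        draws = sample_posterior(
            log_post, [np.log(10.0)], MCMCConfig(seed=3)
        ).transformed(np.exp)
        x = draws.flat("theta_0")
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(x, q) == pytest.approx(prior.ppf(q), rel=0.1)


class TestDiagnostics:
    def test_rhat_near_one_for_iid_chains(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(4, 2500))
        assert rhat(m) < 1.01

    def test_rhat_large_for_disjoint_chains(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(4, 500)) + np.array([[0.0], [100.0], [200.0], [300.0]])
        assert rhat(m) > 1.1

    def test_rhat_constant_chains_flagged(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rhat(np.ones((4, 100))))

    def test_ess_iid(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(4, 2500))
        assert ess(m) == pytest.approx(10_000, rel=0.2)

    def test_ess_ar1(self):
        # AR(1) with phi=0.9 has ESS ~ n (1-phi)/(1+phi)
        rng = np.random.default_rng(2)
        phi, n = 0.9, 20_000
        chains = []
        for _ in range(4):
            e = rng.normal(size=n)
            x = np.empty(n)
            x[0] = e[0] / np.sqrt(1 - phi**2)
            for i in range(1, n):
                x[i] = phi * x[i - 1] + e[i]
            chains.append(x)
        m = np.stack(chains)
        expected = 4 * n * (1 - phi) / (1 + phi)
        assert ess(m) == pytest.approx(expected, rel=0.3)

    def test_ess_constant_minimal(self):
        with pytest.warns(RuntimeWarning):
            assert ess(np.ones((4, 100))) <= 1.0

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))


class TestSummarize:
    def _draws(self, arr, names):
        cfg = MCMCConfig(n_chains=2, n_iter=arr.shape[1] + 1, n_warmup=1, seed=0)
        return PosteriorDraws(arr, names, cfg)

    def test_manual_quantile_oracle(self):
        # 10 hand-listed values; equal-tailed quantiles by linear interpolation:
        # q(0.025) between the 1st and 2nd order stats at fraction 0.225, etc.
        vals = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        s = np.sort(vals)
        expected_low = s[0] + 0.225 * (s[1] - s[0])
        expected_high = s[8] + 0.775 * (s[9] - s[8])
        summary = summarize(self._draws(vals.reshape(2, 5, 1), ["x"]))
        row = summary["x"]
        assert row["median"] == pytest.approx(np.median(vals))
        assert row["ci_low"] == pytest.approx(expected_low)
        assert row["ci_high"] == pytest.approx(expected_high)

    def test_ci_ordering_and_symmetric_median(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(2.0, 1.0, size=(4, 2000, 2))
        summary = summarize(self._draws(arr, ["a", "b"]))
        for name in ("a", "b"):
            row = summary[name]
            assert row["ci_low"] <= row["median"] <= row["ci_high"]
            mcse = arr[..., 0].std() / np.sqrt(row["ess"])
            assert row["median"] == pytest.approx(arr[..., ["a", "b"].index(name)].mean(), abs=4 * mcse)
            assert row["ess"] <= 8000


class TestPrior:
    def test_prior_logpdf_matches_scipy(self):
        from scipy import stats

        cases = [
            (Prior("lognormal", np.log(10), 1.0), stats.lognorm(s=1.0, scale=10.0), 8.0),
            (Prior("normal", -1.0, 1.0), stats.norm(-1.0, 1.0), 0.3),
            (Prior("half_normal", 0.0, 5.0), stats.halfnorm(0.0, 5.0), 2.0),
        ]
        for prior, dist, x in cases:
            assert prior.logpdf(x) == pytest.approx(dist.logpdf(x))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            Prior("normal", 0.0, -1.0)

    def test_priorspec_is_mapping(self):
        spec = PriorSpec({"a": Prior("normal", 10, 5)})
        assert list(spec) == ["a"]
        assert spec.logpdf({"a": 10.0}) == pytest.approx(Prior("normal", 10, 5).logpdf(10.0))
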