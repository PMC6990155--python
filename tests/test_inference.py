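import math

import numpy as np
import pytest
from scipy import stats

from hergchar.inference import (
    ChainConfig,
    PriorBox,
    fit_map,
    log_likelihood,
    log_posterior,
    make_cache,
    rhat,
    sample_posterior,
    simulate_cached,
)
from hergchar.model import N_PARAMETERS
from hergchar.synthetic import synthesize_current


@pytest.fixture(scope="module")
def noiseless_trace(ref_params, env, staircase_1khz):
    return synthesize_current(ref_params, staircase_1khz, env)


class TestLikelihood:
    def test_zero_residual_value(self, ref_params, env, staircase_1khz, noiseless_trace):
        sigma = 2.0
        ll = log_likelihood(ref_params.log_transform(), sigma, noiseless_trace,
                            staircase_1khz, env)
        n = noiseless_trace.times.size
        assert ll == pytest.approx(-0.5 * n * math.log(2 * math.pi * sigma**2), rel=1e-12)

    def test_agrees_with_elementwise_oracle(self, ref_params, env, staircase_1khz, noiseless_trace):
        rng = np.random.default_rng(0)
        sigma = 3.0
        y = noiseless_trace.with_currents(
            noiseless_trace.currents + rng.normal(0, sigma, noiseless_trace.times.size)
        )
        phi = ref_params.log_transform()
        ll = log_likelihood(phi, sigma, y, staircase_1khz, env)
        cache = make_cache(staircase_1khz, env, fit_start=None)
        z = simulate_cached(phi, cache)
        brute = sum(
            float(stats.norm.logpdf(yk, zk, sigma))
            for yk, zk in zip(y.currents, z)
        )
        assert ll == pytest.approx(brute, rel=1e-10)

    def test_doubling_sigma_with_zero_residuals(self, ref_params, env, staircase_1khz, noiseless_trace):
        phi = ref_params.log_transform()
        l1 = log_likelihood(phi, 1.0, noiseless_trace, staircase_1khz, env)
        l2 = log_likelihood(phi, 2.0, noiseless_trace, staircase_1khz, env)
        n = noiseless_trace.times.size
        assert l1 - l2 == pytest.approx(n * math.log(2), rel=1e-9)

    def test_invalid_sigma(self, ref_params, env, staircase_1khz, noiseless_trace):
        with pytest.raises(ValueError):
            log_likelihood(ref_params.log_transform(), 0.0, noiseless_trace,
                           staircase_1khz, env)


class TestPrior:
    def test_reference_parameters_supported(self, ref_params):
        assert PriorBox.default().contains(ref_params.log_transform())

    def test_outside_box_posterior_is_minus_inf(self, ref_params, env, staircase_1khz,
                                                noiseless_trace):
        prior = PriorBox.default()
        phi = prior.phi_max + 1.0
        assert log_posterior(phi, 1.0, noiseless_trace, prior, staircase_1khz, env) == -math.inf

    def test_boundary_included(self, env, staircase_1khz, noiseless_trace):
        prior = PriorBox.default(rate_constraint=False)
        lp = log_posterior(prior.phi_min, 1.0, noiseless_trace, prior, staircase_1khz, env)
        assert math.isfinite(lp)

    def test_inside_equals_likelihood(self, ref_params, env, staircase_1khz, noiseless_trace):
        prior = PriorBox.default()
        phi = ref_params.log_transform()
        assert log_posterior(phi, 2.0, noiseless_trace, prior, staircase_1khz, env) == \
            log_likelihood(phi, 2.0, noiseless_trace, staircase_1khz, env)

    def test_samples_respect_support(self):
        prior = PriorBox.default()
        rng = np.random.default_rng(0)
        for phi in prior.sample(rng, 50):
            assert prior.contains(phi)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            PriorBox(np.zeros(9), np.zeros(9))


class TestFitMap:
    def test_warm_start_recovers_truth(self, ref_params, env, staircase_1khz, noiseless_trace):
        phi_true = ref_params.log_transform()
        rng = np.random.default_rng(0)
        x0 = phi_true + rng.normal(0, 0.05, N_PARAMETERS)
        fit = fit_map(noiseless_trace, staircase_1khz, seed=0, env=env,
                      x0=x0, n_restarts=2, maxiter=400)
        rel = np.abs(fit.theta.as_array() / ref_params.as_array() - 1)
        assert rel.max() < 1e-3
        # global-optimum sanity: the noiseless optimum has zero misfit, so
        # the fitted SSE must be negligible against the data's energy
        energy = float(noiseless_trace.currents @ noiseless_trace.currents)
        assert fit.sse < 1e-9 * energy

    def test_deterministic_given_seed(self, env, staircase_1khz, noiseless_trace, ref_params):
        kwargs = dict(x0=ref_params.log_transform(), n_restarts=2, maxiter=60, polish=False)
        f1 = fit_map(noiseless_trace, staircase_1khz, seed=7, env=env, **kwargs)
        f2 = fit_map(noiseless_trace, staircase_1khz, seed=7, env=env, **kwargs)
        assert np.array_equal(f1.phi, f2.phi)

    def test_sigma_profiled_as_rms_residual(self, ref_params, env, staircase_1khz):
        rng = np.random.default_rng(5)
        sigma = 10.0
        clean = synthesize_current(ref_params, staircase_1khz, env)
        y = clean.with_currents(clean.currents + rng.normal(0, sigma, clean.times.size))
        fit = fit_map(y, staircase_1khz, seed=1, env=env,
                      x0=ref_params.log_transform(), n_restarts=1, maxiter=200)
        assert fit.sigma == pytest.approx(sigma, rel=0.05)

    def test_invalid_restarts(self, noiseless_trace, staircase_1khz, env):
        with pytest.raises(ValueError):
            fit_map(noiseless_trace, staircase_1khz, n_restarts=0, env=env)


class TestSampler:
    def test_prior_only_target_is_uniform(self):
        # small box; likelihood switched off -> the sampler must reproduce
        # the uniform prior in every margin
        lo = np.full(9, -1.0)
        hi = np.full(9, 1.0)
        prior = PriorBox(lo, hi, rate_bounds=None)
        cfg = ChainConfig(n_chains=1, n_iter=60000, n_rungs=1, burn_in=0.25,
                          init_step=0.5, start_jitter=0.1, adapt_start=100)
        chain = sample_posterior(None, None, prior, (np.zeros(9), 1.0),
                                 cfg, seed=3, target="prior")
        samples = chain.samples
        # thin past the random-walk autocorrelation so KS (an iid test)
        # sees effectively independent draws
        for i in range(9):
            u = (samples[::150, i] - lo[i]) / (hi[i] - lo[i])
            p = stats.kstest(u, "uniform").pvalue
            assert p > 0.01, f"margin {i} not uniform (p={p})"

    def test_samples_stay_in_support(self):
        prior = PriorBox(np.full(9, -2.0), np.full(9, 2.0), rate_bounds=None)
        cfg = ChainConfig(n_chains=2, n_iter=2000, n_rungs=2, init_step=0.5,
                          start_jitter=0.1, adapt_start=100)
        chain = sample_posterior(None, None, prior, (np.zeros(9), 1.0),
                                 cfg, seed=4, target="prior")
        phi = chain.samples_by_chain[..., :9]
        assert phi.min() >= -2.0 and phi.max() <= 2.0

    def test_bad_start_rejected(self, staircase_1khz, env, noiseless_trace):
        prior = PriorBox(np.full(9, -1.0), np.full(9, 1.0), rate_bounds=None)
        with pytest.raises(ValueError):
            sample_posterior(noiseless_trace, staircase_1khz, prior,
                             (np.full(9, 5.0), -1.0), ChainConfig(n_iter=10),
                             seed=0, env=env)

    def test_ladder_must_start_cold(self):
        with pytest.raises(ValueError):
            ChainConfig(betas=(0.5, 0.25)).ladder()


def test_rhat_detects_disagreeing_chains():
    rng = np.random.default_rng(0)
    good = rng.normal(0, 1, (4, 500, 1))
    bad = good.copy()
    bad[0] += 5.0
    assert rhat(good).max() < 1.1
    assert rhat(bad).max() > 1.5
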