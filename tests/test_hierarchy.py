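import numpy as np
import pytest
from scipy import stats

from hergchar.hierarchy import (
    HyperSample,
    NIWHyperprior,
    correlation_matrix,
    gibbs_update_hypers,
    marginal_predictive_density,
    posterior_predictive_density,
    run_hierarchical,
    sample_posterior_predictive,
)


def fake_well_chains(phi_set, n_samples=200, jitter=1e-3, seed=0):
    """Stand-in per-well posterior chains: tight Gaussian clouds around the
    true phi_j, emulating the near-certain per-well posteriors that the
    pseudo-Gibbs scheme assumes."""
    rng = np.random.default_rng(seed)
    return [p + jitter * rng.standard_normal((n_samples, p.size)) for p in phi_set]


class TestGibbsUpdate:
    def test_mu_concentrates_at_sample_mean(self):
        rng = np.random.default_rng(0)
        d = 9
        phi = rng.normal(0.0, 0.3, (500, d))
        m = phi.mean(axis=0)
        hp = NIWHyperprior(dim=d)
        mus = []
        sigma = None
        g = np.random.default_rng(1)
        for _ in range(400):
            hs = gibbs_update_hypers(phi, hp, g, sigma=sigma)
            sigma = hs.sigma
            mus.append(hs.mu)
        mu_bar = np.mean(mus, axis=0)
        se = 0.3 / np.sqrt(500)
        assert np.all(np.abs(mu_bar - m) < 3 * se)

    def test_conjugate_moments_in_two_dimensions(self):
        # with kappa0 = 0 the exact marginal posterior of Sigma is
        # InvWishart(nu0 + n - 1, Psi0 + S) about the sample mean
        rng = np.random.default_rng(2)
        n, d = 300, 2
        cov_true = np.array([[1.0, 0.6], [0.6, 1.0]])
        phi = rng.multivariate_normal([0, 0], cov_true, size=n)
        s = (phi - phi.mean(0)).T @ (phi - phi.mean(0))
        psi0 = 0.01 * np.eye(d)
        hp = NIWHyperprior(dim=d, mu0=np.zeros(d), nu0=d + 3, psi0=psi0)
        analytic = (psi0 + s) / (d + 3 + n - 1 - d - 1)
        g = np.random.default_rng(3)
        sigmas = []
        sigma = None
        for _ in range(3000):
            hs = gibbs_update_hypers(phi, hp, g, sigma=sigma)
            sigma = hs.sigma
            sigmas.append(sigma)
        est = np.mean(sigmas, axis=0)
        assert np.allclose(est, analytic, rtol=0.05)

    def test_zero_scatter_shrinks_to_hyperprior_scale(self):
        phi = np.tile(np.arange(9.0), (50, 1))
        hp = NIWHyperprior(dim=9)
        with pytest.warns(UserWarning):
            hs = gibbs_update_hypers(phi, hp, np.random.default_rng(0))
        assert np.all(np.diag(hs.sigma) < 0.01)

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError):
            gibbs_update_hypers(np.zeros((1, 9)), rng=np.random.default_rng(0))


class TestRunHierarchical:
    def _phi_set(self, corr, sd, n, seed):
        rng = np.random.default_rng(seed)
        cov = corr * np.outer(sd, sd)
        return rng.multivariate_normal(np.zeros(9), cov, size=n)

    @staticmethod
    def _oracle_corrs(phi, n_draws=4000, seed=0):
        """Independent conjugate oracle: with kappa0 = 0 the marginal
        posterior of Sigma is InvWishart(nu0 + N - 1, Psi0 + S), S the
        scatter about the sample mean; draw from it directly with scipy."""
        n, d = phi.shape
        hp = NIWHyperprior(dim=d)
        _, _, nu0, psi0 = hp.resolved()
        centred = phi - phi.mean(axis=0)
        scale = psi0 + centred.T @ centred
        draws = stats.invwishart.rvs(df=nu0 + n - 1, scale=scale, size=n_draws,
                                     random_state=np.random.default_rng(seed))
        return np.array([correlation_matrix(s) for s in draws])

    def test_correlated_truth_recovered(self):
        s = np.array([1, 1, -1, 1, -1, 1, 1, -1, 1.0])
        corr_true = 0.9 * np.outer(s, s) + 0.1 * np.eye(9)
        sd = np.full(9, 0.2)
        phi = self._phi_set(corr_true, sd, 20, seed=4)
        hc = run_hierarchical(fake_well_chains(phi), n_iter=3000, seed=5)
        corr = hc.posterior_mean_correlation()
        iu = np.triu_indices(9, 1)
        # the sampler must agree with the analytic conjugate posterior ...
        oracle = self._oracle_corrs(phi).mean(axis=0)
        assert np.max(np.abs(corr - oracle)[iu]) < 0.03
        # ... and every strong correlation keeps its sign
        assert np.all(np.sign(corr[iu]) == np.sign(corr_true[iu]))

    def test_diagonal_truth_credible_intervals_contain_zero(self):
        phi = self._phi_set(np.eye(9), np.full(9, 0.2), 20, seed=6)
        hc = run_hierarchical(fake_well_chains(phi), n_iter=3000, seed=7)
        lo, hi = hc.correlation_credible_interval(0.95)
        iu = np.triu_indices(9, 1)
        contains = ((lo[iu] <= 0) & (0 <= hi[iu])).sum()
        # the sampler's interval endpoints must match the analytic
        # conjugate posterior's quantiles for this particular 20-well draw
        corrs = self._oracle_corrs(phi)
        o_lo, o_hi = np.quantile(corrs, [0.025, 0.975], axis=0)
        assert np.max(np.abs(lo[iu] - o_lo[iu])) < 0.05
        assert np.max(np.abs(hi[iu] - o_hi[iu])) < 0.05
        assert contains >= 30

    def test_deterministic_given_seed(self):
        phi = self._phi_set(np.eye(9), np.full(9, 0.2), 5, seed=8)
        chains = fake_well_chains(phi)
        a = run_hierarchical(chains, n_iter=50, seed=9)
        b = run_hierarchical(chains, n_iter=50, seed=9)
        assert np.array_equal(a.mus, b.mus) and np.array_equal(a.sigmas, b.sigmas)

    def test_every_sigma_sample_is_spd(self):
        phi = self._phi_set(np.eye(9), np.full(9, 0.2), 10, seed=10)
        hc = run_hierarchical(fake_well_chains(phi), n_iter=200, seed=11)
        for s in hc.sigmas[::20]:
            np.linalg.cholesky(s)  # raises if not SPD

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            run_hierarchical([np.zeros((0, 9)), np.zeros((10, 9))], n_iter=10, seed=0)

    def test_single_well_rejected(self):
        with pytest.raises(ValueError):
            run_hierarchical([np.zeros((10, 9))], n_iter=10, seed=0)


class TestCorrelationMatrix:
    def test_diagonal_gives_identity(self):
        assert np.allclose(correlation_matrix(np.diag([1.0, 4.0, 9.0])), np.eye(3))

    def test_closed_form_two_by_two(self):
        corr = correlation_matrix(np.array([[4.0, 2.0], [2.0, 4.0]]))
        assert corr[0, 1] == pytest.approx(0.5)

    def test_unit_diagonal_and_spd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(9, 9))
        sigma = a @ a.T + 9 * np.eye(9)
        corr = correlation_matrix(sigma)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.linalg.eigvalsh(corr).min() > 0

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.diag([1.0, 0.0]))


class TestPosteriorPredictive:
    def _single_sample_chain(self):
        mu = np.zeros(9)
        sigma = 0.04 * np.eye(9)
        hc = run_hierarchical(fake_well_chains(np.tile(mu, (3, 1)), jitter=1e-4),
                              n_iter=2, seed=0)
        hc.mus[:] = mu
        hc.sigmas[:] = sigma
        return hc, mu, sigma

    def test_single_component_density_is_lognormal(self):
        hc, mu, sigma = self._single_sample_chain()
        theta = np.exp(mu) * np.exp(0.05)
        dens = posterior_predictive_density(hc, theta[None, :])[0]
        expected = stats.multivariate_normal.pdf(np.log(theta), mu, sigma) \
            * np.exp(-np.sum(np.log(theta)))
        assert dens == pytest.approx(expected, rel=1e-9)

    def test_marginal_integrates_to_one(self):
        hc, mu, sigma = self._single_sample_chain()
        grid = np.exp(np.linspace(-2.0, 2.0, 4001))
        dens = marginal_predictive_density(hc, 0, grid)
        integral = np.trapezoid(dens, grid)
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_predictive_draw_moments(self):
        hc, mu, sigma = self._single_sample_chain()
        draws = sample_posterior_predictive(hc, 4000, seed=1)
        log_mean = np.log(draws).mean(axis=0)
        se = np.sqrt(np.diag(sigma) / 4000)
        assert np.all(np.abs(log_mean - mu) < 4 * se)

    def test_nonpositive_theta_rejected(self):
        hc, *_ = self._single_sample_chain()
        with pytest.raises(ValueError):
            posterior_predictive_density(hc, np.array([[-1.0] * 9]))


def test_hyper_sample_requires_spd():
    with pytest.raises(np.linalg.LinAlgError):
        HyperSample(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))
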