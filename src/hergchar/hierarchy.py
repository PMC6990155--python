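"""Hierarchical Bayesian pooling of per-well parameter posteriors.

Across wells, the log-parameters are assumed exchangeable draws from a
multivariate normal, phi_j ~ N(mu, Sigma) — i.e. theta_j is multivariate
log-normal — with a conjugate normal-inverse-Wishart hyperprior on
(mu, Sigma).  The joint posterior over hyperparameters and well parameters
is sampled with a *pseudo* Metropolis-within-Gibbs scheme: because each
well's time trace contains vastly more data points than there are wells,
the well-level conditional posterior is essentially unchanged by the
hyperparameter values, so instead of re-running Metropolis steps the
sampler redraws each phi_j uniformly from that well's stored posterior
chain, then Gibbs-updates (mu, Sigma) from their conjugate conditionals:

    mu | Sigma, {phi_j}  ~  N((kappa0 mu0 + N m)/(kappa0 + N), Sigma/(kappa0 + N))
    Sigma | mu, {phi_j}  ~  InvWishart(nu0 + N,
                             Psi0 + sum_j (phi_j - mu)(phi_j - mu)^T
                                  + kappa0 (mu - mu0)(mu - mu0)^T)

The noise scales sigma_j keep their independent per-well priors and are
not pooled.  The inferred Sigma is summarised by the correlation matrix
corr = D^{-1/2} Sigma D^{-1/2}, and the posterior predictive distribution
of a future well's parameters is the mixture over hyper samples of
LogNormal(mu, Sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import N_PARAMETERS

__all__ = [
    "NIWHyperprior",
    "HyperSample",
    "HyperChain",
    "gibbs_update_hypers",
    "run_hierarchical",
    "correlation_matrix",
    "posterior_predictive_density",
    "marginal_predictive_density",
    "sample_posterior_predictive",
]


@dataclass(frozen=True)
class NIWHyperprior:
    """Weakly informative normal-inverse-Wishart hyperprior.

    Defaults: nu0 = dim + 3, Psi0 a small multiple of the identity on the
    log scale, kappa0 = 0 (no shrinkage of mu towards mu0; mu0 then only
    matters as a fallback initialisation), mu0 = centre of the default
    prior box.
    """

    dim: int = N_PARAMETERS
    mu0: np.ndarray | None = None
    kappa0: float = 0.0
    nu0: float | None = None
    psi0: np.ndarray | None = None

    def resolved(self):
        from .inference import PriorBox

        mu0 = self.mu0
        if mu0 is None:
            box = PriorBox.default(rate_constraint=False)
            mu0 = 0.5 * (box.phi_min + box.phi_max)[: self.dim]
            if self.dim != N_PARAMETERS:
                mu0 = np.zeros(self.dim)
        nu0 = self.nu0 if self.nu0 is not None else self.dim + 3
        psi0 = self.psi0 if self.psi0 is not None else 0.005 * np.eye(self.dim)
        if nu0 < self.dim:
            raise ValueError("nu0 must be >= dim for a proper inverse-Wishart")
        return np.asarray(mu0, float), float(self.kappa0), float(nu0), np.asarray(psi0, float)


@dataclass(frozen=True)
class HyperSample:
    mu: np.ndarray
    sigma: np.ndarray  # covariance on the log scale

    def __post_init__(self):
        mu = np.asarray(self.mu, float)
        s = np.asarray(self.sigma, float)
        if s.shape != (mu.size, mu.size):
            raise ValueError("Sigma shape must match mu")
        np.linalg.cholesky(s)  # raises if not SPD
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", s)


@dataclass
class HyperChain:
    """Sequence of (mu, Sigma) samples plus provenance."""

    mus: np.ndarray      # (n_iter, d)
    sigmas: np.ndarray   # (n_iter, d, d)
    hyperprior: NIWHyperprior
    seed: int | None
    n_wells: int

    def __len__(self):
        return self.mus.shape[0]

    def posterior_mean_correlation(self) -> np.ndarray:
        corrs = np.array([correlation_matrix(s) for s in self.sigmas])
        return corrs.mean(axis=0)

    def correlation_credible_interval(self, level: float = 0.95) -> np.ndarray:
        """(2, d, d) elementwise quantiles of the correlation samples."""
        corrs = np.array([correlation_matrix(s) for s in self.sigmas])
        a = (1 - level) / 2
        return np.quantile(corrs, [a, 1 - a], axis=0)


def gibbs_update_hypers(
    phi_set: np.ndarray,
    hyperprior: NIWHyperprior | None = None,
    rng=None,
    sigma: np.ndarray | None = None,
) -> HyperSample:
    """One Gibbs sweep for (mu, Sigma) given well-level log-parameters.

    ``phi_set`` is (N_e, d) with N_e >= 2.  ``sigma`` is the current Sigma
    used to draw mu (initialised from the empirical scatter plus the
    hyperprior scale if omitted).  A rank-deficient phi_set is handled by
    the hyperprior's Psi0 regularisation (with a warning).
    """
    import warnings

    phi_set = np.asarray(phi_set, dtype=float)
    if phi_set.ndim != 2 or phi_set.shape[0] < 2:
        raise ValueError("phi_set must be (N_e >= 2, d)")
    n, d = phi_set.shape
    hyperprior = hyperprior or NIWHyperprior(dim=d)
    mu0, kappa0, nu0, psi0 = hyperprior.resolved()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    m = phi_set.mean(axis=0)
    if sigma is None:
        centred = phi_set - m
        sigma = (centred.T @ centred + psi0) / max(n - 1, 1)
    if np.linalg.matrix_rank(phi_set - m) < min(n - 1, d):
        warnings.warn("rank-deficient phi_set; posterior regularised by the hyperprior")

    kappa_n = kappa0 + n
    mu_mean = (kappa0 * mu0 + n * m) / kappa_n
    mu = rng.multivariate_normal(mu_mean, sigma / kappa_n)

    centred = phi_set - mu
    scale = psi0 + centred.T @ centred + kappa0 * np.outer(mu - mu0, mu - mu0)
    scale = 0.5 * (scale + scale.T)
    sigma_new = stats.invwishart.rvs(df=nu0 + n, scale=scale, random_state=rng)
    sigma_new = 0.5 * (sigma_new + sigma_new.T)
    return HyperSample(mu, sigma_new)


def run_hierarchical(
    per_well_chains,
    hyperprior: NIWHyperprior | None = None,
    n_iter: int = 10000,
    thin: int = 1,
    seed: int | None = None,
) -> HyperChain:
    """Pseudo-Metropolis-within-Gibbs over the hierarchical posterior.

    ``per_well_chains`` is a sequence of stored per-well posterior sample
    arrays (n_samples_j, d) over phi (a :class:`PosteriorChain` is accepted
    and contributes its phi samples).  Each iteration draws one stored
    sample per well uniformly at random (after thinning by ``thin``), then
    Gibbs-updates (mu, Sigma).
    """
    from .inference import PosteriorChain

    chains = []
    for ch in per_well_chains:
        arr = ch.phi_samples if isinstance(ch, PosteriorChain) else np.asarray(ch, float)
        if arr.ndim != 2 or arr.shape[0] == 0:
            raise ValueError("each well must contribute a non-empty 2-D sample array")
        chains.append(arr[::thin])
    if len(chains) < 2:
        raise ValueError("need at least two wells to pool")
    d = chains[0].shape[1]
    hyperprior = hyperprior or NIWHyperprior(dim=d)
    rng = np.random.default_rng(seed)

    mus = np.empty((n_iter, d))
    sigmas = np.empty((n_iter, d, d))
    sigma = None
    for t in range(n_iter):
        phi_set = np.array([c[rng.integers(c.shape[0])] for c in chains])
        hs = gibbs_update_hypers(phi_set, hyperprior, rng, sigma=sigma)
        sigma = hs.sigma
        mus[t] = hs.mu
        sigmas[t] = hs.sigma
    return HyperChain(mus, sigmas, hyperprior, seed, len(chains))


def correlation_matrix(sigma: np.ndarray) -> np.ndarray:
    """corr = D^{-1/2} Sigma D^{-1/2}; raises on nonpositive diagonal."""
    sigma = np.asarray(sigma, dtype=float)
    diag = np.diag(sigma)
    if np.any(diag <= 0):
        raise ValueError("covariance diagonal must be positive")
    d_inv = 1.0 / np.sqrt(diag)
    corr = sigma * np.outer(d_inv, d_inv)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def _check_chain(hyper_chain: HyperChain):
    if len(hyper_chain) == 0:
        raise ValueError("empty hyper chain")


def posterior_predictive_density(hyper_chain: HyperChain, theta_points: np.ndarray,
                                 max_components: int = 500) -> np.ndarray:
    """Posterior predictive density p(theta | data) at the given points.

    The predictive is the mixture over hyper samples of the multivariate
    log-normal LogNormal(mu, Sigma); at most ``max_components`` evenly
    spaced hyper samples are used.  ``theta_points`` is (n, d) on the
    natural (positive) scale.
    """
    _check_chain(hyper_chain)
    theta_points = np.atleast_2d(np.asarray(theta_points, dtype=float))
    if np.any(theta_points <= 0):
        raise ValueError("theta must be positive")
    log_t = np.log(theta_points)
    jac = np.exp(-log_t.sum(axis=1))  # d phi / d theta
    step = max(len(hyper_chain) // max_components, 1)
    dens = np.zeros(theta_points.shape[0])
    count = 0
    for mu, sig in zip(hyper_chain.mus[::step], hyper_chain.sigmas[::step]):
        dens += stats.multivariate_normal.pdf(log_t, mean=mu, cov=sig, allow_singular=False)
        count += 1
    return dens / count * jac


def marginal_predictive_density(hyper_chain: HyperChain, index: int, theta_grid: np.ndarray,
                                max_components: int = 500) -> np.ndarray:
    """1-D marginal of the posterior predictive for parameter ``index``."""
    _check_chain(hyper_chain)
    grid = np.asarray(theta_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("theta grid must be positive")
    step = max(len(hyper_chain) // max_components, 1)
    dens = np.zeros(grid.size)
    count = 0
    for mu, sig in zip(hyper_chain.mus[::step], hyper_chain.sigmas[::step]):
        sd = np.sqrt(sig[index, index])
        dens += stats.lognorm.pdf(grid, s=sd, scale=np.exp(mu[index]))
        count += 1
    return dens / count


def sample_posterior_predictive(hyper_chain: HyperChain, n: int, seed=None) -> np.ndarray:
    """Draw n future-well parameter vectors theta from the predictive."""
    _check_chain(hyper_chain)
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(hyper_chain), size=n)
    out = np.empty((n, hyper_chain.mus.shape[1]))
    for k, i in enumerate(idx):
        out[k] = np.exp(rng.multivariate_normal(hyper_chain.mus[i], hyper_chain.sigmas[i]))
    return out
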