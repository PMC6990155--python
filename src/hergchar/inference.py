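"""Single-well Bayesian inference for the staircase protocol.

The statistical model is additive i.i.d. Gaussian noise on the simulated
current, y_k = z_k(phi) + eps_k, eps_k ~ N(0, sigma^2), with parameters
inferred on the log scale phi = ln(theta) under a uniform box prior
(optionally intersected with a physiological-rate constraint on the four
transition rates).  Inference is two-step:

1. :func:`fit_map` — restart-capable stochastic global optimisation
   (a CMA-ES-style evolution strategy over phi, restarts initialised from
   the prior) with the noise scale sigma profiled analytically as the RMS
   residual, followed by a local polish.
2. :func:`sample_posterior` — population MCMC: several independent
   replicate populations, each a ladder of tempered chains driven by an
   adaptive-Metropolis base sampler with vanishing adaptation, exchanging
   states between neighbouring temperatures; the cold chain (beta = 1) is
   returned and convergence is summarised with split-R-hat across
   replicates.

By default the fit uses the staircase trace from 0.9 s onward: the initial
holding period and the leak ramp carry no kinetic information (the channel
is essentially closed below -80 mV) and the ramp is reserved for leak
estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    CurrentTrace,
    IonicEnvironment,
    KineticParameters,
    N_PARAMETERS,
    _integrate_gates,
    gate_steady_state,
    nernst_potential,
)
from .protocol import VoltageProtocol

__all__ = [
    "PriorBox",
    "NoiseModel",
    "ChainConfig",
    "FitResult",
    "PosteriorChain",
    "SimulationCache",
    "make_cache",
    "log_likelihood",
    "log_posterior",
    "fit_map",
    "sample_posterior",
    "rhat",
    "OptimizationError",
]

#: Samples before this time (holding + leak ramp) are excluded from fits.
DEFAULT_FIT_START = 0.9

#: Uniform prior support for ln(sigma) (sigma in pA).
LN_SIGMA_BOUNDS = (math.log(1e-4), math.log(1e4))


class OptimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


# ---------------------------------------------------------------------------
# Prior
# ---------------------------------------------------------------------------

# increasing rates k = A exp(+B V): parameter index pairs (A, B)
_RATE_UP = ((1, 2), (5, 6))
# decreasing rates k = A exp(-B V)
_RATE_DOWN = ((3, 4), (7, 8))


@dataclass(frozen=True)
class PriorBox:
    """Uniform box prior on phi = ln(theta), with an optional constraint
    that every transition rate stays within physiological bounds over the
    protocol's voltage range.

    Defaults: g_Kr in [0.1, 5e5] pS, A-type parameters in [1e-4, 1e6] 1/s,
    B-type in [1e-4, 400] 1/V, and k_i(V) in [1.67e-2, 1e6] 1/s for
    V in [-120, +60] mV.
    """

    phi_min: np.ndarray
    phi_max: np.ndarray
    rate_bounds: tuple | None = (1.67e-2, 1e6)
    v_range_mv: tuple = (-120.0, 60.0)

    def __post_init__(self):
        lo = np.asarray(self.phi_min, dtype=float)
        hi = np.asarray(self.phi_max, dtype=float)
        if lo.shape != (N_PARAMETERS,) or hi.shape != (N_PARAMETERS,):
            raise ValueError("phi_min/phi_max must be length-9 vectors")
        if not np.all(lo < hi):
            raise ValueError("phi_min must be elementwise < phi_max")
        object.__setattr__(self, "phi_min", lo)
        object.__setattr__(self, "phi_max", hi)

    @classmethod
    def default(cls, rate_constraint: bool = True) -> "PriorBox":
        theta_min = np.array([0.1] + [1e-4, 1e-4] * 4)
        theta_max = np.array([5e5] + [1e6, 400.0] * 4)
        return cls(np.log(theta_min), np.log(theta_max),
                   rate_bounds=(1.67e-2, 1e6) if rate_constraint else None)

    def _rates_ok(self, phi: np.ndarray) -> bool:
        # each rate, evaluated at its maximally activated voltage (+60 mV
        # for increasing, -120 mV for decreasing rates), must lie within
        # the physiological bounds; the rate at the other extreme may be
        # arbitrarily small (channels may be fully shut there)
        if self.rate_bounds is None:
            return True
        k_lo, k_hi = self.rate_bounds
        v_lo, v_hi = self.v_range_mv[0] * 1e-3, self.v_range_mv[1] * 1e-3
        for (ia, ib), sign in [(p, +1) for p in _RATE_UP] + [(p, -1) for p in _RATE_DOWN]:
            b = math.exp(phi[ib]) * sign
            k_max = phi[ia] + b * (v_hi if b > 0 else v_lo)
            if k_max > math.log(k_hi) or k_max < math.log(k_lo):
                return False
        return True

    def contains(self, phi) -> bool:
        phi = np.asarray(phi, dtype=float)
        if np.any(phi < self.phi_min) or np.any(phi > self.phi_max):
            return False
        return self._rates_ok(phi)

    def sample(self, rng, n: int = 1) -> np.ndarray:
        """Uniform draws from the box, rejection-filtered by the rate
        constraint; rows are phi vectors."""
        out = np.empty((n, N_PARAMETERS))
        filled = 0
        for _ in range(100000):
            cand = rng.uniform(self.phi_min, self.phi_max, size=(max(4 * (n - filled), 8), N_PARAMETERS))
            for c in cand:
                if self._rates_ok(c):
                    out[filled] = c
                    filled += 1
                    if filled == n:
                        return out
        raise RuntimeError("prior sampling failed; constraint region too small")

    def rate_violation(self, phi: np.ndarray) -> float:
        """Log-scale magnitude of the worst rate-bound excess (0 if none)."""
        if self.rate_bounds is None:
            return 0.0
        k_lo, k_hi = self.rate_bounds
        v_lo, v_hi = self.v_range_mv[0] * 1e-3, self.v_range_mv[1] * 1e-3
        worst = 0.0
        for (ia, ib), sign in [(p, +1) for p in _RATE_UP] + [(p, -1) for p in _RATE_DOWN]:
            b = math.exp(phi[ib]) * sign
            k_max = phi[ia] + b * (v_hi if b > 0 else v_lo)
            worst = max(worst, k_max - math.log(k_hi), math.log(k_lo) - k_max)
        return max(worst, 0.0)


# ---------------------------------------------------------------------------
# Fast cached simulation on a fixed protocol grid
# ---------------------------------------------------------------------------

@dataclass
class SimulationCache:
    """Precomputed voltage arrays for repeated simulation of one protocol."""

    times: np.ndarray
    v_samp_mv: np.ndarray
    v_mid_volts: np.ndarray
    dt: float
    e_k: float
    mask: np.ndarray  # boolean fit mask on the sample grid

    @property
    def n_fit(self) -> int:
        return int(self.mask.sum())


def make_cache(
    protocol: VoltageProtocol,
    env: IonicEnvironment | None = None,
    fit_start: float | None = DEFAULT_FIT_START,
    v_offset: float = 0.0,
) -> SimulationCache:
    env = env or IonicEnvironment()
    times = protocol.times()
    dt = protocol.sampling_interval
    v_samp = protocol.voltages(times) + v_offset
    v_mid = (protocol.voltages(times[:-1] + 0.5 * dt) + v_offset) * 1e-3
    mask = np.ones(times.size, dtype=bool) if fit_start is None else times >= fit_start
    return SimulationCache(times, v_samp, v_mid, dt, nernst_potential(env), mask)


def simulate_cached(phi: np.ndarray, cache: SimulationCache) -> np.ndarray:
    """Model current (pA) on the cached grid for phi = ln(theta)."""
    th = np.exp(phi)
    k1 = th[1] * math.exp(th[2] * cache.v_samp_mv[0] * 1e-3)
    k2 = th[3] * math.exp(-th[4] * cache.v_samp_mv[0] * 1e-3)
    k3 = th[5] * math.exp(th[6] * cache.v_samp_mv[0] * 1e-3)
    k4 = th[7] * math.exp(-th[8] * cache.v_samp_mv[0] * 1e-3)
    a, r = _integrate_gates(
        cache.v_mid_volts, cache.dt,
        th[1], th[2], th[3], th[4], th[5], th[6], th[7], th[8],
        k1 / (k1 + k2), k4 / (k3 + k4),
    )
    return th[0] * a * r * (cache.v_samp_mv - cache.e_k) * 1e-3


# ---------------------------------------------------------------------------
# Likelihood / posterior
# ---------------------------------------------------------------------------

def _gaussian_loglik(resid: np.ndarray, sigma: float) -> float:
    n = resid.size
    return -0.5 * n * math.log(2.0 * math.pi * sigma * sigma) \
        - float(resid @ resid) / (2.0 * sigma * sigma)


def log_likelihood(
    phi,
    sigma: float,
    y: CurrentTrace,
    protocol: VoltageProtocol,
    env: IonicEnvironment | None = None,
    cache: SimulationCache | None = None,
) -> float:
    """Gaussian log-likelihood of the trace ``y`` under phi = ln(theta).

    A failed simulation returns -inf (the proposal is simply rejected by
    any sampler using it).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    phi = np.asarray(phi, dtype=float)
    if cache is None:
        cache = make_cache(protocol, env, fit_start=None)
        if y.times.shape != cache.times.shape or not np.allclose(y.times, cache.times):
            raise ValueError("trace grid does not match the protocol grid")
    try:
        z = simulate_cached(phi, cache)
    except (FloatingPointError, ValueError):
        return -math.inf
    if not np.all(np.isfinite(z)):
        return -math.inf
    resid = (z - y.currents)[cache.mask]
    return _gaussian_loglik(resid, sigma)


def log_posterior(
    phi,
    sigma: float,
    y: CurrentTrace,
    prior: PriorBox,
    protocol: VoltageProtocol,
    env: IonicEnvironment | None = None,
    cache: SimulationCache | None = None,
) -> float:
    """Log posterior up to a constant: -inf outside the (closed) prior box."""
    phi = np.asarray(phi, dtype=float)
    if not prior.contains(phi):
        return -math.inf
    if not (LN_SIGMA_BOUNDS[0] <= math.log(sigma) <= LN_SIGMA_BOUNDS[1]):
        return -math.inf
    return log_likelihood(phi, sigma, y, protocol, env, cache)


# ---------------------------------------------------------------------------
# CMA-ES-style evolution strategy (minimisation)
# ---------------------------------------------------------------------------

def _cma_es(f, x0, sigma0, rng, maxiter=700, popsize=None, tolfun=1e-12, tolx=1e-13):
    """Minimal covariance-matrix-adaptation evolution strategy.

    Returns ``(x_best, f_best, n_evals)``.  Standard rank-mu/rank-1 update
    with cumulative step-size adaptation.
    """
    n = len(x0)
    lam = popsize or (4 + int(3 * math.log(n)))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    ds = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

    m = np.array(x0, dtype=float)
    sigma = float(sigma0)
    C = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)
    x_best, f_best = m.copy(), math.inf
    n_evals = 0
    history = []

    for it in range(maxiter):
        vals, vecs = np.linalg.eigh(C)
        vals = np.maximum(vals, 1e-20)
        D = np.sqrt(vals)
        inv_sqrt_c = vecs @ np.diag(1.0 / D) @ vecs.T

        z = rng.standard_normal((lam, n))
        y = z @ np.diag(D) @ vecs.T
        xs = m + sigma * y
        fs = np.array([f(x) for x in xs])
        n_evals += lam
        order = np.argsort(fs)
        if fs[order[0]] < f_best:
            f_best = float(fs[order[0]])
            x_best = xs[order[0]].copy()
        history.append(f_best)

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        m = m + sigma * y_w
        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mueff) * (inv_sqrt_c @ y_w)
        h_sig = float(np.linalg.norm(ps)) / math.sqrt(1 - (1 - cs) ** (2 * (it + 1))) \
            < (1.4 + 2 / (n + 1)) * chi_n
        pc = (1 - cc) * pc + (math.sqrt(cc * (2 - cc) * mueff) * y_w if h_sig else 0.0)
        rank1 = np.outer(pc, pc)
        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (1 - c1 - cmu) * C + c1 * rank1 + cmu * rank_mu
        C = 0.5 * (C + C.T)
        sigma *= math.exp((cs / ds) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = min(sigma, 1e4)

        if len(history) > 80 and history[-80] - history[-1] < tolfun * max(1.0, abs(history[-1])):
            break
        if sigma * D.max() < tolx:
            break
    return x_best, f_best, n_evals


# B-type (exponential-slope) parameter indices: searched on a linear scale
_B_IDX = np.array([2, 4, 6, 8])


def _search_bounds(prior: PriorBox):
    """Bounds of the optimiser's search box: log scale for g and the
    A-type rate amplitudes, linear scale for the B-type slopes (the mix
    that makes the staircase SSE landscape most benign)."""
    lo, hi = prior.phi_min.copy(), prior.phi_max.copy()
    lo[_B_IDX] = np.exp(prior.phi_min[_B_IDX])
    hi[_B_IDX] = np.exp(prior.phi_max[_B_IDX])
    return lo, hi


def _unit_to_phi(u, lo, hi):
    x = lo + u * (hi - lo)
    phi = x.copy()
    phi[_B_IDX] = np.log(np.maximum(x[_B_IDX], 1e-300))
    return phi


def _phi_to_unit(phi, lo, hi):
    x = np.asarray(phi, dtype=float).copy()
    x[_B_IDX] = np.exp(x[_B_IDX])
    return (x - lo) / (hi - lo)


@dataclass
class FitResult:
    theta: KineticParameters
    sigma: float
    phi: np.ndarray
    score: float          # log-likelihood at the optimum (profiled sigma)
    sse: float
    n_evals: int
    restart_scores: list


def fit_map(
    y: CurrentTrace,
    protocol: VoltageProtocol,
    prior: PriorBox | None = None,
    n_restarts: int = 5,
    seed: int | None = None,
    env: IonicEnvironment | None = None,
    fit_start: float | None = DEFAULT_FIT_START,
    x0: np.ndarray | None = None,
    x0_spread: float = 0.2,
    sigma0: float = 0.3,
    maxiter: int = 1000,
    start_pool: int = 32,
    search_decimation: int = 4,
    polish: bool = True,
) -> FitResult:
    """Maximum-a-posteriori fit of phi with sigma profiled analytically.

    Each restart starts from a fresh draw from the prior (pre-screened:
    the best ``n_restarts`` of ``start_pool`` prior draws by residual) and
    runs the evolution strategy on the sum of squared residuals in a
    normalised search box (log scale for the amplitudes, linear for the
    exponential slopes); out-of-box proposals are evaluated at their box
    projection plus a smooth distance penalty.  The search stage runs on a
    ``search_decimation``-fold coarsened time grid (the exponential
    integrator stays exact on constant-voltage steps), after which the
    best restart is polished on the full grid with a bounded quasi-Newton
    step.  When ``x0`` is given, restarts are Gaussian perturbations of it
    instead (warm-started continuation).  Deterministic given ``seed``.
    """
    from scipy.optimize import minimize

    prior = prior or PriorBox.default()
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    cache = make_cache(protocol, env, fit_start=fit_start)
    if y.times.shape != cache.times.shape or not np.allclose(y.times, cache.times):
        raise ValueError("trace grid does not match the protocol grid")
    data_masked = y.currents[cache.mask]
    scale = float(data_masked @ data_masked) + 1.0

    dec = max(int(search_decimation), 1)
    coarse = protocol.with_sampling_interval(protocol.sampling_interval * dec)
    cache_s = make_cache(coarse, env, fit_start=fit_start)
    data_s = y.currents[::dec][cache_s.mask]
    scale_s = float(data_s @ data_s) + 1.0

    lo, hi = _search_bounds(prior)

    def sse(phi, c, d):
        z = simulate_cached(phi, c)
        if not np.all(np.isfinite(z)):
            return math.inf
        r = z[c.mask] - d
        return float(r @ r)

    def objective_u(u, c, d, sc):
        uc = np.clip(u, 0.0, 1.0)
        dist = float(np.sum((u - uc) ** 2))
        phi = _unit_to_phi(uc, lo, hi)
        pen = prior.rate_violation(phi)
        return sse(phi, c, d) + sc * (dist + pen)

    search_obj = lambda u: objective_u(u, cache_s, data_s, scale_s)

    results = []
    total_evals = 0
    if x0 is None:
        pool = prior.sample(rng, max(start_pool, n_restarts))
        pool_u = np.array([_phi_to_unit(p, lo, hi) for p in pool])
        pool_f = np.array([search_obj(u) for u in pool_u])
        total_evals += pool_u.shape[0]
        starts = pool_u[np.argsort(pool_f)[:n_restarts]]
        s0 = sigma0
    else:
        u0 = _phi_to_unit(np.asarray(x0, dtype=float), lo, hi)
        jitter = x0_spread / 20.0  # unit-box scale
        starts = np.clip(
            u0 + np.vstack([np.zeros(N_PARAMETERS),
                            rng.normal(0, jitter, (n_restarts - 1, N_PARAMETERS))]),
            0.0, 1.0,
        )
        s0 = max(jitter, 0.01)
    for k in range(n_restarts):
        ub, fb, ne = _cma_es(search_obj, starts[k], s0, rng, maxiter=maxiter)
        total_evals += ne
        results.append((fb, np.clip(ub, 0.0, 1.0)))
    results.sort(key=lambda t: t[0])
    if not math.isfinite(results[0][0]):
        raise OptimizationError("all restarts failed")

    # rank the restarts on the full grid and polish the best
    full_obj = lambda u: objective_u(u, cache, data_masked, scale)
    fulls = sorted((full_obj(u), u) for _, u in results)
    best_f, best_u = fulls[0]
    total_evals += len(fulls)
    if polish:
        res = minimize(
            full_obj, best_u, method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * N_PARAMETERS,
            options={"maxiter": 400, "ftol": 1e-16, "gtol": 1e-14},
        )
        total_evals += res.nfev * (N_PARAMETERS + 1)
        if res.fun <= best_f:
            best_u, best_f = np.clip(res.x, 0.0, 1.0), float(res.fun)

    phi_hat = np.clip(_unit_to_phi(best_u, lo, hi), prior.phi_min, prior.phi_max)
    final_sse = sse(phi_hat, cache, data_masked)
    sigma_hat = math.sqrt(max(final_sse, 1e-300) / cache.n_fit)
    ll = _gaussian_loglik(simulate_cached(phi_hat, cache)[cache.mask] - data_masked, sigma_hat)
    return FitResult(
        theta=KineticParameters.from_log(phi_hat),
        sigma=sigma_hat,
        phi=phi_hat,
        score=ll,
        sse=final_sse,
        n_evals=total_evals,
        restart_scores=[float(f) for f, _ in results],
    )


# ---------------------------------------------------------------------------
# Population MCMC with adaptive Metropolis base
# ---------------------------------------------------------------------------

def laplace_proposal_cov(
    phi_hat: np.ndarray,
    sigma_hat: float,
    cache: SimulationCache,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Gauss-Newton approximation of the posterior covariance at the MAP.

    Finite-difference Jacobian of the simulated current w.r.t. phi gives
    the Fisher information J^T J / sigma^2; the (phi, ln sigma) covariance
    is its inverse padded with the analytic 1/(2N) variance for ln sigma.
    Used to initialise the adaptive-Metropolis proposal so chains mix from
    the first iterations.
    """
    z0 = simulate_cached(phi_hat, cache)[cache.mask]
    n = z0.size
    jac = np.empty((n, N_PARAMETERS))
    for i in range(N_PARAMETERS):
        step = rel_step * max(abs(phi_hat[i]), 1e-3)
        phi_p = phi_hat.copy()
        phi_p[i] += step
        jac[:, i] = (simulate_cached(phi_p, cache)[cache.mask] - z0) / step
    info = jac.T @ jac / sigma_hat**2
    # regularise: the staircase leaves no direction totally flat, but guard
    info += np.eye(N_PARAMETERS) * 1e-12 * np.trace(info) / N_PARAMETERS
    cov_phi = np.linalg.inv(info)
    cov = np.zeros((N_PARAMETERS + 1, N_PARAMETERS + 1))
    cov[:N_PARAMETERS, :N_PARAMETERS] = 0.5 * (cov_phi + cov_phi.T)
    cov[-1, -1] = 1.0 / (2.0 * n)
    return cov


@dataclass(frozen=True)
class ChainConfig:
    """Sampler settings.  The defaults are sized for desk scale and every
    field is adjustable; ``betas`` overrides the geometric temperature
    ladder (must include 1.0)."""

    n_chains: int = 3
    n_iter: int = 20000
    burn_in: float = 0.5
    n_rungs: int = 5
    thin: int = 1
    betas: tuple | None = None
    adapt_decay: float = 0.6
    target_accept: float = 0.234
    init_step: float = 1e-3      # initial proposal SD per dimension
    start_jitter: float = 1e-3   # SD of the replicate-start perturbations
    adapt_start: int = 500       # iterations before covariance adaptation kicks in

    def ladder(self) -> np.ndarray:
        if self.betas is not None:
            b = np.asarray(self.betas, dtype=float)
        else:
            b = 0.5 ** np.arange(self.n_rungs)
        if b[0] != 1.0:
            raise ValueError("temperature ladder must start at beta = 1")
        return b


@dataclass
class PosteriorChain:
    """Cold-chain samples over (phi, ln sigma) from every replicate.

    ``samples_by_chain`` has shape (n_chains, n_kept, 10); the convenience
    properties pool the post-burn-in portion.
    """

    samples_by_chain: np.ndarray
    config: ChainConfig
    seed: int | None
    acceptance: np.ndarray
    swap_acceptance: float

    def _post_burn(self) -> np.ndarray:
        n_kept = self.samples_by_chain.shape[1]
        start = int(self.config.burn_in * n_kept)
        return self.samples_by_chain[:, start:, :]

    @property
    def samples(self) -> np.ndarray:
        s = self._post_burn()
        return s.reshape(-1, s.shape[-1])

    @property
    def phi_samples(self) -> np.ndarray:
        return self.samples[:, :N_PARAMETERS]

    @property
    def theta_samples(self) -> np.ndarray:
        return np.exp(self.phi_samples)

    @property
    def sigma_samples(self) -> np.ndarray:
        return np.exp(self.samples[:, -1])

    @property
    def rhat(self) -> np.ndarray:
        return rhat(self._post_burn())

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """(2, 10) array of lower/upper pooled quantiles on (phi, ln sigma)."""
        a = (1.0 - level) / 2.0
        return np.quantile(self.samples, [a, 1.0 - a], axis=0)


def rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per dimension; ``chains`` is (n_chains, n_iter, d)."""
    m, n, d = chains.shape
    half = n // 2
    split = chains[:, : 2 * half, :].reshape(2 * m, half, d)
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = half * means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * w + b / half
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / w)
    return np.where(w > 0, out, 1.0)


def sample_posterior(
    y: CurrentTrace | None,
    protocol: VoltageProtocol | None,
    prior: PriorBox,
    start,
    chain_config: ChainConfig | None = None,
    seed: int | None = None,
    env: IonicEnvironment | None = None,
    fit_start: float | None = DEFAULT_FIT_START,
    target: str = "posterior",
) -> PosteriorChain:
    """Population MCMC over (phi, ln sigma).

    ``start`` is a :class:`FitResult` or a ``(phi, sigma)`` pair; replicate
    chains start from small jitters of it.  ``target="prior"`` switches the
    likelihood off (every rung then samples the prior; used to verify
    sampler correctness), in which case ``y`` and ``protocol`` may be None.

    Raises if the starting point has non-finite posterior density.
    """
    cfg = chain_config or ChainConfig()
    betas = cfg.ladder()
    rng = np.random.default_rng(seed)

    if isinstance(start, FitResult):
        x0 = np.concatenate([start.phi, [math.log(start.sigma)]])
    else:
        phi0, sigma0 = start
        x0 = np.concatenate([np.asarray(phi0, dtype=float), [math.log(sigma0)]])
    d = x0.size

    prop_cov0 = None
    if target == "prior":
        def loglik(x):
            return 0.0
    elif target == "posterior":
        cache = make_cache(protocol, env, fit_start=fit_start)
        data = y.currents[cache.mask]

        def loglik(x):
            z = simulate_cached(x[:N_PARAMETERS], cache)
            if not np.all(np.isfinite(z)):
                return -math.inf
            sigma = math.exp(x[-1])
            return _gaussian_loglik(z[cache.mask] - data, sigma)
    else:
        raise ValueError("target must be 'posterior' or 'prior'")

    def in_support(x):
        if not (LN_SIGMA_BOUNDS[0] <= x[-1] <= LN_SIGMA_BOUNDS[1]):
            return False
        return prior.contains(x[:N_PARAMETERS])

    if not in_support(x0):
        x0 = np.concatenate([
            np.clip(x0[:N_PARAMETERS], prior.phi_min, prior.phi_max),
            [np.clip(x0[-1], *LN_SIGMA_BOUNDS)],
        ])
    if not in_support(x0):
        raise ValueError("starting point lies outside the prior support")
    l0 = loglik(x0)
    if not math.isfinite(l0):
        raise ValueError("starting point has non-finite likelihood")

    if target == "posterior":
        try:
            prop_cov0 = laplace_proposal_cov(x0[:N_PARAMETERS], math.exp(x0[-1]), cache)
        except np.linalg.LinAlgError:
            prop_cov0 = None
    jitter_sd = (
        2.0 * np.sqrt(np.diag(prop_cov0)) if prop_cov0 is not None
        else np.full(d, cfg.start_jitter)
    )

    n_kept = cfg.n_iter // cfg.thin
    all_samples = np.empty((cfg.n_chains, n_kept, d))
    accept_counts = np.zeros(cfg.n_chains)
    swap_tries = swap_accepts = 0

    for c in range(cfg.n_chains):
        n_rungs = betas.size
        xs = np.tile(x0, (n_rungs, 1)) + jitter_sd * rng.standard_normal((n_rungs, d))
        lls = np.empty(n_rungs)
        for i in range(n_rungs):
            if not in_support(xs[i]):
                xs[i] = x0
            lls[i] = loglik(xs[i])
            if not math.isfinite(lls[i]):
                xs[i], lls[i] = x0, l0
        # adaptive-Metropolis state per rung
        means = xs.copy()
        if prop_cov0 is not None:
            # hotter rungs target flatter distributions: widen accordingly
            covs = np.stack([prop_cov0 / b for b in betas])
        else:
            covs = np.tile(np.eye(d) * cfg.init_step**2, (n_rungs, 1, 1))
        log_scales = np.zeros(n_rungs)
        kept = 0
        for t in range(cfg.n_iter):
            gamma = (t + 1) ** (-cfg.adapt_decay)
            for i in range(n_rungs):
                cov = covs[i] * math.exp(log_scales[i]) * (2.38**2 / d)
                try:
                    prop = rng.multivariate_normal(xs[i], cov, method="cholesky")
                except np.linalg.LinAlgError:
                    covs[i] += 1e-12 * np.eye(d)
                    prop = rng.multivariate_normal(xs[i], covs[i])
                accepted = False
                if in_support(prop):
                    lp = loglik(prop)
                    if math.isfinite(lp) and math.log(rng.uniform()) < betas[i] * (lp - lls[i]):
                        xs[i], lls[i] = prop, lp
                        accepted = True
                if i == 0 and accepted:
                    accept_counts[c] += 1
                # vanishing adaptation: global scale from the start, the
                # covariance only once the chain has begun exploring
                # (adapting it from a barely-moved chain collapses the
                # proposal and stalls mixing)
                delta = xs[i] - means[i]
                means[i] += gamma * delta
                if t >= cfg.adapt_start:
                    g2 = (t - cfg.adapt_start + 1) ** (-cfg.adapt_decay)
                    covs[i] += g2 * (np.outer(delta, delta) - covs[i])
                log_scales[i] += gamma * ((1.0 if accepted else 0.0) - cfg.target_accept)
            if n_rungs > 1:
                j = rng.integers(n_rungs - 1)
                swap_tries += 1
                log_alpha = (betas[j] - betas[j + 1]) * (lls[j + 1] - lls[j])
                if math.log(rng.uniform()) < log_alpha:
                    xs[[j, j + 1]] = xs[[j + 1, j]]
                    lls[[j, j + 1]] = lls[[j + 1, j]]
                    swap_accepts += 1
            if (t + 1) % cfg.thin == 0 and kept < n_kept:
                all_samples[c, kept] = xs[0]
                kept += 1

    return PosteriorChain(
        samples_by_chain=all_samples,
        config=cfg,
        seed=seed,
        acceptance=accept_counts / cfg.n_iter,
        swap_acceptance=swap_accepts / max(swap_tries, 1),
    )
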