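"""Bayesian Baum-Welch (MAP-EM) training for AR(P)-HMM(L) models.

Priors: Dirichlet pseudocounts on the initial distribution and on every
transition row; a Gaussian-Inverted-Gamma (NIG) prior per state on the basic
mean and variance, ``N(mu | m, sigma^2/kappa) * InvGamma(sigma^2 | a, b)``;
the autoregressive coefficients carry a flat prior.  Each M-step maximises
Baum's auxiliary function plus the log prior: transition rows get the
Dirichlet-MAP update, and the basic mean together with the AR coefficients
solve a posterior-weighted system of normal equations.

With all priors flat the procedure reduces exactly to maximum-likelihood
Baum-Welch (and, at orders P = L = 0, to Gaussian-mixture EM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import (
    _iter_profiles,
    _profile_obs,
    forward_backward_batch,
    group_by_length,
)
from .model import SIGMA_FLOOR, AREmissionModel, ARHMM, StateSpace, TransitionModel

logger = logging.getLogger(__name__)

# initialization defaults: mostly-unchanged genes, clearly separated
# differential states on the log2 scale, moderate state persistence
DEFAULT_PI_INIT = (0.9, 0.05, 0.05)
DEFAULT_MU_INIT = (0.0, -2.0, 2.0)
DEFAULT_SIGMA_INIT = (0.5, 1.0, 1.0)
DEFAULT_RHO = 0.1


@dataclass
class PriorSpec:
    """Hyperparameters of the factorised prior over model parameters.

    ``dirichlet_pi``: (N,) pseudocounts >= 1; ``dirichlet_A``: per order d a
    (N**d, N) pseudocount matrix >= 1.  Per state: NIG hyperparameters
    ``m`` (prior mean), ``kappa`` (mean strength, 0 = flat mean prior),
    ``a``/``b`` (inverse-gamma shape/scale).  ``a = -1, b = 0, kappa = 0``
    is the flat (maximum-likelihood) limit and contributes 0 to the log
    posterior.
    """

    dirichlet_pi: np.ndarray
    dirichlet_A: list[np.ndarray]
    m: np.ndarray
    kappa: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        if np.any(self.dirichlet_pi < 1):
            raise ValueError("Dirichlet pseudocounts must be >= 1")
        for mat in self.dirichlet_A:
            if np.any(np.asarray(mat) < 1):
                raise ValueError("Dirichlet pseudocounts must be >= 1")
        if np.any(self.kappa < 0):
            raise ValueError("kappa must be >= 0")

    @classmethod
    def flat(cls, N: int, L: int) -> "PriorSpec":
        """Flat prior everywhere: MAP training equals maximum likelihood."""
        return cls(
            dirichlet_pi=np.ones(N),
            dirichlet_A=[np.ones((N**d, N)) for d in range(1, L + 1)],
            m=np.zeros(N),
            kappa=np.zeros(N),
            a=np.full(N, -1.0),
            b=np.zeros(N),
        )


@dataclass
class TrainingConfig:
    stop_epsilon: float = 1e-4
    patience: int = 2
    max_iterations: int = 500
    seed: int = 0
    sigma_floor: float = SIGMA_FLOOR

    def __post_init__(self):
        if self.stop_epsilon <= 0:
            raise ValueError("stop_epsilon must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class ExpectedCounts:
    """Sufficient statistics accumulated by the E-step.

    ``gram``/``moment`` are built from the regressor vector
    ``x_t = (1, o_{t-1}, ..., o_{t-P})`` with start-truncated entries set to
    zero; ``sum_sq`` is the gamma-weighted sum of squared observations.
    """

    pi_counts: np.ndarray  # (N,)
    xi: list[np.ndarray]  # per order d: (N**d, N)
    weight: np.ndarray  # (N,)  W_s = sum of gamma
    gram: np.ndarray  # (N, P+1, P+1)
    moment: np.ndarray  # (N, P+1)
    sum_sq: np.ndarray  # (N,)
    loglik: float = 0.0
    n_observations: int = 0


def init_model(
    N: int = 3,
    L: int = 1,
    P: int = 0,
    pi_init=DEFAULT_PI_INIT,
    rho: float = DEFAULT_RHO,
    mu_init=DEFAULT_MU_INIT,
    sigma_init=DEFAULT_SIGMA_INIT,
    states: tuple[str, ...] | None = None,
) -> ARHMM:
    """Initial model whose first-order matrix is stationary for ``pi_init``.

    The matrix M with off-diagonal ``M_ij = rho * pi_j`` and diagonal
    ``M_ii = 1 - rho * (1 - pi_i)`` satisfies ``pi M = pi``; ``rho`` in
    (0, 1] scales expected state durations (smaller = longer segments).
    Every higher-order context row copies the row of its most recent state,
    and all autoregressive coefficients start at zero.
    """
    pi = np.asarray(pi_init, dtype=float)
    if len(pi) != N:
        raise ValueError("pi_init length must equal N")
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    M = rho * np.tile(pi, (N, 1))
    np.fill_diagonal(M, 1.0 - rho * (1.0 - pi))
    if np.any(np.diag(M) < 0):
        raise ValueError("negative diagonal in initial transition matrix; reduce rho")
    A = []
    for d in range(1, L + 1):
        rows = np.empty((N**d, N))
        for code in range(N**d):
            rows[code] = M[code % N]  # most recent state is the lowest digit
        A.append(rows)
    space = StateSpace(states) if states is not None else StateSpace(("=", "-", "+")[:N] if N <= 3 else tuple(f"s{i}" for i in range(N)))
    return ARHMM(
        states=space,
        transitions=TransitionModel(pi=pi.copy(), A=A),
        emissions=AREmissionModel(
            mu=np.asarray(mu_init, dtype=float)[:N].copy(),
            sigma=np.asarray(sigma_init, dtype=float)[:N].copy(),
            coef=np.zeros((N, P)),
        ),
    )


def default_prior(
    model_init: ARHMM,
    kappa_pi: float = 10.0,
    kappa_A: float = 10.0,
    kappa_s: float = 1.0,
    a_s: float = 2.0,
) -> PriorSpec:
    """Prior whose mode is the initial model (zero-data MAP fixed point).

    Dirichlet pseudocounts are ``1 + strength * initial probability``; the
    NIG scale ``b`` is set so the joint prior mode of sigma^2 equals the
    initial variance (``b = sigma_init^2 * (a + 1.5)`` when kappa > 0).
    """
    if min(kappa_pi, kappa_A, kappa_s) < 0 or a_s <= 0:
        raise ValueError("prior strengths must be nonnegative, a_s positive")
    tr, em = model_init.transitions, model_init.emissions
    N = model_init.n_states
    extra = 1.5 if kappa_s > 0 else 1.0
    return PriorSpec(
        dirichlet_pi=1.0 + kappa_pi * tr.pi,
        dirichlet_A=[1.0 + kappa_A * mat for mat in tr.A],
        m=em.mu.copy(),
        kappa=np.full(N, float(kappa_s)),
        a=np.full(N, float(a_s)),
        b=em.sigma**2 * (a_s + extra),
    )


def e_step(profiles, model: ARHMM) -> ExpectedCounts:
    """Expected counts across all profiles (batched by sequence length)."""
    seqs = [_profile_obs(p) for p in _iter_profiles(profiles)]
    if not seqs:
        raise ValueError("no profiles")
    N = model.n_states
    L, P = model.order_L, model.order_P
    counts = ExpectedCounts(
        pi_counts=np.zeros(N),
        xi=[np.zeros((N**d, N)) for d in range(1, L + 1)],
        weight=np.zeros(N),
        gram=np.zeros((N, P + 1, P + 1)),
        moment=np.zeros((N, P + 1)),
        sum_sq=np.zeros(N),
    )
    for obs in group_by_length(seqs):
        res = forward_backward_batch(obs, model, want_counts=True)
        gamma = res["gamma"]  # (B, T, N)
        counts.loglik += float(res["loglik"].sum())
        counts.pi_counts += res["pi_counts"]
        for d in range(L):
            counts.xi[d] += res["xi"][d]
        B, T = obs.shape
        X = np.zeros((B, T, P + 1))
        X[:, :, 0] = 1.0
        for j in range(1, P + 1):
            X[:, j:, j] = obs[:, :-j]
        counts.weight += gamma.sum(axis=(0, 1))
        counts.gram += np.einsum("btn,bti,btj->nij", gamma, X, X)
        counts.moment += np.einsum("btn,bti,bt->ni", gamma, X, obs)
        counts.sum_sq += np.einsum("btn,bt->n", gamma, obs**2)
        counts.n_observations += B * T
    return counts


def _map_row(counts_row: np.ndarray, eta_row: np.ndarray) -> np.ndarray:
    num = counts_row + eta_row - 1.0
    if np.any(num < 0):
        raise ValueError("MAP numerator negative; pseudocounts must be >= 1")
    denom = num.sum()
    if denom <= 0:  # no data and flat prior: fall back to the uniform row
        return np.full(len(eta_row), 1.0 / len(eta_row))
    return num / denom


def m_step_transitions(counts: ExpectedCounts, prior: PriorSpec):
    """Dirichlet-MAP update of pi and every transition row."""
    pi = _map_row(counts.pi_counts, prior.dirichlet_pi)
    A = []
    for d, xi_d in enumerate(counts.xi):
        eta = prior.dirichlet_A[d]
        A.append(np.vstack([_map_row(xi_d[r], eta[r]) for r in range(xi_d.shape[0])]))
    return pi, A


def m_step_emissions(counts: ExpectedCounts, prior: PriorSpec, sigma_floor: float = SIGMA_FLOOR):
    """Posterior-weighted normal equations per state, then the variance update.

    The NIG prior adds ``kappa`` to the Gram diagonal entry of the basic
    mean and ``kappa * m`` to its right-hand side; the flat prior yields
    pure weighted least squares.  Singular systems fall back to the
    least-norm solution.
    """
    N, Pp1 = counts.moment.shape
    mu = np.empty(N)
    coef = np.empty((N, Pp1 - 1))
    sigma = np.empty(N)
    for s in range(N):
        kappa, m_s, a_s, b_s = (
            float(prior.kappa[s]),
            float(prior.m[s]),
            float(prior.a[s]),
            float(prior.b[s]),
        )
        W = float(counts.weight[s])
        denom = W + 2.0 * (a_s + 1.0) + (1.0 if kappa > 0 else 0.0)
        if W + kappa <= 0 or denom <= 0:
            logger.warning("state %d carries no posterior mass and no prior; skipped", s)
            mu[s], coef[s], sigma[s] = np.nan, np.nan, np.nan
            continue
        G = counts.gram[s].copy()
        v = counts.moment[s].copy()
        G[0, 0] += kappa
        v[0] += kappa * m_s
        try:
            beta = np.linalg.solve(G, v)
        except np.linalg.LinAlgError:
            logger.warning("singular normal equations for state %d; least-norm solution", s)
            beta = np.linalg.lstsq(G, v, rcond=None)[0]
        mu[s] = beta[0]
        coef[s] = beta[1:]
        resid = (
            counts.sum_sq[s]
            - 2.0 * beta @ counts.moment[s]
            + beta @ counts.gram[s] @ beta
        )
        var = (max(resid, 0.0) + 2.0 * b_s + kappa * (mu[s] - m_s) ** 2) / denom
        sigma[s] = max(np.sqrt(var), sigma_floor)
    return mu, coef, sigma


def log_prior(model: ARHMM, prior: PriorSpec) -> float:
    """Log prior density up to additive constants; flat priors contribute 0.

    Returns -inf outside the prior support (zero probability where a
    pseudocount exceeds 1, or nonpositive variance).
    """
    tr, em = model.transitions, model.emissions
    total = 0.0

    def dir_term(p, eta):
        w = eta - 1.0
        if np.any((w > 0) & (p <= 0)):
            return -np.inf
        active = w > 0
        return float(np.sum(w[active] * np.log(p[active])))

    total += dir_term(tr.pi, prior.dirichlet_pi)
    for d, mat in enumerate(tr.A):
        for r in range(mat.shape[0]):
            total += dir_term(mat[r], prior.dirichlet_A[d][r])
    for s in range(model.n_states):
        var = float(em.sigma[s]) ** 2
        if var <= 0:
            return -np.inf
        a_s, b_s, kappa = float(prior.a[s]), float(prior.b[s]), float(prior.kappa[s])
        total += -(a_s + 1.0) * np.log(var) - b_s / var
        if kappa > 0:
            total += -0.5 * np.log(var / kappa) - kappa * (em.mu[s] - prior.m[s]) ** 2 / (
                2.0 * var
            )
    return float(total)


def log_posterior(profiles, model: ARHMM, prior: PriorSpec) -> float:
    from .inference import loglikelihood

    return loglikelihood(profiles, model) + log_prior(model, prior)


@dataclass
class FitResult:
    model: ARHMM
    trace: list[dict] = field(default_factory=list)
    converged: bool = False

    @property
    def log_posteriors(self) -> np.ndarray:
        return np.array([row["logposterior"] for row in self.trace])


def map_update(counts: ExpectedCounts, model: ARHMM, prior: PriorSpec, sigma_floor=SIGMA_FLOOR) -> ARHMM:
    """One M-step: build the new model from expected counts and the prior."""
    pi, A = m_step_transitions(counts, prior)
    mu, coef, sigma = m_step_emissions(counts, prior, sigma_floor)
    old = model.emissions
    mu = np.where(np.isnan(mu), old.mu, mu)
    sigma = np.where(np.isnan(sigma), old.sigma, sigma)
    coef = np.where(np.isnan(coef), old.coef, coef)
    return ARHMM(
        states=model.states,
        transitions=TransitionModel(pi=pi, A=A),
        emissions=AREmissionModel(mu=mu, sigma=sigma, coef=coef),
    )


def fit(profiles, model_init: ARHMM, prior: PriorSpec, config: TrainingConfig | None = None) -> FitResult:
    """MAP-EM: alternate E-step and M-steps until the log-posterior stalls.

    Stops when the log-posterior increase stays below ``stop_epsilon`` for
    ``patience`` consecutive iterations (default two), or at
    ``max_iterations``.  A decrease beyond 1e-8 raises, since exact EM
    guarantees ascent.
    """
    config = config or TrainingConfig()
    model = model_init
    trace: list[dict] = []
    prev = -np.inf
    stall = 0
    converged = False
    for it in range(config.max_iterations):
        counts = e_step(profiles, model)
        lp = log_prior(model, prior)
        logpost = counts.loglik + lp
        trace.append(
            {"iteration": it, "loglik": counts.loglik, "logprior": lp, "logposterior": logpost}
        )
        if logpost < prev - 1e-8:
            raise RuntimeError(
                f"log-posterior decreased at iteration {it}: {prev:.10g} -> {logpost:.10g}"
            )
        if np.isfinite(prev) and logpost - prev < config.stop_epsilon:
            stall += 1
            if stall >= config.patience:
                converged = True
                break
        else:
            stall = 0
        prev = logpost
        model = map_update(counts, model, prior, config.sigma_floor)
    return FitResult(model=model, trace=trace, converged=converged)
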