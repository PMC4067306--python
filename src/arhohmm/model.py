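"""Parameter containers and emission mathematics for AR(P)-HMM(L) models.

An AR(P)-HMM(L) is a hidden Markov model whose state-transition process has
Markov order ``L`` (the distribution of the next hidden state depends on the
previous ``L`` states) and whose Gaussian emissions are autoregressive of
order ``P``: in state ``s`` the mean of observation ``o_t`` is shifted by a
linear combination of the ``P`` preceding *observed* values,

    mean_s(t) = mu_s + sum_{j=1..P} h(t, j) * c_{s,j} * o_{t-j},

where ``h(t, j)`` truncates terms that would reach before the start of the
sequence (``h(t, j) = 0`` if ``t - j < 1``, else 1; positions are 1-based in
formulas, 0-based in storage).

Special cases obtained purely by the orders: ``AR(0)-HMM(0)`` is a Gaussian
mixture model, ``AR(0)-HMM(1)`` a standard first-order HMM, ``AR(P)-HMM(0)``
an autoregressive mixture, ``AR(0)-HMM(L)`` a higher-order HMM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_STATES = ("=", "-", "+")

#: lower bound for emission standard deviations (log-ratio scale); prevents
#: variance collapse on constant segments
SIGMA_FLOOR = 1e-3


def context_index(context: tuple[int, ...], n_states: int) -> int:
    """Row index of a state context ``(q_{t-d}, ..., q_{t-1})``.

    The most recent state occupies the lowest digit of a base-N code:
    ``index = q_{t-1} + q_{t-2}*N + ... + q_{t-d}*N^(d-1)``.
    """
    code = 0
    for q in context:
        code = code * n_states + int(q)
    return code


def context_tuple(code: int, d: int, n_states: int) -> tuple[int, ...]:
    """Inverse of :func:`context_index` for a length-``d`` context."""
    out = []
    for _ in range(d):
        out.append(code % n_states)
        code //= n_states
    return tuple(reversed(out))


@dataclass(frozen=True)
class StateSpace:
    """Ordered hidden-state labels; index 0 is the 'unchanged' state."""

    states: tuple[str, ...] = DEFAULT_STATES

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValueError("need at least two states")
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        return self.states.index(label)


@dataclass
class TransitionModel:
    """Initial distribution pi and order-``L`` transition matrices.

    ``A[d-1]`` is the order-``d`` matrix with ``N**d`` context rows and ``N``
    columns, for ``d = 1..L``.  With ``L = 0`` the list is empty and ``pi``
    is reused at every position (mixture model).
    """

    pi: np.ndarray
    A: list[np.ndarray] = field(default_factory=list)

    @property
    def order(self) -> int:
        return len(self.A)

    @property
    def n(self) -> int:
        return len(self.pi)

    def matrix_for_step(self, t: int) -> np.ndarray:
        """Matrix used for the transition into 0-based position ``t`` (t >= 1).

        Ramp-up: positions ``2..L`` (1-based) use the lower-order matrix of
        their partial context; beyond that the full-order matrix applies.
        """
        d = min(t, self.order)
        return self.A[d - 1]


@dataclass
class AREmissionModel:
    """State-specific autoregressive Gaussian emissions of order ``P``.

    ``mu``: basic state means; ``sigma``: state standard deviations;
    ``coef``: (N, P) autoregressive coefficients c_{s,j}.
    """

    mu: np.ndarray
    sigma: np.ndarray
    coef: np.ndarray  # shape (N, P)

    @property
    def order(self) -> int:
        return self.coef.shape[1]

    @property
    def n(self) -> int:
        return len(self.mu)


@dataclass
class ARHMM:
    states: StateSpace
    transitions: TransitionModel
    emissions: AREmissionModel

    @property
    def n_states(self) -> int:
        return self.states.n

    @property
    def order_L(self) -> int:
        return self.transitions.order

    @property
    def order_P(self) -> int:
        return self.emissions.order


def ar_mean(model: ARHMM, state: int, t: int, history) -> float:
    """Autoregressive mean of ``state`` at 1-based position ``t``.

    ``history`` is the observed sequence ``o_1 .. o_{t-1}``.  Terms reaching
    before position 1 are truncated (h(t, j) = 0 for t - j < 1).
    """
    if t < 1 or len(history) != t - 1:
        raise ValueError("history must contain exactly the t-1 preceding observations")
    em = model.emissions
    m = float(em.mu[state])
    for j in range(1, em.order + 1):
        if t - j >= 1:
            m += float(em.coef[state, j - 1]) * float(history[t - 1 - j])
    return m


def emission_logdensity(model: ARHMM, state: int, t: int, o_t: float, history) -> float:
    """Gaussian log-density of ``o_t`` under the state's autoregressive mean."""
    s = float(model.emissions.sigma[state])
    if s <= 0:
        raise ValueError("sigma must be positive")
    m = ar_mean(model, state, t, history)
    return -0.5 * math.log(2.0 * math.pi * s * s) - 0.5 * ((o_t - m) / s) ** 2


def expand_to_first_order(model: ARHMM) -> tuple[np.ndarray, np.ndarray]:
    """First-order representation of the order-``L`` transition process.

    Returns ``(pi_exp, A_exp)`` over the ``N**L`` length-L context tuples
    (coded by :func:`context_index`).  ``pi_exp`` is the law of the first
    ``L`` hidden states under pi and the ramp-up matrices; ``A_exp`` moves a
    context ``(q_{t-L+1..t})`` to ``(q_{t-L+2..t+1})`` with the full-order
    probability, and is zero for moves whose tuples do not overlap.
    """
    L = model.order_L
    if L == 0:
        raise ValueError("no expansion defined for order 0; use the mixture path")
    N = model.n_states
    tr = model.transitions
    K = N**L

    # law of (q_1, ..., q_L): pi then ramp-up matrices A^(1..L-1)
    probs = {(): 1.0}
    for t in range(L):
        nxt: dict[tuple[int, ...], float] = {}
        for ctx, p in probs.items():
            if t == 0:
                step = tr.pi
            else:
                step = tr.A[t - 1][context_index(ctx, N)]
            for j in range(N):
                nxt[ctx + (j,)] = nxt.get(ctx + (j,), 0.0) + p * float(step[j])
        probs = nxt
    pi_exp = np.zeros(K)
    for ctx, p in probs.items():
        pi_exp[context_index(ctx, N)] = p

    A_exp = np.zeros((K, K))
    AL = tr.A[L - 1]
    for code in range(K):
        suffix = code % (N ** (L - 1)) if L > 1 else 0
        for j in range(N):
            A_exp[code, suffix * N + j] = AL[code, j]
    return pi_exp, A_exp


def validate(model: ARHMM, atol: float = 1e-9) -> list[str]:
    """Check all structural invariants; returns a list of violation messages."""
    issues: list[str] = []
    N = model.n_states
    tr, em = model.transitions, model.emissions
    if tr.n != N or em.n != N:
        issues.append("state counts of transitions/emissions disagree with state space")
        return issues
    if np.any(tr.pi < -atol):
        issues.append("pi has negative entries")
    if abs(tr.pi.sum() - 1.0) > atol:
        issues.append(f"pi sums to {tr.pi.sum():.12g}, expected 1")
    for d, mat in enumerate(tr.A, start=1):
        if mat.shape != (N**d, N):
            issues.append(f"A^({d}) has shape {mat.shape}, expected {(N ** d, N)}")
            continue
        if np.any(mat < -atol):
            issues.append(f"A^({d}) has negative entries")
        bad = np.nonzero(np.abs(mat.sum(axis=1) - 1.0) > atol)[0]
        for row in bad:
            issues.append(f"A^({d}) row {int(row)} sums to {mat[row].sum():.12g}")
    if np.any(em.sigma <= 0):
        issues.append("sigma must be strictly positive for every state")
    elif np.any(em.sigma < SIGMA_FLOOR):
        issues.append(f"sigma below floor {SIGMA_FLOOR}")
    if em.coef.shape != (N, em.order):
        issues.append("coefficient matrix shape inconsistent")
    if not np.all(np.isfinite(em.mu)) or not np.all(np.isfinite(em.coef)):
        issues.append("non-finite emission parameters")
    return issues


def to_dict(model: ARHMM) -> dict:
    tr, em = model.transitions, model.emissions
    return {
        "states": list(model.states.states),
        "L": tr.order,
        "P": em.order,
        "pi": [float(x) for x in tr.pi],
        "A": [[[float(x) for x in row] for row in mat] for mat in tr.A],
        "mu": [float(x) for x in em.mu],
        "sigma": [float(x) for x in em.sigma],
        "coef": [[float(x) for x in row] for row in em.coef],
    }


def from_dict(d: dict) -> ARHMM:
    states = StateSpace(tuple(d["states"]))
    N = states.n
    tr = TransitionModel(
        pi=np.asarray(d["pi"], dtype=float),
        A=[np.asarray(m, dtype=float).reshape(N ** (i + 1), N) for i, m in enumerate(d["A"])],
    )
    P = int(d["P"])
    em = AREmissionModel(
        mu=np.asarray(d["mu"], dtype=float),
        sigma=np.asarray(d["sigma"], dtype=float),
        coef=np.asarray(d["coef"], dtype=float).reshape(N, P),
    )
    m = ARHMM(states, tr, em)
    if tr.order != int(d["L"]):
        raise ValueError("stored order L disagrees with matrix list")
    return m


def save(model: ARHMM, path) -> None:
    """Serialize to a YAML file; floats round-trip losslessly (repr precision)."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(model), fh, sort_keys=False)


def load(path) -> ARHMM:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))
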