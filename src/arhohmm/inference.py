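"""Scaled forward-backward, posteriors and posterior decoding for AR(P)-HMM(L).

The order-``L`` recursion runs over state *contexts* (tuples of the most
recent hidden states, coded base-N with the newest state in the lowest
digit).  During the ramp-up phase the context grows from length 1 to ``L``
and the lower-order transition matrices apply; afterwards the full-order
matrix moves a length-``L`` context to its successor.  Because the
autoregressive conditioning is on *observations* (always fully known), the
emission term depends only on the current state and the observed history.

All recursions are vectorised over batches of equal-length sequences, which
keeps Baum-Welch training on hundreds of profiles fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ARHMM


@dataclass
class PosteriorMatrix:
    """Per-position state posteriors gamma_t(s) for one profile."""

    gamma: np.ndarray  # (T, N)
    loglik: float
    scales: np.ndarray  # (T,) positive; loglik == sum(log(scales))
    states: tuple[str, ...]


def emission_log_matrix(obs: np.ndarray, model: ARHMM) -> np.ndarray:
    """Log emission densities, shape (B, T, N), for a batch of sequences.

    Autoregressive means use the observed history with start-of-sequence
    truncation (terms reaching before position 1 are dropped).
    """
    em = model.emissions
    B, T = obs.shape
    mean = np.broadcast_to(em.mu, (B, T, em.n)).copy()
    for j in range(1, em.order + 1):
        shifted = np.zeros_like(obs)
        shifted[:, j:] = obs[:, :-j]
        mean += shifted[:, :, None] * em.coef[None, None, :, j - 1]
    sig = em.sigma[None, None, :]
    z = (obs[:, :, None] - mean) / sig
    return -0.5 * np.log(2.0 * np.pi * sig**2) - 0.5 * z**2


def _tile_emission(b_t: np.ndarray, K: int, N: int) -> np.ndarray:
    """Broadcast per-state emissions (B, N) onto K contexts (last digit = state)."""
    if K == N:
        return b_t
    return np.tile(b_t, (1, K // N))


def forward_backward_batch(obs: np.ndarray, model: ARHMM, want_counts: bool = False):
    """Scaled forward-backward on a batch of equal-length sequences.

    Returns a dict with ``gamma`` (B, T, N) state posteriors, ``loglik``
    (B,), ``scales`` (B, T), and — with ``want_counts`` — ``pi_counts``
    (N,) and ``xi`` (one (N**d, N) expected-transition matrix per order
    d = 1..L, summed over the batch).
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    B, T = obs.shape
    if T < 1:
        raise ValueError("empty sequence")
    N = model.n_states
    L = model.order_L
    tr = model.transitions

    logb = emission_log_matrix(obs, model)
    if not np.all(np.isfinite(logb)):
        bad = np.argwhere(~np.isfinite(logb))
        raise FloatingPointError(f"non-finite emission density at position {int(bad[0][1])}")
    off = logb.max(axis=2)  # (B, T) log-offsets for numerical range
    b = np.exp(logb - off[:, :, None])

    if L == 0:
        w = b * tr.pi[None, None, :]
        c = w.sum(axis=2)
        gamma = w / c[:, :, None]
        loglik = (np.log(c) + off).sum(axis=1)
        out = {"gamma": gamma, "loglik": loglik, "scales": c * np.exp(off)}
        if want_counts:
            out["pi_counts"] = gamma.sum(axis=(0, 1))  # pi reused at every position
            out["xi"] = []
        return out

    # ---- forward pass over contexts -------------------------------------
    alphas: list[np.ndarray] = []
    c = np.empty((B, T))
    a = tr.pi[None, :] * b[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    a = a / c[:, 0, None]
    alphas.append(a)
    for t in range(1, T):
        d = min(t, L)
        A = tr.A[d - 1]  # (N**d, N); context at t-1 has length d
        M = a[:, :, None] * A[None, :, :]
        if t < L:  # context grows: new code = old*N + j
            a = M.reshape(B, -1)
        else:  # drop oldest digit: new code = (old % N**(L-1))*N + j
            if L == 1:
                a = M.sum(axis=1)
            else:
                a = M.reshape(B, N, N ** (L - 1), N).sum(axis=1).reshape(B, -1)
        K = a.shape[1]
        a = a * _tile_emission(b[:, t, :], K, N)
        c[:, t] = a.sum(axis=1)
        a = a / c[:, t, None]
        alphas.append(a)
    loglik = (np.log(c) + off).sum(axis=1)

    # ---- backward pass ---------------------------------------------------
    gamma = np.empty((B, T, N))
    xi = [np.zeros((N**d, N)) for d in range(1, L + 1)] if want_counts else None
    beta = np.ones_like(alphas[-1])
    g = alphas[-1] * beta
    gamma[:, T - 1, :] = g.reshape(B, -1, N).sum(axis=1)
    for t in range(T - 2, -1, -1):
        d = min(t + 1, L)
        A = tr.A[d - 1]
        Knext = alphas[t + 1].shape[1]
        w = _tile_emission(b[:, t + 1, :], Knext, N) * beta / c[:, t + 1, None]
        if t + 1 < L:  # growing step: successor code = old*N + j
            wexp = w.reshape(B, -1, N)
        else:  # successor code = (old % N**(L-1))*N + j, same for every dropped digit
            if L == 1:
                wexp = np.broadcast_to(w[:, None, :], (B, N, N)).reshape(B, N, N)
            else:
                wexp = np.broadcast_to(
                    w.reshape(B, 1, N ** (L - 1), N), (B, N, N ** (L - 1), N)
                ).reshape(B, N**L, N)
        if want_counts:
            xi[d - 1] += np.einsum("bk,kj,bkj->kj", alphas[t], A, wexp)
        beta = np.einsum("kj,bkj->bk", A, wexp)
        g = alphas[t] * beta
        gamma[:, t, :] = g.reshape(B, -1, N).sum(axis=1)

    out = {"gamma": gamma, "loglik": loglik, "scales": c * np.exp(off)}
    if want_counts:
        out["pi_counts"] = gamma[:, 0, :].sum(axis=0)
        out["xi"] = xi
    return out


def _profile_obs(profile) -> np.ndarray:
    if hasattr(profile, "log_ratios"):
        return np.asarray(profile.log_ratios, dtype=float)
    return np.asarray(profile, dtype=float)


def forward_backward(profile, model: ARHMM) -> PosteriorMatrix:
    """State posteriors, log-likelihood and scaling constants for one profile."""
    obs = _profile_obs(profile)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("profile must be a nonempty 1-D observation sequence")
    res = forward_backward_batch(obs[None, :], model)
    return PosteriorMatrix(
        gamma=res["gamma"][0],
        loglik=float(res["loglik"][0]),
        scales=res["scales"][0],
        states=model.states.states,
    )


def loglikelihood(profiles, model: ARHMM) -> float:
    """Sum of forward log-likelihoods across all profiles."""
    seqs = [_profile_obs(p) for p in _iter_profiles(profiles)]
    if not seqs:
        raise ValueError("no profiles")
    total = 0.0
    for obs_batch in group_by_length(seqs):
        total += float(forward_backward_batch(obs_batch, model)["loglik"].sum())
    return total


def _iter_profiles(profiles):
    if hasattr(profiles, "profiles"):
        return list(profiles.profiles)
    return list(profiles)


def group_by_length(seqs: list[np.ndarray]) -> list[np.ndarray]:
    """Stack equal-length sequences into (B, T) batches for vectorised passes."""
    by_len: dict[int, list[np.ndarray]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    return [np.vstack(group) for _, group in sorted(by_len.items())]


def decode(posteriors: PosteriorMatrix) -> list[str]:
    """Argmax state per position; ties resolve toward '=' then lower index."""
    gamma = posteriors.gamma
    labels = list(posteriors.states)
    eq = labels.index("=") if "=" in labels else 0
    idx = np.argmax(gamma, axis=1)  # argmax already prefers the lower index on ties
    rowmax = gamma[np.arange(len(gamma)), idx]
    tie_with_eq = gamma[:, eq] >= rowmax - 0.0
    idx = np.where(tie_with_eq & (gamma[:, eq] == rowmax), eq, idx)
    return [labels[i] for i in idx]


def rank_genes(profile_posteriors, target_state: str) -> pd.DataFrame:
    """Rank genes across profiles by the posterior of ``target_state``.

    ``profile_posteriors`` is an iterable of (ExpressionProfile,
    PosteriorMatrix) pairs.  Descending score; deterministic tie-break on
    (sample_id, chromosome, position).
    """
    rows = []
    for profile, post in profile_posteriors:
        s = list(post.states).index(target_state)
        for i in range(len(post.gamma)):
            rows.append(
                (
                    profile.gene_ids[i],
                    profile.sample_id,
                    profile.chromosome,
                    int(profile.positions[i]),
                    float(post.gamma[i, s]),
                )
            )
    df = pd.DataFrame(rows, columns=["gene", "sample", "chrom", "pos", "score"])
    df = df.sort_values(
        ["score", "sample", "chrom", "pos"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def enumerate_loglikelihood(obs: np.ndarray, model: ARHMM) -> tuple[float, np.ndarray]:
    """Exact log-likelihood and posteriors by summing over all N**T state paths.

    Exponential-time reference for small T; used to validate the scaled
    context recursion.
    """
    from itertools import product

    from .model import context_index, emission_logdensity

    obs = np.asarray(obs, dtype=float)
    T = len(obs)
    N = model.n_states
    L = model.order_L
    tr = model.transitions
    total = 0.0
    gamma = np.zeros((T, N))
    logb = np.array(
        [
            [emission_logdensity(model, s, t + 1, obs[t], obs[:t]) for s in range(N)]
            for t in range(T)
        ]
    )
    for path in product(range(N), repeat=T):
        lp = math.log(tr.pi[path[0]]) if tr.pi[path[0]] > 0 else -math.inf
        if L == 0:
            lp = sum(
                (math.log(tr.pi[q]) if tr.pi[q] > 0 else -math.inf) for q in path
            )
        else:
            for t in range(1, T):
                d = min(t, L)
                row = context_index(path[t - d : t], N)
                p = tr.A[d - 1][row, path[t]]
                lp += math.log(p) if p > 0 else -math.inf
        lp += float(logb[np.arange(T), list(path)].sum())
        w = math.exp(lp) if lp > -math.inf else 0.0
        total += w
        for t, q in enumerate(path):
            gamma[t, q] += w
    gamma /= total
    return math.log(total), gamma
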