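"""Simulators producing chromosome-ordered profiles with the segmental,
autocorrelated structure the model assumes.

``simulate_profiles`` draws hidden states from the higher-order transition
process (initial distribution, ramp-up matrices, then the full-order matrix)
and observations from the state's autoregressive Gaussian around the
realised observation history.  ``simulate_cn_coupled`` additionally emits a
matched copy-number track: each state carries a fold level (duplicated
segments > 1, deleted < 1) and the expression log-ratio is the state mean
plus ``beta * log2(fold)`` plus Gaussian noise, emulating the coupling
between copy number and expression used to anchor ROC evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ARHMM, context_index
from .profiles_io import CopyNumberTrack, ExpressionProfile, ProfileSet
from .training import init_model

#: gene spacing (bp) of simulated profiles; only ordering matters
GENE_SPACING = 1000


@dataclass
class CNCoupling:
    """State-wise copy-number fold levels and the expression coupling."""

    fold_levels: dict[str, float] = field(
        default_factory=lambda: {"=": 1.0, "-": 0.5, "+": 3.5}
    )
    beta: float = 0.5
    noise_sd: float = 1.0


@dataclass
class SimulationSpec:
    model: ARHMM
    n_sequences: int = 50
    T: int = 300
    seed: int = 0
    coupling: CNCoupling | None = None


def default_generating_model(L: int = 1, P: int = 0, ar_coef: float = 0.0, **kwargs) -> ARHMM:
    """Generating model mirroring the training initialization defaults."""
    model = init_model(N=3, L=max(L, 0), P=P, **kwargs)
    if P > 0 and ar_coef:
        model.emissions.coef[:] = ar_coef / max(P, 1)
    return model


def _draw_states(model: ARHMM, T: int, rng: np.random.Generator) -> np.ndarray:
    N = model.n_states
    tr = model.transitions
    L = tr.order
    q = np.empty(T, dtype=np.int64)
    q[0] = rng.choice(N, p=tr.pi)
    for t in range(1, T):
        if L == 0:
            q[t] = rng.choice(N, p=tr.pi)
        else:
            d = min(t, L)
            row = context_index(tuple(q[t - d : t]), N)
            q[t] = rng.choice(N, p=tr.A[d - 1][row])
    return q


def simulate_profiles(spec: SimulationSpec) -> tuple[ProfileSet, list[np.ndarray]]:
    """Profiles drawn from the generative process, plus the hidden states."""
    rng = np.random.default_rng(spec.seed)
    em = spec.model.emissions
    P = em.order
    profiles = []
    states = []
    for i in range(spec.n_sequences):
        q = _draw_states(spec.model, spec.T, rng)
        o = np.empty(spec.T)
        for t in range(spec.T):
            mean = em.mu[q[t]]
            for j in range(1, P + 1):
                if t - j >= 0:
                    mean += em.coef[q[t], j - 1] * o[t - j]
            o[t] = rng.normal(mean, em.sigma[q[t]])
        profiles.append(_profile(i, o))
        states.append(q)
    return ProfileSet(profiles=profiles), states


def simulate_cn_coupled(spec: SimulationSpec):
    """Copy-number-coupled profiles with ground-truth overexpression labels.

    Returns ``(profiles, cn_tracks, truth)`` where ``truth`` maps
    (sample, gene) index arrays of genes lying in '+' segments.  Expression
    is ``mu_state + beta * log2(fold_state) + N(0, noise_sd)``; the
    copy-number track carries the state fold levels on the linear scale.
    """
    coupling = spec.coupling or CNCoupling()
    rng = np.random.default_rng(spec.seed)
    em = spec.model.emissions
    labels = spec.model.states.states
    folds = np.array([coupling.fold_levels[s] for s in labels])
    plus = labels.index("+")
    profiles, tracks, truth = [], [], []
    for i in range(spec.n_sequences):
        q = _draw_states(spec.model, spec.T, rng)
        fold = folds[q]
        o = em.mu[q] + coupling.beta * np.log2(fold) + rng.normal(0.0, coupling.noise_sd, spec.T)
        prof = _profile(i, o)
        profiles.append(prof)
        tracks.append(
            CopyNumberTrack(
                sample_id=prof.sample_id,
                chromosome=prof.chromosome,
                gene_ids=prof.gene_ids.copy(),
                positions=prof.positions.copy(),
                fold_change=fold,
            )
        )
        truth.append(q == plus)
    return ProfileSet(profiles=profiles), tracks, truth


def default_cn_spec(n_sequences: int = 50, T: int = 300, seed: int = 0) -> SimulationSpec:
    """Copy-number-coupled study conditions used throughout the test suite.

    State means (0, -1, +1) combine with the 0.5 * log2(fold) coupling to
    total shifts of about -1.5 / +1.9 for deleted / duplicated segments, a
    moderately noisy (sd 1.0) but realistic tumor-profile separation;
    segments persist for ~10 genes on average.
    """
    model = init_model(
        N=3, L=1, P=0, pi_init=(0.8, 0.1, 0.1), rho=0.1, mu_init=(0.0, -1.0, 1.0),
        sigma_init=(1.0, 1.0, 1.0),
    )
    return SimulationSpec(model=model, n_sequences=n_sequences, T=T, seed=seed, coupling=CNCoupling())


def _profile(i: int, o: np.ndarray) -> ExpressionProfile:
    T = len(o)
    return ExpressionProfile(
        sample_id=f"S{i:03d}",
        chromosome="chr1",
        gene_ids=np.array([f"G{i:03d}_{t:05d}" for t in range(T)]),
        positions=(np.arange(T, dtype=np.int64) + 1) * GENE_SPACING,
        log_ratios=o,
    )
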