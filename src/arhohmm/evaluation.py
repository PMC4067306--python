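"""Evaluation machinery: chromosomal autocorrelation with a permutation
baseline, copy-number candidate labelling, and ROC / TPR at fixed FPR.

The autocorrelation analysis quantifies the local chromosomal dependence
that motivates transition and emission memory: in tumor profiles, genes in
close chromosomal proximity have correlated log-ratios because deletions and
duplications span many genes, whereas randomly permuted profiles are flat.

Candidate genes of overexpression are defined by a copy-number fold cutoff
(two-, three- or four-fold) in the matched sample, and a posterior-based
gene ranking is scored by the true positive rate reached at a small fixed
false positive rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.tsa.stattools import acf as _sm_acf


def _as_sequences(profiles) -> list[np.ndarray]:
    if hasattr(profiles, "profiles"):
        profiles = profiles.profiles
    return [
        np.asarray(p.log_ratios if hasattr(p, "log_ratios") else p, dtype=float)
        for p in profiles
    ]


@dataclass
class AutocorrelationResult:
    lags: np.ndarray  # 1..max_lag
    mean: np.ndarray  # per-lag mean across usable profiles
    sd: np.ndarray
    n_profiles: np.ndarray  # usable profiles per lag
    n_skipped: int  # profiles skipped entirely (zero variance / too short)


def average_autocorrelation(profiles, max_lag: int = 10) -> AutocorrelationResult:
    """Average sample autocorrelation function across profiles.

    Per profile the lag-k autocorrelation is the mean lagged product of
    centred values over ``T - k`` pairs, normalised by the full-profile
    variance (so a strictly alternating series gives exactly -1 at lag 1).
    A profile contributes to lag k only if ``T > k``; zero-variance profiles
    are skipped.
    """
    seqs = _as_sequences(profiles)
    if not seqs:
        raise ValueError("no profiles")
    per_lag: list[list[float]] = [[] for _ in range(max_lag)]
    skipped = 0
    for x in seqs:
        if len(x) < 2 or np.var(x) == 0:
            skipped += 1
            continue
        nl = min(max_lag, len(x) - 1)
        r = _sm_acf(x, nlags=nl, adjusted=True, fft=False)
        for k in range(1, nl + 1):
            per_lag[k - 1].append(float(r[k]))
    if all(len(v) == 0 for v in per_lag):
        raise ValueError("all profiles skipped (too short or zero variance)")
    mean = np.array([np.mean(v) if v else np.nan for v in per_lag])
    sd = np.array([np.std(v, ddof=1) if len(v) > 1 else 0.0 for v in per_lag])
    return AutocorrelationResult(
        lags=np.arange(1, max_lag + 1),
        mean=mean,
        sd=sd,
        n_profiles=np.array([len(v) for v in per_lag]),
        n_skipped=skipped,
    )


def permutation_baseline(profiles, max_lag: int = 10, n_permutations: int = 100, seed: int = 0):
    """Per-lag mean and sd of the average autocorrelation after destroying
    gene order by permuting every profile independently in each repeat."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if n_permutations == 1:
        warnings.warn("single permutation: baseline sd reported as 0", stacklevel=2)
    seqs = _as_sequences(profiles)
    rng = np.random.default_rng(seed)
    means = np.empty((n_permutations, max_lag))
    for r in range(n_permutations):
        permuted = [rng.permutation(x) for x in seqs]
        means[r] = average_autocorrelation(permuted, max_lag).mean
    return means.mean(axis=0), (means.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(max_lag))


def label_candidates(copy_numbers, fold_cutoff: float) -> pd.DataFrame:
    """Binary candidate labels per (sample, chrom, gene): 1 iff fold >= cutoff."""
    if fold_cutoff <= 1:
        raise ValueError("fold cutoff must exceed 1")
    rows = []
    for track in copy_numbers:
        for g, p, f in zip(track.gene_ids, track.positions, track.fold_change):
            rows.append((track.sample_id, track.chromosome, g, int(p), int(f >= fold_cutoff)))
    return pd.DataFrame(rows, columns=["sample", "chrom", "gene", "pos", "label"])


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def tpr_at_fpr(self, f: float) -> float:
        """TPR at the largest achievable FPR <= f (step convention, no interpolation)."""
        ok = self.fpr <= f
        if not ok.any():
            return 0.0
        return float(self.tpr[ok].max())


def roc(scores, labels) -> ROCResult:
    """ROC over a descending score sweep; tied scores collapse to one point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both a positive and a negative class")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))


def labeled_ranking(ranking: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Join a gene ranking (from ``rank_genes``) with candidate labels.

    Keys: (sample, chrom, gene).  Genes without a copy-number measurement
    are dropped.
    """
    merged = ranking.merge(labels[["sample", "chrom", "gene", "label"]], on=["sample", "chrom", "gene"], how="inner")
    if merged.empty:
        raise ValueError("ranking and labels share no (sample, chrom, gene) keys")
    return merged
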