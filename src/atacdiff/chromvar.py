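"""Motif-deviation analysis over a union interval set.

Re-implements the deviation-score idea: per motif and sample, the relative
excess of reads in motif-bearing intervals over the expectation from the
sample's depth and the intervals' global accessibility, normalized against
size- and accessibility-matched random background interval sets.

Background matching uses mean-accessibility deciles only (no GC matching).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .fragments import GenomicInterval
from .seatac import SampleInfo

__all__ = [
    "CountsMatrix",
    "MotifMembership",
    "DeviationMatrix",
    "expected_counts",
    "deviation_scores",
    "pca_deviations",
    "cluster_deviations",
]


@dataclass
class CountsMatrix:
    intervals: Sequence[GenomicInterval]
    samples: Sequence[SampleInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.intervals), len(self.samples)):
            raise ValueError("counts shape must be (n_intervals, n_samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("every sample must have > 0 total reads")


@dataclass
class MotifMembership:
    motif_names: Sequence[str]
    membership: np.ndarray  # (n_intervals, n_motifs) boolean

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape[1] != len(self.motif_names):
            raise ValueError("membership columns must match motif_names")


@dataclass
class DeviationMatrix:
    motif_names: Sequence[str]
    samples: Sequence[SampleInfo]
    deviations: np.ndarray  # (n_motifs, n_samples)
    variability: np.ndarray  # (n_motifs,)
    variability_p: np.ndarray  # (n_motifs,)


def expected_counts(counts: CountsMatrix, membership: MotifMembership) -> np.ndarray:
    """Expected motif x sample read counts under the global accessibility model.

    E[j, n] = (sum of member-interval read fractions) x (sample n total),
    where an interval's read fraction is its share of all reads in the matrix.
    """
    if membership.membership.shape[0] != len(counts.intervals):
        raise ValueError("membership rows must match intervals")
    c = counts.counts.astype(float)
    w = c.sum(axis=1) / c.sum()  # interval read fractions
    col_totals = c.sum(axis=0)
    member_w = membership.membership.T.astype(float) @ w  # (n_motifs,)
    return np.outer(member_w, col_totals)


def _raw_deviation(c: np.ndarray, member: np.ndarray, w: np.ndarray,
                   col_totals: np.ndarray) -> np.ndarray:
    """(observed - expected) / expected for one membership matrix."""
    obs = member.T.astype(float) @ c  # (n_motifs, n_samples)
    exp = np.outer(member.T.astype(float) @ w, col_totals)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (obs - exp) / exp
    return raw


def deviation_scores(
    counts: CountsMatrix,
    membership: MotifMembership,
    n_background: int = 50,
    seed: int = 0,
) -> DeviationMatrix:
    """Bias-corrected deviation scores, variability and variability p-values.

    Background motifs are random interval sets of the same size drawn within
    the same mean-accessibility decile as each member interval; deviations
    are the raw deviations standardized by the background mean and sd, the
    variability is the per-motif standard deviation of deviations across
    samples, and its p-value is the +1-smoothed upper tail of the background
    variability distribution.
    """
    if n_background < 2:
        raise ValueError("n_background must be >= 2")
    c = counts.counts.astype(float)
    n_intervals, n_samples = c.shape
    member = membership.membership
    if member.shape[0] != n_intervals:
        raise ValueError("membership rows must match intervals")
    empty = member.sum(axis=0) == 0
    if empty.any():
        names = [membership.motif_names[j] for j in np.flatnonzero(empty)]
        raise ValueError(f"motifs with zero member intervals: {names}")

    w = c.sum(axis=1) / c.sum()
    col_totals = c.sum(axis=0)
    raw = _raw_deviation(c, member, w, col_totals)

    # accessibility deciles for background matching
    mean_access = c.mean(axis=1)
    deciles = np.clip(
        np.searchsorted(np.quantile(mean_access, np.linspace(0.1, 0.9, 9)),
                        mean_access, side="right"),
        0, 9,
    )
    decile_pools = [np.flatnonzero(deciles == d) for d in range(10)]
    rng = np.random.default_rng(seed)

    n_motifs = member.shape[1]
    bg_raw = np.empty((n_background, n_motifs, n_samples))
    for b in range(n_background):
        bg_member = np.zeros_like(member)
        for j in range(n_motifs):
            idx = np.flatnonzero(member[:, j])
            picked = np.empty(idx.size, dtype=int)
            for pos, i in enumerate(idx):
                pool = decile_pools[deciles[i]]
                if pool.size == 0:
                    warnings.warn(
                        "empty accessibility stratum; falling back to global sampling"
                    )
                    pool = np.arange(n_intervals)
                picked[pos] = rng.choice(pool)
            bg_member[picked, j] = True
        bg_raw[b] = _raw_deviation(c, bg_member, w, col_totals)

    bg_mean = bg_raw.mean(axis=0)
    bg_sd = bg_raw.std(axis=0, ddof=1)
    bg_sd = np.where(bg_sd > 0, bg_sd, 1.0)
    deviations = (raw - bg_mean) / bg_sd

    variability = deviations.std(axis=1, ddof=1)
    # background variabilities: standardize each background draw the same way
    bg_dev = (bg_raw - bg_mean[None]) / bg_sd[None]
    bg_var = bg_dev.std(axis=2, ddof=1)  # (n_background, n_motifs)
    exceed = (bg_var >= variability[None, :]).sum(axis=0)
    variability_p = (exceed + 1.0) / (n_background + 1.0)

    return DeviationMatrix(
        list(membership.motif_names), list(counts.samples),
        deviations, variability, variability_p,
    )


def pca_deviations(dev: DeviationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples in deviation space via column-centered SVD.

    Returns (scores: n_samples x n_components, explained-variance fractions).
    Component signs are fixed so each component's largest-magnitude loading
    is positive.
    """
    X = np.asarray(dev.deviations, dtype=float).T  # samples x motifs
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires >= 2 samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U * s
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    return scores, fractions


def cluster_deviations(dev: DeviationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical-clustering leaf orders (Euclidean, average linkage).

    Returns (motif row order, sample column order); deterministic.
    """
    D = np.asarray(dev.deviations, dtype=float)

    def order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        return leaves_list(linkage(pdist(mat), method="average"))

    return order(D), order(D.T)
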