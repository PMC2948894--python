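"""Baseline segmentations: hard/soft/Otsu thresholding and K-means clustering.

These are the conventional techniques the neural pipelines are compared
against.  Thresholding separates a slice f(x, y) into foreground/background
at an intensity T; Otsu's method picks T by exhaustively minimising the
within-class intensity variance over a 256-bin histogram; K-means (Lloyd's
algorithm on scalar voxel intensities) partitions voxels into K clusters by
minimising the intracluster variance V = sum_i sum_{x in S_i} (x - mu_i)^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volume_io import LabelVolume, PETVolume

__all__ = [
    "ThresholdResult",
    "KMeansResult",
    "hard_threshold",
    "soft_threshold",
    "otsu_threshold",
    "kmeans",
]

log = logging.getLogger(__name__)


@dataclass
class ThresholdResult:
    T: float
    labels: LabelVolume
    mode: str  # hard | soft | otsu
    values: np.ndarray  # thresholded intensities, same shape as the input


@dataclass
class KMeansResult:
    K: int
    centers: np.ndarray  # cluster mean intensities, ascending
    assignment: LabelVolume  # cluster index per voxel (0..K-1)
    V: float  # final intracluster variance objective
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0


def hard_threshold(volume: PETVolume, T: float) -> ThresholdResult:
    """Keep voxel values above T, zero the rest (values at T map to 0)."""
    if not np.isfinite(T):
        raise ValueError("threshold must be finite")
    f = volume.voxels
    fg = f > T
    return ThresholdResult(float(T), LabelVolume(fg.astype(np.int16)), "hard",
                           np.where(fg, f, 0.0))


def soft_threshold(volume: PETVolume, T: float) -> ThresholdResult:
    """Shrink voxel values above T to f - T, zero the rest."""
    if not np.isfinite(T):
        raise ValueError("threshold must be finite")
    f = volume.voxels
    fg = f > T
    return ThresholdResult(float(T), LabelVolume(fg.astype(np.int16)), "soft",
                           np.where(fg, f - T, 0.0))


def otsu_threshold(volume: PETVolume, nbins: int = 256) -> ThresholdResult:
    """Adaptive threshold minimising within-class variance (Otsu).

    The search is exhaustive over all candidate cuts of an ``nbins``-bin
    histogram of the whole volume; ties are broken toward the lower
    threshold.  The returned T is the centre of the selected bin; voxels
    strictly above T are foreground.
    """
    f = volume.voxels.ravel()
    if f.max() == f.min():
        raise ValueError("Otsu threshold undefined for a constant volume")
    counts, edges = np.histogram(f, bins=nbins, range=(f.min(), f.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(np.float64)

    # cut after bin t: class0 = bins <= t, class1 = bins > t
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    csum = np.cumsum(counts * centers)
    csum2 = np.cumsum(counts * centers ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (csum[-1] - csum) / w1
        var0 = csum2 / w0 - mu0 ** 2
        var1 = (csum2[-1] - csum2) / w1 - mu1 ** 2
    within = np.where((w0 > 0) & (w1 > 0), w0 * var0 + w1 * var1, np.inf)[:-1]
    t = int(np.argmin(within))  # argmin takes the first (lowest) minimiser
    T = float(centers[t])
    fg = volume.voxels > T
    return ThresholdResult(T, LabelVolume(fg.astype(np.int16)), "otsu",
                           np.where(fg, volume.voxels, 0.0))


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int
           ) -> tuple[np.ndarray, np.ndarray, list[float], int]:
    K = centers.size
    assign = np.full(x.size, -1, dtype=np.int32)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = np.abs(x[:, None] - centers[None, :])
        new_assign = np.argmin(dist, axis=1).astype(np.int32)
        for i in range(K):
            members = x[new_assign == i]
            if members.size == 0:
                far = int(np.argmax(np.abs(x - centers[i])))
                log.info("kmeans: cluster %d empty, reseeding at farthest voxel", i)
                centers[i] = x[far]
                new_assign[far] = i
            else:
                centers[i] = members.mean()
        history.append(float(np.sum((x - centers[new_assign]) ** 2)))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return centers, assign, history, n_iter


def kmeans(volume: PETVolume, K: int = 3, seed: int = 0,
           max_iter: int = 100, n_init: int = 5) -> KMeansResult:
    """Lloyd's K-means on voxel intensities.

    Each restart seeds the K centres at random voxel values and alternates
    nearest-centre assignment with mean updates until the assignment is a
    fixed point or ``max_iter`` is reached; of the ``n_init`` seeded
    restarts the run with the lowest final objective V is kept (single
    random starts routinely stall in local optima on multimodal intensity
    histograms).  V is recorded after every iteration and is
    non-increasing within a run.  An empty cluster is re-seeded at the
    voxel farthest from its centre (logged).
    """
    x = volume.voxels.ravel().astype(np.float64)
    n = x.size
    if K < 2:
        raise ValueError("K must be >= 2")
    if K >= n:
        raise ValueError("K must be smaller than the number of voxels")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    centers = assign = history = n_iter = None
    for _ in range(n_init):
        init = x[rng.choice(n, size=K, replace=False)].copy()
        c, a, h, it = _lloyd(x, init, max_iter)
        if history is None or h[-1] < history[-1]:
            centers, assign, history, n_iter = c, a, h, it

    order = np.argsort(centers)
    relabel = np.empty(K, dtype=np.int32)
    relabel[order] = np.arange(K)
    assign = relabel[assign]
    centers = centers[order]
    labels = LabelVolume(assign.reshape(volume.shape).astype(np.int16))
    return KMeansResult(K, centers, labels, history[-1], history, n_iter)
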