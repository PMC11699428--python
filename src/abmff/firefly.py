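"""Firefly-metaheuristic intensity clustering with K-means refinement (phase 2).

A candidate solution ("firefly") is a set of k centroid intensities in
[0, 255].  Its quality is the regularized clustering objective

    J(C) = sum_i sum_{x in C_i} ||x - mu_i||^2  -  alpha * sum_{i<j} ||mu_i - mu_j||^2

under nearest-centroid assignment: the first term rewards tight clusters,
the second (weighted by ``alpha_reg``, nominal 0.6) rewards well-separated
centroids.  Brightness is any strictly decreasing map of J; pairwise
comparisons only ever use the ordering, so -J is used directly.

Because the data are 1-D intensities, all objective evaluations run over
the 256-bin intensity histogram, which is exactly equal to (and much
faster than) the per-pixel sum.

The firefly search moves every solution toward each brighter solution with
distance-decaying attractiveness plus a decaying random walk, and the
best-ever solution is retained.  That solution then seeds a weighted
K-means on the histogram (the classical within-cluster variance criterion,
i.e. J with alpha = 0), and the hybrid keeps whichever of the two has the
lower J.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FireflyConfig",
    "ClusterSolution",
    "intensity_histogram",
    "clustering_objective",
    "firefly_search",
    "kmeans_refine",
    "optimize_centroids",
    "assign_labels",
]

_VALUES = np.arange(256, dtype=np.float64)


@dataclass(frozen=True)
class FireflyConfig:
    """Tunables of the firefly search and its K-means refinement.

    swarm_size / iter2 control the breadth and length of the search;
    alpha_reg is the separation weight of the objective; beta0 and gamma
    set the attractiveness at distance zero and its decay with squared
    distance (gamma defaults to 1/255^2 so that attraction is on the
    intensity scale); step_scale is the random-walk amplitude as a
    fraction of the 255 intensity range, shrunk by step_decay each
    iteration.  ``seed`` makes the whole search reproducible.
    """

    swarm_size: int = 20
    iter2: int = 100
    alpha_reg: float = 0.6
    beta0: float = 1.0
    gamma: float = 1.0 / 255.0 ** 2
    step_scale: float = 0.2
    step_decay: float = 0.97
    seed: int | None = None
    kmeans_max_iter: int = 300
    kmeans_tol: float = 1e-4

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iter2 < 1:
            raise ValueError("iter2 must be >= 1")
        if self.alpha_reg < 0:
            raise ValueError("alpha_reg must be >= 0")


@dataclass(frozen=True)
class ClusterSolution:
    """k centroid intensities plus the objective value J at those centroids."""

    centroids: np.ndarray
    objective: float

    def __post_init__(self):
        c = np.asarray(self.centroids, dtype=np.float64)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("centroids must be a non-empty 1-D array")
        if np.any(c < 0) or np.any(c > 255):
            raise ValueError("centroids must lie in [0, 255]")
        object.__setattr__(self, "centroids", c)

    @property
    def k(self) -> int:
        return self.centroids.size

    @property
    def brightness(self) -> float:
        """Firefly fitness: any strictly decreasing map of J (here -J)."""
        return -self.objective


def intensity_histogram(image: np.ndarray) -> np.ndarray:
    """256-bin histogram counts of an 8-bit grayscale image."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    flat = img.astype(np.int64).ravel()
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return np.bincount(flat, minlength=256)


def _check_hist(hist: np.ndarray) -> np.ndarray:
    h = np.asarray(hist, dtype=np.float64)
    if h.shape != (256,) or h.sum() <= 0:
        raise ValueError("hist must be a 256-bin histogram with positive mass")
    return h


def _assignment(centroids: np.ndarray):
    """Nearest-centroid index for every intensity 0..255 (ties -> lowest index)."""
    d2 = (_VALUES[None, :] - centroids[:, None]) ** 2
    assign = np.argmin(d2, axis=0)
    return assign, d2


def _separation(centroids: np.ndarray) -> float:
    diffs = centroids[:, None] - centroids[None, :]
    return float(np.sum(np.triu(diffs ** 2, k=1)))


def clustering_objective(hist: np.ndarray, centroids: Sequence[float],
                         alpha_reg: float = 0.6) -> float:
    """Evaluate J at ``centroids`` over a 256-bin intensity histogram.

    Exactly equal to the per-pixel evaluation: each intensity value is
    assigned to its nearest centroid (ties to the lowest centroid index),
    intra-cluster squared distances are weighted by the bin counts, and
    alpha_reg times the summed pairwise squared centroid separations is
    subtracted.
    """
    h = _check_hist(hist)
    mu = np.asarray(centroids, dtype=np.float64)
    if mu.ndim != 1 or mu.size < 1 or not np.all(np.isfinite(mu)):
        raise ValueError("centroids must be finite and 1-D")
    assign, d2 = _assignment(mu)
    intra = float(np.sum(h * d2[assign, np.arange(256)]))
    return intra - float(alpha_reg) * _separation(mu)


def firefly_search(hist: np.ndarray, k: int, config: FireflyConfig | None = None,
                   return_history: bool = False):
    """Swarm search for k centroids minimizing J over the histogram.

    ``swarm_size`` centroid sets are initialized uniformly in [0, 255];
    for ``iter2`` iterations every firefly moves toward each brighter one
    (snapshot brightness) with attractiveness beta0*exp(-gamma*r^2), plus
    a decaying uniform random kick; positions are clipped to [0, 255] and
    kept sorted so the firefly-to-firefly distance r is free of label
    permutation.  Returns the best solution ever seen (optionally with the
    per-iteration best-J trace, which is non-increasing by construction).
    """
    cfg = config or FireflyConfig()
    h = _check_hist(hist)
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = int(np.count_nonzero(h))
    if k > distinct:
        raise ValueError(f"k={k} exceeds the {distinct} distinct intensities")
    rng = np.random.default_rng(cfg.seed)

    pos = np.sort(rng.uniform(0.0, 255.0, size=(cfg.swarm_size, k)), axis=1)
    obj = np.array([clustering_objective(h, p, cfg.alpha_reg) for p in pos])
    best_idx = int(np.argmin(obj))
    best_pos, best_obj = pos[best_idx].copy(), float(obj[best_idx])
    history = [best_obj]

    step = cfg.step_scale
    for _ in range(cfg.iter2):
        obj_snap = obj.copy()
        pos_snap = pos.copy()
        for i in range(cfg.swarm_size):
            moved = False
            for j in range(cfg.swarm_size):
                if obj_snap[j] < obj_snap[i]:
                    vec = pos_snap[j] - pos[i]
                    beta = cfg.beta0 * np.exp(-cfg.gamma * float(vec @ vec))
                    pos[i] = (pos[i] + beta * vec
                              + step * rng.uniform(-0.5, 0.5, k) * 255.0)
                    moved = True
            if not moved:  # current best wanders randomly
                pos[i] = pos[i] + step * rng.uniform(-0.5, 0.5, k) * 255.0
            np.clip(pos[i], 0.0, 255.0, out=pos[i])
            pos[i].sort()
        obj = np.array([clustering_objective(h, p, cfg.alpha_reg) for p in pos])
        it_best = int(np.argmin(obj))
        if obj[it_best] < best_obj:
            best_obj = float(obj[it_best])
            best_pos = pos[it_best].copy()
        history.append(best_obj)
        step *= cfg.step_decay

    solution = ClusterSolution(np.sort(best_pos), best_obj)
    return (solution, history) if return_history else solution


def kmeans_refine(hist: np.ndarray, init_centroids: Sequence[float],
                  max_iter: int = 300, tol: float = 1e-4,
                  alpha_reg: float = 0.6, return_history: bool = False):
    """Weighted K-means on the intensity histogram from given initial centroids.

    Alternates nearest-centroid assignment and count-weighted centroid-mean
    updates until the largest centroid displacement falls below ``tol`` or
    ``max_iter`` is reached.  A centroid left with no mass is re-seeded at
    the occupied intensity farthest from its nearest surviving centroid.
    The recorded within-cluster cost JK (the alpha=0 objective) is
    non-increasing across iterations.

    The returned solution's ``objective`` is the full J (with
    ``alpha_reg``) at the refined centroids, so it is directly comparable
    with the firefly search output.
    """
    h = _check_hist(hist)
    mu = np.asarray(init_centroids, dtype=np.float64).copy()
    if mu.ndim != 1 or mu.size < 1:
        raise ValueError("init_centroids must be 1-D and non-empty")
    occupied = _VALUES[h > 0]
    jk_history = []
    for _ in range(max_iter):
        assign, d2 = _assignment(mu)
        jk_history.append(float(np.sum(h * d2[assign, np.arange(256)])))
        new_mu = mu.copy()
        empties = []
        for c in range(mu.size):
            mask = assign == c
            mass = h[mask].sum()
            if mass > 0:
                new_mu[c] = float((h[mask] * _VALUES[mask]).sum() / mass)
            else:
                empties.append(c)
        for c in empties:
            others = np.delete(new_mu, c) if mu.size > 1 else new_mu
            dist = np.min(np.abs(occupied[:, None] - others[None, :]), axis=1)
            new_mu[c] = float(occupied[int(np.argmax(dist))])
        shift = float(np.max(np.abs(new_mu - mu)))
        mu = new_mu
        if shift < tol:
            break
    mu = np.sort(mu)
    solution = ClusterSolution(mu, clustering_objective(h, mu, alpha_reg))
    return (solution, jk_history) if return_history else solution


def optimize_centroids(hist: np.ndarray, k: int,
                       config: FireflyConfig | None = None) -> ClusterSolution:
    """Full phase-2 optimizer: firefly search, K-means refinement, best of both.

    The K-means step optimizes the alpha=0 criterion, so on degenerate
    inputs it can worsen J; the hybrid therefore keeps whichever of the
    firefly best-ever and the refined solution scores lower under J.  On
    image-sized histograms the intra term dominates and the refined
    solution is essentially always the winner.
    """
    cfg = config or FireflyConfig()
    ff = firefly_search(hist, k, cfg)
    km = kmeans_refine(hist, ff.centroids, cfg.kmeans_max_iter,
                       cfg.kmeans_tol, cfg.alpha_reg)
    return km if km.objective <= ff.objective else ff


def assign_labels(image: np.ndarray, solution: ClusterSolution) -> np.ndarray:
    """Label every pixel 1..k by its nearest centroid (ties -> lowest index)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    lut, _ = _assignment(solution.centroids)
    return (lut[img.astype(np.int64)] + 1).astype(np.int32)
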