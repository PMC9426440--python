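"""K-medoid clustering of ICA feature loadings under correlation distance.

Rows of the source matrix S (one loading vector per MS1 feature) are
partitioned around medoids: k-medoids++ seeding followed by PAM-style
alternation of assignment and best-improvement swap until the total
within-module distance stops decreasing.  The module count k is chosen by
the maximum mean silhouette over a candidate range, computed on the same
correlation distance used for clustering.

The swap search uses the FastPAM1 bookkeeping (nearest and second-nearest
medoid distances) so one full sweep over candidate swaps costs O(n^2)
rather than O(k n^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class FeatureClustering:
    """Module labels, medoids, and the silhouette trace behind the chosen k."""

    labels: np.ndarray
    medoids: np.ndarray
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None


def correlation_distance_matrix(S: np.ndarray) -> np.ndarray:
    """Pairwise d(i,j) = 1 - Pearson r between rows of S; range [0, 2]."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ValueError("need at least 2 components per feature row")
    sd = S.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)[:5].tolist()
        raise ValueError(f"constant feature rows have undefined correlation: rows {bad}")
    Z = (S - S.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = np.clip(Z @ Z.T / S.shape[1], -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2


def _kmedoidspp_init(dist: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-medoids++ seeding: spread initial medoids proportionally to distance."""
    n = dist.shape[0]
    medoids = [int(rng.integers(n))]
    closest = dist[medoids[0]].copy()
    for _ in range(1, k):
        weights = closest**2
        total = weights.sum()
        if total <= 0:
            # all remaining points coincide with a medoid; pick any non-medoid
            candidates = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(candidates[0]))
        else:
            medoids.append(int(rng.choice(n, p=weights / total)))
        np.minimum(closest, dist[medoids[-1]], out=closest)
    return np.array(sorted(set(medoids)), dtype=int)


def _alternate(dist: np.ndarray, medoids: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Assign-to-nearest / recompute-medoid alternation until stable."""
    n = dist.shape[0]
    medoids = medoids.copy()
    for _ in range(max_iter):
        labels = np.argmin(dist[medoids], axis=0)
        new_medoids = medoids.copy()
        for c in range(len(medoids)):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            return medoids
        medoids = new_medoids
    return medoids


def _pam_iterate(dist: np.ndarray, medoids: np.ndarray, max_sweeps: int = 200):
    """Best-improvement swap loop; returns (labels, medoids, cost)."""
    n = dist.shape[0]
    medoids = medoids.copy()
    for _ in range(max_sweeps):
        D = dist[medoids]  # (k, n)
        nearest_idx = np.argmin(D, axis=0)
        order = np.argsort(D, axis=0, kind="stable")
        d_nearest = D[order[0], np.arange(n)]
        d_second = D[order[1], np.arange(n)] if len(medoids) > 1 else np.full(n, np.inf)
        cost = d_nearest.sum()

        best_delta = 0.0
        best_swap: tuple[int, int] | None = None
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        for j in np.flatnonzero(~is_medoid):
            dj = dist[j]
            # removal loss per medoid: points whose nearest medoid is removed
            # move to min(second-nearest, candidate); others may gain from j
            gain = np.minimum(dj - d_nearest, 0.0)  # improvement for all points
            shared = gain.sum()
            # per-medoid correction for points losing their nearest medoid
            delta_m = np.zeros(len(medoids))
            move_to = np.minimum(d_second, dj) - d_nearest
            np.add.at(delta_m, nearest_idx, move_to - gain)
            delta = shared + delta_m
            m_best = int(np.argmin(delta))
            if delta[m_best] < best_delta - 1e-12:
                best_delta = float(delta[m_best])
                best_swap = (m_best, j)
        if best_swap is None:
            return nearest_idx, medoids, float(cost)
        medoids[best_swap[0]] = best_swap[1]
        medoids.sort()
    D = dist[medoids]
    nearest_idx = np.argmin(D, axis=0)
    return nearest_idx, medoids, float(D[nearest_idx, np.arange(n)].sum())


def kmedoids_cluster(
    dist: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """PAM clustering on a precomputed distance matrix.

    Returns (labels, medoid indices); deterministic given ``seed``.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    rng = np.random.default_rng(int(seed))
    medoids = _kmedoidspp_init(dist, k, rng)
    while len(medoids) < k:  # degenerate duplicates during seeding
        extra = np.setdiff1d(np.arange(n), medoids)[0]
        medoids = np.sort(np.append(medoids, extra))
    medoids = _alternate(dist, medoids)
    labels, medoids, _ = _pam_iterate(dist, medoids)
    return labels, medoids


def pam_cost(dist: np.ndarray, labels: np.ndarray, medoids: np.ndarray) -> float:
    """Total distance of each point to its own medoid."""
    return float(dist[medoids[labels], np.arange(dist.shape[0])].sum())


def select_k(
    dist: np.ndarray,
    k_range: range | list[int] = range(10, 51),
    seed: int = 0,
    restarts: int = 1,
) -> FeatureClustering:
    """Cluster at every k in the range; keep the k with maximum mean silhouette.

    Ties go to the smallest k.  ``restarts`` > 1 reruns each k from
    different seeds and keeps the lowest-cost solution before scoring.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    n = dist.shape[0]
    if max(ks) >= n:
        raise ValueError(f"max(k_range)={max(ks)} must be < n={n}")
    sil_by_k: dict[int, float] = {}
    best: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in ks:
        sols = []
        for r in range(max(1, restarts)):
            labels, medoids = kmedoids_cluster(dist, k, seed=int(seed) + 7919 * r)
            sols.append((pam_cost(dist, labels, medoids), labels, medoids))
        _, labels, medoids = min(sols, key=lambda t: t[0])
        best[k] = (labels, medoids)
        if len(np.unique(labels)) < 2:
            sil_by_k[k] = -1.0  # degenerate single effective module
        else:
            sil_by_k[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    chosen = max(ks, key=lambda k: (sil_by_k[k], -k))
    labels, medoids = best[chosen]
    logger.info("silhouette model selection chose k=%d (s=%.3f)", chosen, sil_by_k[chosen])
    return FeatureClustering(
        labels=labels,
        medoids=medoids,
        k=chosen,
        silhouette_by_k=sil_by_k,
        chosen_k=chosen,
    )
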