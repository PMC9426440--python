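"""Robust consensus independent-component analysis.

The intensity matrix X (features x samples, log2 scale, feature-centered)
is decomposed many times by fixed-point ICA from different random seeds.
Components pooled across runs are grouped by single-linkage clustering on
the correlation distance 1 - |r| between loading vectors; groups supported
by at least half of the runs yield robust components as their sign-aligned
centroids.  The number of components is guided by PCA: the smallest count
explaining a target fraction (default 99%) of the variance.

The result is S (features x n_robust, unit-norm columns of feature
contributions) and A (n_robust x samples activities, recovered by least
squares from the centered data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .types import IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class DecompositionResult:
    """Robust source matrix S, activity matrix A, and run provenance."""

    S: np.ndarray  # features x n_robust, unit-norm columns
    A: np.ndarray  # n_robust x samples
    n_requested: int
    n_robust: int
    run_seeds: list[int]
    cluster_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.S.shape[1] != self.n_robust or self.A.shape[0] != self.n_robust:
            raise ValueError("S/A shapes inconsistent with n_robust")
        if self.n_robust > self.n_requested:
            raise ValueError("n_robust cannot exceed n_requested")


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, IntensityMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def _center_features(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def select_n_components(matrix, var_target: float = 0.99) -> int:
    """Smallest component count explaining ``var_target`` of the variance.

    Computed from the singular values of the feature-centered matrix and
    capped at min(n_features, n_samples - 1).
    """
    X = _as_array(matrix)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    Xc = _center_features(X)
    if not np.any(Xc):
        raise ValueError("constant matrix has no variance structure")
    s = np.linalg.svd(Xc, compute_uv=False)
    var = s**2
    ratio = np.cumsum(var) / var.sum()
    cap = min(X.shape[0], X.shape[1] - 1)
    n = int(np.searchsorted(ratio, var_target - 1e-12) + 1)
    return min(n, cap)


def ica_single_run(
    matrix,
    n_comp: int,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One fixed-point ICA estimate with whitening.

    Returns (S_run, A_run, converged); columns of S_run are unit-norm.
    The decomposition treats features as observations so the recovered
    sources are independent across features, matching the screening model
    where module loading patterns are the non-Gaussian signals.
    """
    X = _as_array(matrix)
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")
    Xc = _center_features(X)
    # whiten against the feature-centered principal subspace so recovered
    # sources span exactly the top-n_comp PCA directions of Xc
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    if sv[min(n_comp, len(sv)) - 1] <= 1e-12 * sv[0]:
        raise ValueError("requested components exceed the numerical rank")
    Z = U[:, :n_comp] * np.sqrt(X.shape[0])
    if n_comp == 1:
        S = U[:, :1]
        converged = True
    else:
        ica = FastICA(
            n_components=n_comp,
            whiten=False,
            fun="logcosh",
            tol=tol,
            max_iter=max_iter,
            random_state=int(seed),
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(Z)  # (features, n_comp)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    S = S / norms
    # activities by least squares against the centered data
    A, *_ = np.linalg.lstsq(S, Xc, rcond=None)
    return S, A, converged


def consensus_components(
    runs: list[np.ndarray],
    X_centered: np.ndarray,
    n_requested: int,
    run_seeds: list[int],
    min_support: float = 0.5,
    link_threshold: float = 0.1,
) -> DecompositionResult:
    """Cluster pooled run components and extract robust centroids.

    Components from all runs are pooled; distance between two loading
    vectors is 1 - |Pearson r|; single-linkage groups at ``link_threshold``
    are kept when they contain components from at least ``min_support`` of
    the runs.  Members are sign-aligned to the member closest to the group
    mean, the centroid is the element-wise mean (re-normalized), and A is
    recomputed by least squares.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 successful runs for a consensus")
    pool = np.concatenate(runs, axis=1)  # features x total_components
    run_of = np.concatenate([
        np.full(r.shape[1], i) for i, r in enumerate(runs)
    ])
    # correlation distance between pooled loading vectors
    Z = pool - pool.mean(axis=0, keepdims=True)
    sd = np.linalg.norm(Z, axis=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    corr = np.clip(np.abs(Z.T @ Z), 0.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    L = linkage(squareform(dist, checks=False), method="single")
    groups = fcluster(L, t=link_threshold, criterion="distance")

    n_runs = len(runs)
    robust: list[np.ndarray] = []
    sizes: list[int] = []
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        support = len(set(run_of[members].tolist()))
        if support / n_runs < min_support:
            continue
        vecs = pool[:, members]
        # sign-align to the member closest to the (abs-correlation) group mean
        ref_idx = np.argmax(corr[np.ix_(members, members)].sum(axis=1))
        ref = vecs[:, ref_idx]
        signs = np.sign(vecs.T @ ref)
        signs[signs == 0] = 1.0
        centroid = (vecs * signs[None, :]).mean(axis=1)
        norm = np.linalg.norm(centroid)
        if norm == 0:
            continue
        robust.append(centroid / norm)
        sizes.append(support)
    if not robust:
        raise ValueError(
            "no component group reached the support threshold; "
            "try fewer components or a lower --support"
        )
    S = np.column_stack(robust)
    A, *_ = np.linalg.lstsq(S, X_centered, rcond=None)
    # deterministic order: decreasing explained variance of the activity rows
    order = np.argsort(-np.var(A, axis=1), kind="stable")
    S = S[:, order]
    A = A[order]
    sizes = [sizes[i] for i in order]
    return DecompositionResult(
        S=S,
        A=A,
        n_requested=n_requested,
        n_robust=S.shape[1],
        run_seeds=list(run_seeds),
        cluster_sizes=sizes,
    )


def robust_ica(
    matrix,
    n_runs: int = 100,
    var_target: float = 0.99,
    n_components: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    min_support: float = 0.5,
    link_threshold: float = 0.1,
    seed: int = 0,
) -> DecompositionResult:
    """Full robust decomposition: PCA-guided n, repeated ICA, consensus.

    Per-run seeds are derived from the master ``seed`` by a counter and
    recorded in the result.  Runs that fail to converge within ``max_iter``
    iterations are excluded from the consensus (logged); if fewer than two
    runs converge the convergence flag is ignored with a warning so a
    decomposition is still produced.
    """
    X = _as_array(matrix)
    n_comp = n_components if n_components is not None else select_n_components(X, var_target)
    Xc = _center_features(X)
    seeds = [int(seed) * 100003 % (2**31) + i for i in range(n_runs)]
    runs, used_seeds, flagged = [], [], []
    all_runs, all_seeds = [], []
    for s in seeds:
        S_run, _, converged = ica_single_run(X, n_comp, seed=s, tol=tol, max_iter=max_iter)
        all_runs.append(S_run)
        all_seeds.append(s)
        if converged:
            runs.append(S_run)
            used_seeds.append(s)
        else:
            flagged.append(s)
    if flagged:
        logger.info("%d/%d ICA runs did not converge and are excluded", len(flagged), n_runs)
    if len(runs) < 2:
        logger.warning(
            "fewer than 2 converged ICA runs; using all %d runs regardless", n_runs
        )
        runs, used_seeds = all_runs, all_seeds
    return consensus_components(
        runs,
        Xc,
        n_requested=n_comp,
        run_seeds=used_seeds,
        min_support=min_support,
        link_threshold=link_threshold,
    )
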