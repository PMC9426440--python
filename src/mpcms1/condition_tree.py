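"""Hierarchical clustering of conditions with multiscale-bootstrap support.

The module x condition correlation profile is converted to a condition
distance matrix (1 - Pearson r between profile columns), agglomerated by
average linkage (merge height = mean pairwise inter-group distance), cut
into flat groups by maximum mean silhouette, and annotated per node with
bootstrap probabilities:

BP
    plain bootstrap proportion of resamples (of module rows, at resample
    size equal to the data) whose tree contains the same leaf clade.
AU
    approximately unbiased p-value from the multiscale bootstrap: BP is
    measured at several resample-size scales r, z(r) = Phi^-1(1 - BP(r))
    is regressed on {sqrt(r), 1/sqrt(r)} by weighted least squares giving
    signed distance v and curvature c, and AU = 1 - Phi(v - c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.metrics import silhouette_score

from .eigenfeatures import GroupCorrelationProfile

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


@dataclass
class ConditionTree:
    """Average-linkage tree over condition leaves (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaves: list[str]
    au: np.ndarray | None = None  # per internal node, linkage row order
    bp: np.ndarray | None = None
    flat_labels: np.ndarray | None = None
    chosen_k: int | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def clades(self) -> list[frozenset[str]]:
        """Leaf set of every internal node, in linkage row order."""
        n = self.n_leaves
        sets: list[frozenset[str]] = []
        store: dict[int, frozenset[str]] = {i: frozenset([self.leaves[i]]) for i in range(n)}
        for row, (a, b, _, _) in enumerate(self.linkage):
            merged = store[int(a)] | store[int(b)]
            store[n + row] = merged
            sets.append(merged)
        return sets

    def cophenetic_matrix(self) -> np.ndarray:
        """Symmetric matrix of merge heights between all leaf pairs."""
        return squareform(hierarchy.cophenet(self.linkage))

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self, digits: int = 10) -> str:
        """Newick string; internal nodes carry [&AU=...,BP=...] comments."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for row, (a, b, h, _) in enumerate(self.linkage):
            heights[n + row] = h

        def fmt(x: float) -> str:
            return f"{x:.{digits}g}"

        def render(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.leaves[node]}:{fmt(parent_h)}"
            row = node - n
            a, b, h, _ = self.linkage[row]
            inner = ",".join(render(int(c), h - heights[int(c)]) for c in (int(a), int(b)))
            comment = ""
            if self.au is not None and self.bp is not None:
                comment = f"[&AU={fmt(self.au[row])},BP={fmt(self.bp[row])}]"
            return f"({inner}){comment}:{fmt(parent_h)}"

        root = n + len(self.linkage) - 1
        a, b, h, _ = self.linkage[-1]
        inner = ",".join(render(int(c), h - heights[int(c)]) for c in (int(a), int(b)))
        comment = ""
        if self.au is not None and self.bp is not None:
            comment = f"[&AU={fmt(self.au[-1])},BP={fmt(self.bp[-1])}]"
        return f"({inner}){comment};"


def condition_distance(R) -> np.ndarray:
    """d(g1, g2) = 1 - Pearson r between correlation-profile columns."""
    M = R.R if isinstance(R, GroupCorrelationProfile) else np.asarray(R, float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 modules (rows) for a condition distance")
    sd = M.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant correlation-profile columns: {bad}")
    Z = (M - M.mean(axis=0, keepdims=True)) / sd[None, :]
    corr = np.clip(Z.T @ Z / M.shape[0], -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2


def average_linkage_tree(dist: np.ndarray, leaves: list[str]) -> ConditionTree:
    """UPGMA agglomeration; merge height = mean inter-group pairwise distance."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 conditions")
    if dist.shape[0] != len(leaves):
        raise ValueError("distance size does not match leaf count")
    L = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ConditionTree(linkage=L, leaves=list(leaves))


def cut_by_silhouette(
    tree: ConditionTree, dist: np.ndarray, k_range=None
) -> ConditionTree:
    """Flat cut at the k maximizing mean silhouette on the condition distance."""
    n = tree.n_leaves
    if n == 2:
        logger.info("two leaves: forced single cut, silhouette skipped")
        tree.flat_labels = np.array([1, 2])
        tree.chosen_k = 2
        return tree
    if n < 3:
        raise ValueError("need at least 3 leaves to cut by silhouette")
    ks = sorted(set(int(k) for k in (k_range if k_range is not None else range(2, n))))
    ks = [k for k in ks if 2 <= k <= n]
    if not ks:
        raise ValueError("empty k_range after bounds check")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        labels = tree.cut(k)
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2 or len(np.unique(labels)) >= n:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    chosen = max(ks, key=lambda k: (sil[k], -k))
    tree.flat_labels = labels_by_k[chosen]
    tree.chosen_k = chosen
    tree.silhouette_by_k = sil
    return tree


def _bootstrap_proportions(
    R: np.ndarray,
    leaves: list[str],
    target_clades: list[frozenset[str]],
    n_boot: int,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    m = R.shape[0]
    counts = np.zeros(len(target_clades))
    target_index = {c: i for i, c in enumerate(target_clades)}
    for _ in range(n_boot):
        rows = rng.integers(0, m, size=size)
        Rb = R[rows]
        sd = Rb.std(axis=0)
        if np.any(sd == 0):
            # resample with no variance for some condition: no tree; skip
            continue
        d = condition_distance(Rb)
        t = average_linkage_tree(d, leaves)
        for clade in t.clades():
            idx = target_index.get(clade)
            if idx is not None:
                counts[idx] += 1
    return counts / n_boot


def au_bootstrap(
    R,
    tree: ConditionTree,
    n_boot: int = 1000,
    scales=DEFAULT_SCALES,
    seed: int = 0,
) -> ConditionTree:
    """Attach AU and BP support to every internal node of ``tree``.

    Resamples module rows of the correlation profile with replacement at
    each scale, rebuilds the condition tree, and counts clade recovery.
    BP is the plain proportion at scale 1; AU comes from the weighted
    least-squares fit of z(r) across scales.  Nodes with BP 0 or 1 at every
    scale are clamped to AU 0 or 1; a singular fit leaves AU as NaN.
    """
    M = R.R if isinstance(R, GroupCorrelationProfile) else np.asarray(R, float)
    m = M.shape[0]
    if m < 4:
        raise ValueError("need at least 4 module rows to bootstrap")
    rng = np.random.default_rng(int(seed))
    clades = tree.clades()
    scales = np.asarray(list(scales), dtype=float)
    sizes = np.maximum(1, np.ceil(scales * m).astype(int))
    bp_by_scale = np.zeros((len(scales), len(clades)))
    for si, size in enumerate(sizes):
        bp_by_scale[si] = _bootstrap_proportions(
            M, tree.leaves, clades, n_boot, int(size), rng
        )
    # effective scale actually used after ceiling
    r_eff = sizes / m

    au = np.full(len(clades), np.nan)
    bp_scale1 = np.zeros(len(clades))
    idx_scale1 = int(np.argmin(np.abs(r_eff - 1.0)))
    for ci in range(len(clades)):
        bps = bp_by_scale[:, ci]
        bp_scale1[ci] = bps[idx_scale1]
        usable = (bps > 0) & (bps < 1)
        if not usable.any():
            au[ci] = 1.0 if bps.mean() >= 0.5 else 0.0
            continue
        if usable.sum() < 2:
            au[ci] = 1.0 if bps[usable].mean() >= 0.5 else 0.0
            continue
        r = r_eff[usable]
        z = norm.ppf(1.0 - bps[usable])
        X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        # binomial-variance weights on the probit scale
        phi = norm.pdf(z)
        w = n_boot * phi**2 / (bps[usable] * (1.0 - bps[usable]))
        XtWX = X.T @ (w[:, None] * X)
        try:
            beta = np.linalg.solve(XtWX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            logger.info("singular multiscale fit for node %d; AU unavailable", ci)
            continue
        v, c = beta
        au[ci] = float(np.clip(1.0 - norm.cdf(v - c), 0.0, 1.0))
    # root clade is always recovered
    tree.au = au
    tree.bp = bp_scale1
    return tree
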