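"""Dendrogram comparison: cophenetic correlation and a permutation test.

Two condition trees over the same leaf set are compared by the Pearson
correlation of their cophenetic distances (the merge height at which each
leaf pair joins).  Significance is assessed by shuffling the leaf labels
of the second tree and counting permutations whose |r| reaches the
observed |r|; the reported p-value uses the add-one correction
p = (count + 1) / (n_perm + 1) so it is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .condition_tree import ConditionTree

logger = logging.getLogger(__name__)


@dataclass
class TreeComparison:
    r_cophenetic: float
    n_perm: int
    count_ge: int
    p_value: float
    seed: int


def _cophenetic_of(tree) -> tuple[np.ndarray, list[str]]:
    if isinstance(tree, ConditionTree):
        return tree.cophenetic_matrix(), list(tree.leaves)
    if isinstance(tree, tuple) and len(tree) == 2:
        return np.asarray(tree[0], float), list(tree[1])
    raise TypeError("expected a ConditionTree or (cophenetic matrix, leaves) pair")


def read_newick_cophenetic(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Cophenetic matrix and leaf labels from an ultrametric Newick file.

    The cophenetic distance of a leaf pair in an ultrametric dendrogram is
    half the leaf-to-leaf path length.
    """
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = pdm.patristic_distance(taxa[i], taxa[j]) / 2.0
    return C, labels


def _aligned_condensed(tree1, tree2) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    C1, l1 = _cophenetic_of(tree1)
    C2, l2 = _cophenetic_of(tree2)
    if set(l1) != set(l2):
        only1 = sorted(set(l1) - set(l2))
        only2 = sorted(set(l2) - set(l1))
        raise ValueError(
            f"leaf label sets differ: only in first {only1}, only in second {only2}"
        )
    order = [l2.index(name) for name in l1]
    C2 = C2[np.ix_(order, order)]
    iu = np.triu_indices(len(l1), k=1)
    return C1[iu], C2, C2[iu], l1


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs, ys = x.std(), y.std()
    if xs == 0 or ys == 0:
        raise ValueError("cophenetic distances are constant; correlation undefined")
    return float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * xs * ys))


def cophenetic_correlation(tree1, tree2) -> float:
    """Pearson r between the two trees' cophenetic distances, label-aligned."""
    v1, _, v2, _ = _aligned_condensed(tree1, tree2)
    if np.array_equal(v1, v2):
        return 1.0  # identical distances: r is exactly 1 by definition
    return _pearson(v1, v2)


def permutation_pvalue(
    tree1, tree2, n_perm: int = 10000, seed: int = 0
) -> TreeComparison:
    """Two-sided label-permutation test of cophenetic correlation.

    Leaf labels of ``tree2`` are shuffled uniformly; permutations with
    |r_perm| >= |r_obs| are counted.  If either tree has constant
    cophenetic distances every permutation reproduces the observed value
    and p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    v1, C2, v2, labels = _aligned_condensed(tree1, tree2)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 leaves for a meaningful permutation test")
    rng = np.random.default_rng(int(seed))
    if v1.std() == 0 or v2.std() == 0:
        logger.warning("constant cophenetic distances; permutation test degenerate, p=1")
        return TreeComparison(
            r_cophenetic=float("nan"),
            n_perm=n_perm,
            count_ge=n_perm,
            p_value=(n_perm + 1) / (n_perm + 1),
            seed=int(seed),
        )
    r_obs = _pearson(v1, v2)
    iu = np.triu_indices(n, k=1)
    z1 = (v1 - v1.mean()) / v1.std()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = C2[np.ix_(perm, perm)][iu]
        sd = vp.std()
        if sd == 0:
            count += 1
            continue
        r = float(np.dot(z1, (vp - vp.mean()) / sd) / len(z1))
        if abs(r) >= abs(r_obs) - 1e-15:
            count += 1
    return TreeComparison(
        r_cophenetic=r_obs,
        n_perm=n_perm,
        count_ge=count,
        p_value=(count + 1) / (n_perm + 1),
        seed=int(seed),
    )
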