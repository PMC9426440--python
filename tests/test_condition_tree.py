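import numpy as np
import pytest

from mpcms1.condition_tree import (
    au_bootstrap,
    average_linkage_tree,
    condition_distance,
    cut_by_silhouette,
)
from mpcms1.eigenfeatures import GroupCorrelationProfile


def two_block_profile(n_modules=12, per_block=4, noise=0.05, seed=0):
    """Correlation profile with two clearly separated condition blocks."""
    rng = np.random.default_rng(seed)
    n_cond = 2 * per_block
    R = np.zeros((n_modules, n_cond))
    R[:, :per_block] = rng.normal(0, 1, size=(n_modules, 1))
    R[:, per_block:] = rng.normal(0, 1, size=(n_modules, 1))
    R += noise * rng.normal(size=R.shape)
    return GroupCorrelationProfile(
        R=R, conditions=[f"c{i}" for i in range(n_cond)], module_ids=np.arange(n_modules)
    )


class TestConditionDistance:
    def test_identical_and_negated_columns(self):
        col = np.array([0.5, -0.2, 0.8, 0.1])
        R = np.column_stack([col, col, -col])
        d = condition_distance(R)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        R = rng.normal(size=(10, 6))
        d = condition_distance(R)
        for i in range(6):
            for j in range(6):
                r = np.corrcoef(R[:, i], R[:, j])[0, 1]
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_constant_column_errors(self):
        R = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError):
            condition_distance(R)


class TestAverageLinkage:
    def test_hand_agglomeration_three_points(self):
        d = np.array(
            [
                [0.0, 0.1, 0.9],
                [0.1, 0.0, 0.9],
                [0.9, 0.9, 0.0],
            ]
        )
        tree = average_linkage_tree(d, ["A", "B", "C"])
        np.testing.assert_allclose(tree.heights(), [0.1, 0.9])
        assert frozenset(["A", "B"]) in tree.clades()

    def test_heights_match_bruteforce_mean_pairwise(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        tree = average_linkage_tree(d, [f"L{i}" for i in range(7)])
        clades = tree.clades()
        n = 7
        store = {i: {tree.leaves[i]} for i in range(n)}
        for row, (a, b, h, _) in enumerate(tree.linkage):
            left, right = store[int(a)], store[int(b)]
            idx = {tree.leaves.index(x) for x in left}
            jdx = {tree.leaves.index(x) for x in right}
            mean_d = np.mean([d[i, j] for i in idx for j in jdx])
            assert h == pytest.approx(mean_d, abs=1e-12)
            store[n + row] = left | right

    def test_leaf_permutation_same_topology(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = [f"L{i}" for i in range(6)]
        t1 = average_linkage_tree(d, labels)
        perm = rng.permutation(6)
        t2 = average_linkage_tree(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert set(t1.clades()) == set(t2.clades())

    def test_ultrametric_input_reproduced(self):
        # heights in an ultrametric are recovered exactly by average linkage
        d = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ]
        )
        tree = average_linkage_tree(d, list("ABCD"))
        np.testing.assert_allclose(sorted(tree.heights()), [0.2, 0.4, 0.8])


class TestSilhouetteCut:
    def test_two_blocks_chosen(self):
        prof = two_block_profile()
        d = condition_distance(prof)
        tree = average_linkage_tree(d, prof.conditions)
        tree = cut_by_silhouette(tree, d)
        assert tree.chosen_k == 2
        # flat groups are unions of subtrees
        for g in np.unique(tree.flat_labels):
            members = frozenset(
                l for l, lab in zip(tree.leaves, tree.flat_labels) if lab == g
            )
            assert members in tree.clades() or len(members) == 1

    def test_chosen_k_maximizes_silhouette(self):
        prof = two_block_profile(noise=0.4, seed=5)
        d = condition_distance(prof)
        tree = cut_by_silhouette(average_linkage_tree(d, prof.conditions), d)
        assert tree.silhouette_by_k[tree.chosen_k] == max(tree.silhouette_by_k.values())

    def test_singleton_range(self):
        prof = two_block_profile(seed=6)
        d = condition_distance(prof)
        tree = cut_by_silhouette(average_linkage_tree(d, prof.conditions), d, k_range=[3])
        assert tree.chosen_k == 3


class TestAuBootstrap:
    def test_true_split_high_support_and_determinism(self):
        prof = two_block_profile(noise=0.02, seed=7)
        d = condition_distance(prof)
        t1 = au_bootstrap(prof, average_linkage_tree(d, prof.conditions), n_boot=300, seed=1)
        block = frozenset(prof.conditions[:4])
        idx = t1.clades().index(block)
        assert t1.au[idx] >= 0.95
        assert t1.bp[idx] >= 0.95
        t2 = au_bootstrap(prof, average_linkage_tree(d, prof.conditions), n_boot=300, seed=1)
        np.testing.assert_array_equal(t1.au, t2.au)
        np.testing.assert_array_equal(t1.bp, t2.bp)

    def test_values_in_unit_interval_and_root_is_one(self):
        prof = two_block_profile(noise=0.5, seed=8)
        d = condition_distance(prof)
        tree = au_bootstrap(prof, average_linkage_tree(d, prof.conditions), n_boot=200, seed=2)
        valid = ~np.isnan(tree.au)
        assert ((tree.au[valid] >= 0) & (tree.au[valid] <= 1)).all()
        assert ((tree.bp >= 0) & (tree.bp <= 1)).all()
        root = tree.clades().index(frozenset(prof.conditions))
        assert tree.bp[root] == 1.0 and tree.au[root] == 1.0

    def test_bp_is_plain_proportion_at_scale_one(self):
        # with a single scale of 1.0 the BP equals the resample recovery rate
        prof = two_block_profile(noise=0.3, seed=9)
        d = condition_distance(prof)
        tree = au_bootstrap(
            prof,
            average_linkage_tree(d, prof.conditions),
            n_boot=150,
            scales=[1.0],
            seed=3,
        )
        assert np.all((np.round(tree.bp * 150) - tree.bp * 150) < 1e-9)

    def test_too_few_modules_errors(self):
        prof = GroupCorrelationProfile(
            R=np.random.default_rng(0).normal(size=(3, 5)),
            conditions=[f"c{i}" for i in range(5)],
            module_ids=np.arange(3),
        )
        d = condition_distance(prof)
        with pytest.raises(ValueError):
            au_bootstrap(prof, average_linkage_tree(d, prof.conditions), n_boot=50, seed=0)


class TestNewick:
    def test_roundtrip_topology_and_leaves(self, tmp_path):
        import dendropy

        prof = two_block_profile(seed=10)
        d = condition_distance(prof)
        tree = au_bootstrap(prof, average_linkage_tree(d, prof.conditions), n_boot=100, seed=4)
        nwk = tree.to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = {t.taxon.label for t in parsed.leaf_node_iter()}
        assert leaves == set(prof.conditions)
        # bipartitions agree (ignoring the root)
        parsed.encode_bipartitions()
        clade_sets = {
            frozenset(t.label for t in bip.leafset_taxa(parsed.taxon_namespace))
            for bip in parsed.bipartition_encoding
        }
        for clade in tree.clades():
            if len(clade) < len(prof.conditions):
                assert clade in clade_sets or frozenset(
                    set(prof.conditions) - clade
                ) in clade_sets
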