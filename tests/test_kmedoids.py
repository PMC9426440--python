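import numpy as np
import pytest

from mpcms1.kmedoids import (
    correlation_distance_matrix,
    kmedoids_cluster,
    pam_cost,
    select_k,
)


def planted_rows(n_modules, per_module, dims, noise, seed):
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_modules, dims))
    rows = np.vstack(
        [centers[m] + noise * rng.normal(size=(per_module, dims)) for m in range(n_modules)]
    )
    truth = np.repeat(np.arange(n_modules), per_module)
    return rows, truth


class TestCorrelationDistance:
    def test_identical_and_negated_rows(self):
        row = np.array([1.0, 2.0, 0.5, 3.0])
        S = np.vstack([row, row, -row])
        d = correlation_distance_matrix(S)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert np.all(np.diag(d) == 0)

    def test_orthogonal_rows_near_one(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(2, 50))
        A[1] -= A[1].mean() + (A[0] - A[0].mean()) @ (A[1] - A[1].mean()) / np.sum(
            (A[0] - A[0].mean()) ** 2
        ) * (A[0] - A[0].mean())
        d = correlation_distance_matrix(A)
        assert d[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_constant_row_errors(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_distance_matrix(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


def naive_pam(dist, init):
    """Brute-force alternation + exhaustive-swap search (tiny n only).

    Plain-loop re-implementation of the same algorithm: Voronoi alternation
    until stable, then best-improvement swaps evaluated by recomputing the
    full assignment cost for every (medoid, candidate) pair.
    """
    n = dist.shape[0]
    medoids = sorted(init.tolist())
    while True:  # alternation
        labels = dist[medoids].argmin(axis=0)
        new = []
        for c in range(len(medoids)):
            members = [i for i in range(n) if labels[i] == c]
            if not members:
                new.append(medoids[c])
                continue
            costs = [sum(dist[i, j] for j in members) for i in members]
            new.append(members[int(np.argmin(costs))])
        new = sorted(new)
        if new == medoids:
            break
        medoids = new
    while True:  # exhaustive swaps
        cost = dist[medoids].min(axis=0).sum()
        best = (cost, None)
        for mi in range(len(medoids)):
            for j in range(n):
                if j in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = j
                c = dist[cand].min(axis=0).sum()
                if c < best[0] - 1e-12:
                    best = (c, cand)
        if best[1] is None:
            return cost
        medoids = sorted(best[1])


class TestKMedoids:
    def test_two_far_blocks_recovered(self):
        rows, truth = planted_rows(2, 10, 12, 0.05, seed=1)
        d = correlation_distance_matrix(rows)
        labels, medoids = kmedoids_cluster(d, 2, seed=0)
        # perfect block recovery up to label swap
        assert len(set(zip(truth.tolist(), labels.tolist()))) == 2

    def test_k_equal_n_errors(self):
        d = correlation_distance_matrix(planted_rows(2, 3, 8, 0.1, 2)[0])
        with pytest.raises(ValueError):
            kmedoids_cluster(d, 6, seed=0)

    def test_deterministic_given_seed(self):
        rows, _ = planted_rows(3, 8, 10, 0.3, seed=3)
        d = correlation_distance_matrix(rows)
        out1 = kmedoids_cluster(d, 3, seed=5)
        out2 = kmedoids_cluster(d, 3, seed=5)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_exhaustive_swap_oracle(self, seed):
        from mpcms1.kmedoids import _kmedoidspp_init

        rng = np.random.default_rng(seed)
        rows = rng.normal(size=(12, 6))
        d = correlation_distance_matrix(rows)
        init = _kmedoidspp_init(d, 3, np.random.default_rng(seed))
        labels, medoids = kmedoids_cluster(d, 3, seed=seed)
        assert pam_cost(d, labels, medoids) == pytest.approx(naive_pam(d, init), abs=1e-9)

    def test_medoid_labels_its_own_module(self):
        rows, _ = planted_rows(4, 6, 10, 0.2, seed=6)
        d = correlation_distance_matrix(rows)
        labels, medoids = kmedoids_cluster(d, 4, seed=1)
        for c, m in enumerate(medoids):
            assert labels[m] == c


class TestSelectK:
    def test_recovers_planted_module_count(self):
        rows, _ = planted_rows(12, 25, 26, 0.15, seed=7)
        d = correlation_distance_matrix(rows)
        fc = select_k(d, range(10, 51), seed=0)
        assert fc.chosen_k == 12

    def test_chosen_k_has_max_silhouette(self):
        rows, _ = planted_rows(3, 10, 8, 0.4, seed=8)
        d = correlation_distance_matrix(rows)
        fc = select_k(d, range(2, 8), seed=0)
        assert fc.silhouette_by_k[fc.chosen_k] == max(fc.silhouette_by_k.values())

    def test_singleton_range_forced(self):
        rows, _ = planted_rows(2, 8, 8, 0.1, seed=9)
        d = correlation_distance_matrix(rows)
        fc = select_k(d, [2], seed=0)
        assert fc.chosen_k == 2

    def test_empty_range_errors(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            select_k(d, [], seed=0)
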