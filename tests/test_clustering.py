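import itertools

import numpy as np
import pandas as pd
import pytest

from morphodelim import (
    DistanceMatrix,
    MorphometryError,
    Partition,
    agglomerate,
    compare_partitions,
    euclidean_distances,
    gap_statistic,
    kmeans_partition,
    nmds,
    part,
)


def dm(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [chr(65 + i) for i in range(values.shape[0])]
    return DistanceMatrix(ids=list(ids), values=values)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_upgma_cophenetic(D):
    """O(n^3) UPGMA: returns the cophenetic matrix of merge heights."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def scipy_cophenetic(dend, n):
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform

    return squareform(cophenet(dend.merge_matrix))


def best_two_partition_wss(X):
    """Exhaustive best 2-partition by within-cluster sum of squares."""
    n = X.shape[0]
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):
        sel = np.array([(mask >> i) & 1 for i in range(n)], bool)
        if sel.all() or (~sel).all():
            continue
        w = 0.0
        for part_sel in (sel, ~sel):
            sub = X[part_sel]
            w += ((sub - sub.mean(0)) ** 2).sum()
        best = min(best, w)
    return best


# ---------------------------------------------------------------------------


class TestEuclideanDistances:
    def test_identical_rows_zero(self):
        d = euclidean_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.values[0, 1] == 0

    def test_three_four_five(self):
        d = euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_brute_force_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        d = euclidean_distances(X)
        for i in range(5):
            for j in range(5):
                assert d.values[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), rel=1e-12
                )

    def test_standardize_columns(self, rng):
        X = rng.normal(size=(10, 2)) * np.array([1.0, 1000.0])
        d = euclidean_distances(X, standardize=True)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert d.values[0, 1] == pytest.approx(np.linalg.norm(Z[0] - Z[1]))

    def test_too_few_items(self):
        with pytest.raises(MorphometryError):
            euclidean_distances(np.array([[1.0, 2.0]]))


class TestAgglomerate:
    def test_two_items_merge_at_distance(self):
        dend = agglomerate(dm([[0, 3.5], [3.5, 0]]), "UPGMA")
        assert dend.heights[-1] == pytest.approx(3.5)

    def test_three_item_hand_case(self):
        dend = agglomerate(dm([[0, 2, 6], [2, 0, 6], [6, 6, 0]]), "UPGMA")
        assert list(dend.heights) == pytest.approx([2.0, 6.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(4, 9), 3))
        d = euclidean_distances(X)
        dend = agglomerate(d, "UPGMA")
        np.testing.assert_allclose(
            scipy_cophenetic(dend, X.shape[0]),
            naive_upgma_cophenetic(d.values),
            rtol=1e-9, atol=1e-12,
        )

    def test_upgma_heights_monotone(self, rng):
        X = rng.normal(size=(8, 4))
        dend = agglomerate(euclidean_distances(X), "UPGMA")
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_ward_runs_and_is_monotone(self, rng):
        X = rng.normal(size=(8, 4))
        dend = agglomerate(euclidean_distances(X), "Ward")
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_newick_has_all_leaves(self, rng):
        import dendropy

        X = rng.normal(size=(6, 2))
        dend = agglomerate(euclidean_distances(X), "UPGMA")
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(dend.ids)

    def test_cut_gives_k_clusters(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, (4, 2)), rng.normal(8, 0.1, (4, 2))])
        p = agglomerate(euclidean_distances(X), "UPGMA").cut(2)
        assert p.k == 2


class TestKMeans:
    def test_k_equals_n(self, rng):
        X = rng.normal(size=(5, 2))
        p = kmeans_partition(X, k=5, seed=0)
        assert p.k == 5
        assert p.metadata["wss"] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_separated_pairs_and_matches_exhaustive(self, rng):
        X = np.concatenate([rng.normal(0, 0.3, (4, 2)), rng.normal(10, 0.3, (4, 2))])
        p = kmeans_partition(X, k=2, seed=1, n_init=20)
        assert p.metadata["wss"] == pytest.approx(best_two_partition_wss(X), rel=1e-9)
        clusters = {p.labels[str(i)] for i in range(4)}
        assert len(clusters) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_exhaustive_oracle_random_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(7, 2))
        p = kmeans_partition(X, k=2, seed=seed, n_init=50)
        assert p.metadata["wss"] == pytest.approx(best_two_partition_wss(X), rel=1e-9)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(12, 3))
        a = kmeans_partition(X, k=3, seed=7)
        b = kmeans_partition(X, k=3, seed=7)
        assert a.labels == b.labels

    def test_invalid_k(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(MorphometryError):
            kmeans_partition(X, k=0)
        with pytest.raises(MorphometryError):
            kmeans_partition(X, k=5)


class TestGapStatistic:
    def test_single_blob_mostly_one_cluster(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 2))
            if gap_statistic(X, k_max=4, b=30, base="kmeans", seed=seed).chosen_k == 1:
                hits += 1
        assert hits >= 18

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, (20, 2)), rng.normal(10, 1, (20, 2))])
        g = gap_statistic(X, k_max=4, b=50, base="kmeans", seed=0)
        assert g.chosen_k == 2

    def test_log_wk_matches_direct_dispersion(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        g = gap_statistic(X, k_max=3, b=2, base="kmeans", seed=3)
        # k = 1 dispersion is label-free: direct formula check
        w1 = ((X - X.mean(0)) ** 2).sum()
        assert g.log_wk[0] == pytest.approx(np.log(w1), rel=1e-12)

    def test_degenerate_data_warns_and_chooses_one(self):
        X = np.ones((10, 3))
        with pytest.warns(UserWarning):
            g = gap_statistic(X, k_max=3, b=5, base="kmeans", seed=0)
        assert g.chosen_k == 1


class TestPart:
    def test_split_impossible_below_twice_min_size(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 0.1, (4, 2)), rng.normal(50, 0.1, (4, 2))])
        p = part(X, base="kmeans", b=10, min_size=5, seed=0)
        assert p.k == 1

    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        X = np.concatenate([rng.normal(c, 1.0, (10, 2)) for c in centers])
        p = part(X, base="kmeans", b=50, min_size=5, seed=1)
        assert p.k == 3

    def test_min_size_respected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(23, 3))
        p = part(X, base="kmeans", b=20, min_size=5, seed=4)
        assert all(len(v) >= 5 for v in p.members().values())

    def test_bit_reproducible(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(0, 1, (12, 2)), rng.normal(9, 1, (12, 2))])
        a = part(X, base="hclust", b=25, min_size=5, seed=11)
        b = part(X, base="hclust", b=25, min_size=5, seed=11)
        assert a.labels == b.labels and a.k == b.k

    def test_hclust_base_on_separated_blobs(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(0, 1, (15, 2)), rng.normal(12, 1, (15, 2))])
        p = part(X, base="hclust", b=50, min_size=5, seed=2)
        assert p.k == 2


class TestNMDS:
    def test_embeddable_configuration_low_stress(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 2))
        emb = nmds(euclidean_distances(X), dims=2, seed=0, restarts=4)
        assert emb.stress < 0.01
        assert 0.0 <= emb.stress <= 1.0

    def test_monotone_transform_preserves_rank_order(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        d = euclidean_distances(X)
        d2 = DistanceMatrix(ids=d.ids, values=d.values**1.7)
        e1 = nmds(d, seed=3, restarts=6)
        e2 = nmds(d2, seed=3, restarts=6)

        def ranks(emb):
            from scipy.spatial.distance import pdist
            from scipy.stats import rankdata

            return rankdata(pdist(emb.coords.to_numpy()))

        rho = np.corrcoef(ranks(e1), ranks(e2))[0, 1]
        assert rho > 0.95

    def test_too_few_items(self):
        with pytest.raises(MorphometryError):
            nmds(dm([[0, 1], [1, 0]]), dims=2)


class TestComparePartitions:
    def test_identical_partitions(self):
        truth = {f"i{j}": "a" if j < 5 else "b" for j in range(10)}
        p = Partition(labels={k: 1 if v == "a" else 2 for k, v in truth.items()}, k=2)
        rep = compare_partitions(p, truth)
        assert rep.n_misassigned == 0
        assert rep.agreement == 1.0

    def test_single_flip_of_52(self):
        truth = {f"n{j}": "a" if j < 35 else "b" for j in range(52)}
        labels = {k: 1 if v == "a" else 2 for k, v in truth.items()}
        labels["n0"] = 2
        rep = compare_partitions(Partition(labels=labels, k=2), truth)
        assert rep.n_misassigned == 1
        assert rep.misassigned == ["n0"]

    def test_random_labels_near_half_agreement(self):
        agreements = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            truth = {f"i{j}": ("a", "b")[j % 2] for j in range(20)}
            draw = rng.integers(1, 3, 20)
            if len(set(draw)) < 2:
                continue
            p = Partition(labels={k: int(c) for k, c in zip(truth, draw)}, k=2)
            agreements.append(compare_partitions(p, truth).agreement)
        assert 0.45 < np.mean(agreements) < 0.75

    def test_item_mismatch_rejected(self):
        p = Partition(labels={"a": 1, "b": 2}, k=2)
        with pytest.raises(MorphometryError):
            compare_partitions(p, {"a": "x", "c": "y"})
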