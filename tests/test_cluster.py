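"""Tocher grouping, UPGMA dendrograms and the Mojena cutoff."""

import numpy as np
import pandas as pd
import pytest

from phenodiv.cluster import MergeTree, cophenetic, mojena_cut, tocher, upgma
from phenodiv.distance import DistanceMatrix


def dist_from(labels, entries, default=0.0):
    n = len(labels)
    d = np.full((n, n), default, float)
    np.fill_diagonal(d, 0.0)
    for (a, b), v in entries.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(list(labels), d, "custom")


def chain_tree(heights):
    """Caterpillar dendrogram with the given fusion heights."""
    n = len(heights) + 1
    labels = [f"g{i}" for i in range(n)]
    z = []
    current = 0  # node index of the growing cluster
    for i, h in enumerate(heights):
        z.append([current, i + 1, h, i + 2])
        current = n + i
    return MergeTree(labels=labels, linkage=np.array(z, float))


class TestTocher:
    def test_two_planted_pairs_recovered(self):
        d = dist_from(
            ["A", "B", "C", "D"], {("A", "B"): 1.0, ("C", "D"): 1.0}, default=100.0
        )
        res = tocher(d)
        assert sorted(map(sorted, res.groups)) == [["A", "B"], ["C", "D"]]

    def test_all_equal_distances_form_one_group(self):
        labels = list("ABCDE")
        d = dist_from(labels, {}, default=3.0)
        res = tocher(d)
        assert res.n_groups == 1
        assert sorted(res.groups[0]) == labels

    def test_hand_traced_four_point_example(self):
        d = dist_from(
            ["A", "B", "C", "D"], {("A", "B"): 1.0, ("C", "D"): 2.0}, default=50.0
        )
        res = tocher(d)
        assert res.groups[0] == ["A", "B"]  # seeded with the closest pair
        assert res.groups[1] == ["C", "D"]
        assert res.theta == pytest.approx(2.0)
        assert res.within_means == [pytest.approx(1.0), pytest.approx(2.0)]

    def test_partition_property_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 12))
            x = rng.normal(size=(n, 3))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            labels = [f"g{i}" for i in range(n)]
            res = tocher(DistanceMatrix(labels, d, "euclid"))
            flat = sorted(g for grp in res.groups for g in grp)
            assert flat == sorted(labels)  # every genotype exactly once

    def test_singleton_input(self):
        res = tocher(DistanceMatrix(["A"], np.zeros((1, 1)), "x"))
        assert res.groups == [["A"]]

    def test_recovery_invariant_to_scale(self):
        labels = ["A", "B", "C", "D", "E", "F"]
        base = dist_from(
            labels,
            {("A", "B"): 1.0, ("A", "C"): 1.0, ("B", "C"): 1.0,
             ("D", "E"): 1.0, ("D", "F"): 1.0, ("E", "F"): 1.0},
            default=100.0,
        )
        for scale in (0.01, 1.0, 250.0):
            res = tocher(DistanceMatrix(labels, base.values * scale, "x"))
            assert sorted(map(sorted, res.groups)) == [list("ABC"), list("DEF")]


class TestUpgma:
    def test_three_leaf_example(self):
        d = dist_from(["A", "B", "C"], {("A", "B"): 2.0, ("A", "C"): 8.0,
                                        ("B", "C"): 8.0})
        tree = upgma(d)
        assert tree.heights == pytest.approx([2.0, 8.0])

    def test_heights_non_decreasing_on_random_input(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 15))
            x = rng.normal(size=(n, 4))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            tree = upgma(DistanceMatrix([f"g{i}" for i in range(n)], d, "e"))
            h = tree.heights
            assert len(h) == n - 1
            assert np.all(np.diff(h) >= -1e-12)

    def test_ultrametric_input_reproduced_by_cophenetic(self):
        """On an ultrametric matrix UPGMA is exact: cophenetic == input."""
        labels = ["A", "B", "C", "D"]
        d = dist_from(
            labels,
            {("A", "B"): 2.0, ("C", "D"): 3.0, ("A", "C"): 9.0, ("A", "D"): 9.0,
             ("B", "C"): 9.0, ("B", "D"): 9.0},
        )
        tree = upgma(d)
        coph = cophenetic(tree)
        assert np.allclose(coph.values, d.values, atol=1e-12)

    def test_newick_roundtrip_depths(self):
        d = dist_from(["A", "B", "C"], {("A", "B"): 2.0, ("A", "C"): 8.0,
                                        ("B", "C"): 8.0})
        nwk = upgma(d).to_newick()
        assert nwk.endswith(";")
        assert "A:1" in nwk and "B:1" in nwk  # leaf depth = height/2
        assert "C:4" in nwk


class TestMojena:
    def test_equal_heights_one_group(self):
        tree = chain_tree([2.0, 2.0, 2.0])
        cut = mojena_cut(tree, c=1.25)
        assert cut.sd_height == pytest.approx(0.0)
        assert cut.cutoff == pytest.approx(2.0)
        assert cut.n_groups == 1

    def test_hand_worked_example(self):
        """heights {1,2,3,10}, c=1.25 -> cutoff 9.103, top merge cut, 2 groups."""
        tree = chain_tree([1.0, 2.0, 3.0, 10.0])
        cut = mojena_cut(tree, c=1.25)
        assert cut.mean_height == pytest.approx(4.0)
        assert cut.sd_height == pytest.approx(np.std([1, 2, 3, 10], ddof=1))
        assert cut.cutoff == pytest.approx(4.0 + 1.25 * 4.08248, abs=1e-4)
        assert cut.n_groups == 2

    def test_limits_in_c(self):
        tree = chain_tree([1.0, 2.0, 3.0, 10.0])
        assert mojena_cut(tree, c=100.0).n_groups == 1
        assert mojena_cut(tree, c=-100.0).n_groups == 5

    def test_group_count_monotone_non_increasing_in_c(self, rng):
        x = rng.normal(size=(12, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        tree = upgma(DistanceMatrix([f"g{i}" for i in range(12)], d, "e"))
        counts = [mojena_cut(tree, c=c).n_groups for c in np.linspace(-3, 3, 13)]
        assert counts == sorted(counts, reverse=True)

    def test_cut_count_matches_cluster_labels(self):
        tree = chain_tree([1.0, 2.0, 3.0, 10.0])
        cut = mojena_cut(tree, c=1.25)
        assert cut.clusters.nunique() == cut.n_groups
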