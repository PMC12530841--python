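"""Distances, UPGMA, Newick export, cluster cuts, duplicates and PCoA."""

import itertools

import numpy as np
import pandas as pd
import pytest

import germdiv as gd
from germdiv.clustering import pcoa_from_distance
from germdiv.ssr import GenotypeMatrix


def random_distance_matrix(n, rng):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return gd.DistanceMatrix([f"x{i:02d}" for i in range(n)], d, "euclidean")


def leaf_depths(node, acc=0.0, parent_h=None):
    """Root-to-leaf path lengths of a dendrogram."""
    out = {}

    def walk(nd, depth):
        if not nd.children:
            out[nd.label] = depth
        for c in nd.children:
            walk(c, depth + (nd.height - c.height))

    walk(node, 0.0)
    return out


class TestGeneticDistance:
    def test_identical_genotypes_zero(self, small_genotypes):
        dm = gd.genetic_distance_matrix(small_genotypes)
        assert dm.d[0, 1] == 0.0

    def test_single_shared_copy_half(self):
        a1 = np.array([[100], [100]])
        a2 = np.array([[100], [102]])
        gm = GenotypeMatrix(["x", "y"], ["L1"], a1, a2)
        dm = gd.genetic_distance_matrix(gm)
        assert dm.d[0, 1] == pytest.approx(0.5)

    def test_disjoint_alleles_one(self):
        a1 = np.array([[100, 200], [104, 204]])
        a2 = np.array([[102, 202], [106, 206]])
        gm = GenotypeMatrix(["x", "y"], ["L1", "L2"], a1, a2)
        dm = gd.genetic_distance_matrix(gm)
        assert dm.d[0, 1] == 1.0

    def test_bounded_and_symmetric(self):
        gm, _ = gd.simulate_populations(gd.PopSimConfig(
            group_sizes=(20, 20), n_loci=10, missing_rate=0.05, seed=3))
        dm = gd.genetic_distance_matrix(gm)
        assert (dm.d >= 0).all() and (dm.d <= 1).all()
        assert np.allclose(dm.d, dm.d.T)

    def test_nei_individual_zero_for_identical(self, small_genotypes):
        dm = gd.genetic_distance_matrix(small_genotypes, method="nei_individual")
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestTraitDistance:
    def test_identical_rows_zero_and_unit_sd_offset(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(1, 6, size=(20, 4)).astype(float)
        arr[1] = arr[0]
        codes = pd.DataFrame(arr, index=[f"A{i}" for i in range(20)],
                             columns=[f"T{j}" for j in range(4)])
        desc = {t: gd.TraitDescriptor(t, t, "qualitative", (1, 2, 3, 4, 5))
                for t in codes.columns}
        table = gd.TraitTable(codes=codes, descriptors=desc)
        dm = gd.trait_distance_matrix(table)
        assert dm.d[0, 1] == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        arr = rng.integers(1, 8, size=(10, 5)).astype(float)
        codes = pd.DataFrame(arr, index=[f"A{i}" for i in range(10)],
                             columns=[f"T{j}" for j in range(5)])
        desc = {t: gd.TraitDescriptor(t, t, "qualitative", tuple(range(1, 8)))
                for t in codes.columns}
        table = gd.TraitTable(codes=codes, descriptors=desc)
        dm = gd.trait_distance_matrix(table)
        z = (codes - codes.mean()) / codes.std(ddof=1)
        for i in range(10):
            for j in range(10):
                expect = np.sqrt(((z.iloc[i] - z.iloc[j]) ** 2).sum())
                assert dm.d[i, j] == pytest.approx(expect, abs=1e-9)


class TestUpgma:
    def test_three_leaf_hand_computed_tree(self):
        dm = gd.DistanceMatrix(["A", "B", "C"],
                               np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                               "toy")
        tree = gd.upgma(dm)
        assert gd.write_newick(tree) == "((A:1,B:1):1,C:2);"

    def test_two_leaves_half_distance(self):
        dm = gd.DistanceMatrix(["A", "B"], np.array([[0, 3.0], [3.0, 0]]), "toy")
        tree = gd.upgma(dm)
        assert tree.root.height == pytest.approx(1.5)

    def test_ultrametric_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            tree = gd.upgma(random_distance_matrix(n, rng))
            depths = leaf_depths(tree.root)
            vals = list(depths.values())
            assert max(vals) - min(vals) < 1e-9

    def test_row_order_invariance(self):
        rng = np.random.default_rng(6)
        dm = random_distance_matrix(8, rng)
        perm = rng.permutation(8)
        dm2 = gd.DistanceMatrix([dm.ids[i] for i in perm],
                                dm.d[np.ix_(perm, perm)], "euclidean")
        assert gd.write_newick(gd.upgma(dm)) == gd.write_newick(gd.upgma(dm2))

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(7)
        dm = random_distance_matrix(12, rng)
        tree = gd.upgma(dm)
        ours = sorted(gd.Dendrogram(tree.root).internal_heights())
        scipy_heights = sorted(linkage(squareform(dm.d), method="average")[:, 2] / 2)
        assert np.allclose(ours, scipy_heights, atol=1e-9)


class TestNewick:
    def test_single_leaf(self):
        tree = gd.Dendrogram(root=gd.clustering.TreeNode(label="A"))
        assert gd.write_newick(tree) == "A;"

    def test_metacharacter_labels_quoted(self):
        from germdiv.clustering import TreeNode
        t = gd.Dendrogram(TreeNode(height=1.0, children=(
            TreeNode(label="a b"), TreeNode(label="c:d"))))
        text = gd.write_newick(t)
        assert "'a b'" in text and "'c:d'" in text

    def test_roundtrip_against_skbio_parser(self, tmp_path):
        import io
        import skbio
        rng = np.random.default_rng(8)
        for rep in range(100):
            n = int(rng.integers(2, 12))
            tree = gd.upgma(random_distance_matrix(n, rng))
            text = gd.write_newick(tree)
            parsed = skbio.TreeNode.read(io.StringIO(text))
            ours = leaf_depths(tree.root)
            for tip in parsed.tips():
                assert parsed.distance(tip) == pytest.approx(ours[tip.name], abs=1e-9)


class TestCutClusters:
    @pytest.fixture
    def toy_tree(self):
        dm = gd.DistanceMatrix(["A", "B", "C"],
                               np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                               "toy")
        return gd.upgma(dm)

    def test_k_extremes(self, toy_tree):
        assert set(gd.cut_clusters(toy_tree, 1).values()) == {1}
        single = gd.cut_clusters(toy_tree, 3)
        assert len(set(single.values())) == 3

    def test_k_two_partition(self, toy_tree):
        assign = gd.cut_clusters(toy_tree, 2)
        assert assign["A"] == assign["B"] != assign["C"]
        # numbered by decreasing size
        assert assign["A"] == 1

    def test_k_out_of_range(self, toy_tree):
        with pytest.raises(ValueError):
            gd.cut_clusters(toy_tree, 4)


class TestDuplicates:
    def test_all_distinct(self):
        rng = np.random.default_rng(9)
        dm = random_distance_matrix(6, rng)
        rep = gd.find_duplicates(dm)
        assert rep.groups == [] and rep.n_distinct == 6 and rep.n_redundant == 0

    def test_planted_clone_pair(self):
        gm, truth = gd.simulate_populations(gd.PopSimConfig(
            group_sizes=(30, 30), n_loci=15, clone_pairs=1, seed=10))
        rep = gd.find_duplicates(gd.genetic_distance_matrix(gm))
        assert rep.groups == [sorted(truth["clone_groups"][0])]

    def test_three_mutual_clones(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = d[0, 2] = d[2, 0] = d[1, 2] = d[2, 1] = 0.0
        dm = gd.DistanceMatrix(["a", "b", "c", "d"], d, "toy")
        rep = gd.find_duplicates(dm)
        assert rep.groups == [["a", "b", "c"]]
        assert rep.n_redundant == 2

    def test_negative_threshold_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            gd.find_duplicates(random_distance_matrix(4, rng), threshold=-0.1)

    def test_matches_genotype_string_oracle(self, fixture_bundle):
        gm = fixture_bundle["genotypes"]
        rep = gd.find_duplicates(gd.genetic_distance_matrix(gm))
        strings = {}
        for i, acc in enumerate(gm.accessions):
            key = tuple(zip(gm.a1[i], gm.a2[i]))
            strings.setdefault(key, []).append(acc)
        oracle = sorted((sorted(v) for v in strings.values() if len(v) > 1),
                        key=lambda g: (-len(g), g[0]))
        assert rep.groups == oracle
        assert rep.n_distinct == len(strings)
        assert rep.n_distinct + rep.n_redundant == rep.n_total


class TestHomonyms:
    def test_clones_sharing_name_not_flagged(self):
        d = np.array([[0.0, 0.0], [0.0, 0.0]])
        dm = gd.DistanceMatrix(["a", "b"], d, "toy")
        rep = gd.find_homonyms({"a": "Same", "b": "Same"}, dm)
        assert rep.flagged == {}

    def test_distinct_genotypes_sharing_name_flagged(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        dm = gd.DistanceMatrix(["a", "b"], d, "toy")
        rep = gd.find_homonyms({"a": "Same", "b": "Same"}, dm)
        assert list(rep.flagged) == ["Same"]

    def test_planted_homonym_groups(self, fixture_bundle):
        gm = fixture_bundle["genotypes"]
        dm = gd.genetic_distance_matrix(gm)
        rep = gd.find_homonyms(fixture_bundle["names"], dm)
        assert sorted(rep.flagged) == sorted(
            fixture_bundle["truth"]["population"]["homonym_names"])

    def test_missing_accession_rejected(self):
        dm = gd.DistanceMatrix(["a"], np.zeros((1, 1)), "toy")
        with pytest.raises(ValueError, match="absent"):
            gd.find_homonyms({"zz": "Name"}, dm)


class TestPcoa:
    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, explained = pcoa_from_distance(gd.DistanceMatrix(["a", "b", "c"], d, "t"))
        assert explained[0] == pytest.approx(explained[1], abs=1e-9)

    def test_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(12)
        dm = random_distance_matrix(8, rng)
        coords, _ = pcoa_from_distance(dm)
        rec = np.sqrt(((coords.to_numpy()[:, None, :]
                        - coords.to_numpy()[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, dm.d, atol=1e-9)

    def test_agrees_with_skbio_pcoa(self):
        import skbio
        rng = np.random.default_rng(13)
        dm = random_distance_matrix(10, rng)
        ours, explained = pcoa_from_distance(dm)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm.d, dm.ids))
        np.testing.assert_allclose(
            np.sort(np.abs(ours.iloc[:, 0])),
            np.sort(np.abs(ref.samples.iloc[:, 0].to_numpy())), atol=1e-8)
        assert explained[0] == pytest.approx(
            ref.proportion_explained.iloc[0], abs=1e-9)

    def test_separates_planted_groups(self):
        from sklearn.metrics import silhouette_score
        gm, truth = gd.simulate_populations(gd.PopSimConfig(
            group_sizes=(30, 30, 30), n_loci=19, fst=0.25, seed=5))
        with pytest.warns(UserWarning, match="negative"):
            coords, _ = gd.genotype_pca(gm)
        labels = [truth["group_labels"][a] for a in coords.index]
        assert silhouette_score(coords.iloc[:, :2], labels) > 0.5
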