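"""Distances (allele sharing, Nei, sharing-count) and tree building."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from cnvpop.io import (
    load_shared_breakpoint_counts,
    read_newick,
    tree_to_newick,
    write_newick,
)
from cnvpop.model import DistanceMatrix, FrequencyTable
from cnvpop.phylo import (
    allele_sharing_distance,
    build_nj,
    build_upgma,
    consensus_tree,
    is_ultrametric,
    leaf_labels,
    nei_distance,
    nei_distance_cn,
    nei_distance_matrix,
    patristic_matrix,
    root_to_leaf_depths,
    sharing_to_distance,
    trees_isomorphic,
    upgma_merge_order,
)


def dm_from_tree(newick: str) -> DistanceMatrix:
    """Additive distance matrix computed from a tree's path lengths."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return patristic_matrix(tree)


class TestAlleleSharing:
    def test_identical_individuals(self):
        v = np.array([[0, 1, 0, 1]])
        assert allele_sharing_distance(v, v) == 0.0

    def test_fully_mismatched(self):
        assert allele_sharing_distance([[0, 0, 0]], [[1, 1, 1]]) == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, size=(3, 4))
        b = rng.integers(0, 2, size=(2, 4))
        brute = np.mean(
            [np.mean(a[i] != b[j]) for i in range(3) for j in range(2)]
        )
        assert allele_sharing_distance(a, b) == pytest.approx(brute)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            allele_sharing_distance([[0, 1]], [[0, 1, 1]])

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            allele_sharing_distance(np.empty((0, 3)), [[0, 1, 0]])


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        for f in ([0.2, 0.9, 0.5], [1.0, 0.0], [0.33]):
            assert nei_distance(f, f) == 0.0

    def test_symmetric(self):
        a, b = [0.1, 0.6, 0.9], [0.4, 0.2, 0.8]
        assert nei_distance(a, b) == pytest.approx(nei_distance(b, a))

    def test_hand_evaluated_oracle(self):
        # fA=(0.5,0.5), fB=(1.0,0.5): Jxy=0.5, Jx=0.5, Jy=0.75
        # D = -ln(0.5/sqrt(0.375)) = 0.5*ln(1.5)
        expected = 0.5 * np.log(1.5)
        assert nei_distance([0.5, 0.5], [1.0, 0.5]) == pytest.approx(expected)

    def test_degenerate_opposite_fixation(self):
        with pytest.raises(ValueError, match="degenerate"):
            nei_distance([1.0], [0.0])

    def test_frequency_out_of_range(self):
        with pytest.raises(ValueError):
            nei_distance([1.2], [0.5])

    def test_cn_mode_matches_biallelic_on_two_states(self):
        fa, fb = np.array([0.3, 0.8]), np.array([0.5, 0.6])
        a2 = np.stack([fa, 1 - fa], axis=1)
        b2 = np.stack([fb, 1 - fb], axis=1)
        assert nei_distance_cn(a2, b2) == pytest.approx(nei_distance(fa, fb))

    def test_matrix_is_valid_distance_matrix(self):
        freq = pd.DataFrame(
            {"A": [0.1, 0.5, 0.9], "B": [0.2, 0.5, 0.7], "C": [0.9, 0.1, 0.2]},
            index=["L1", "L2", "L3"],
        )
        ft = FrequencyTable(freq=freq, counts_individuals={p: 10 for p in "ABC"})
        dm = nei_distance_matrix(ft)
        assert dm[("A", "A")] == 0.0
        assert dm[("A", "B")] == pytest.approx(nei_distance(freq["A"], freq["B"]))


class TestSharingToDistance:
    def test_max_pair_gets_zero(self):
        m = load_shared_breakpoint_counts()
        dm = sharing_to_distance(m, "max_minus")
        assert dm[("China_CHB", "Taiwan")] == 0.0

    def test_all_equal_counts_give_equal_distances(self):
        from cnvpop.model import SharingMatrix

        counts = np.full((3, 3), 7.0)
        m = SharingMatrix(["A", "B", "C"], counts)
        for method in ("max_minus", "one_minus_norm"):
            dm = sharing_to_distance(m, method)
            off = [dm[p] for p in itertools.combinations("ABC", 2)]
            assert len(set(off)) == 1

    def test_all_na_rejected(self):
        from cnvpop.model import SharingMatrix

        m = SharingMatrix(["A", "B"], np.full((2, 2), np.nan))
        with pytest.raises(ValueError, match="NA"):
            sharing_to_distance(m)

    def test_closest_pair_in_packaged_matrix(self):
        # the two most-sharing populations end up nearest in distance space
        m = load_shared_breakpoint_counts()
        dm = sharing_to_distance(m)
        off = {
            (a, b): dm[(a, b)]
            for a, b in itertools.combinations(dm.labels, 2)
        }
        assert min(off, key=off.get) == ("China_CHB", "Taiwan")


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        dm = dm_from_tree("((A:1,B:2):1,(C:3,D:4):0);")
        tree = build_nj(dm)
        pm = patristic_matrix(tree)
        assert pm.labels == dm.labels
        assert np.allclose(pm.d, dm.d, atol=1e-9)

    def test_equidistant_three_taxa(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        tree = build_nj(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert all(v == pytest.approx(1.0) for v in lengths.values())

    @pytest.mark.parametrize("n_taxa,seed", [(5, 0), (6, 1), (8, 2)])
    def test_recovers_random_additive_matrices(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        newick = _random_tree_newick(n_taxa, rng)
        dm = dm_from_tree(newick)
        pm = patristic_matrix(build_nj(dm))
        assert np.allclose(pm.d, dm.submatrix(pm.labels).d, atol=1e-8)

    def test_agrees_with_independent_implementation(self):
        # cross-check against scikit-bio's neighbor joining on an additive matrix
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        dm = dm_from_tree(_random_tree_newick(8, rng))
        ours = patristic_matrix(build_nj(dm))
        sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.labels)
        sk_tree = skbio.tree.nj(sk_dm)
        sk = np.array(
            [
                [0.0 if a == b else sk_tree.find(a).distance(sk_tree.find(b)) for b in ours.labels]
                for a in ours.labels
            ]
        )
        assert np.allclose(ours.d, sk, atol=1e-8)

    def test_leaf_set_matches_labels(self):
        rng = np.random.default_rng(9)
        dm = dm_from_tree(_random_tree_newick(8, rng))
        assert leaf_labels(build_nj(dm)) == set(dm.labels)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            build_nj(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


def _random_tree_newick(n_taxa: int, rng: np.random.Generator) -> str:
    """Random binary tree with positive branch lengths (additive oracle)."""
    nodes = [f"T{i}" for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        la, lb = rng.uniform(0.5, 3.0, size=2).round(3)
        merged = f"({a}:{la},{b}:{lb})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def _random_ultrametric_dm(labels, rng) -> DistanceMatrix:
    """Random ultrametric matrix via a random agglomeration of leaves."""
    clusters = [[l] for l in labels]
    h = 0.0
    n = len(labels)
    d = np.zeros((n, n))
    idx = {l: i for i, l in enumerate(labels)}
    while len(clusters) > 1:
        h += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2 * h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return DistanceMatrix(list(labels), d)


class TestUPGMA:
    def test_two_taxa_root_height(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 2], [2, 0]], float))
        tree = build_upgma(dm)
        assert root_to_leaf_depths(tree) == {"A": 1.0, "B": 1.0}

    def test_recovers_ultrametric_four_taxon_matrix(self):
        dm = dm_from_tree("((A:1,B:1):2,(C:2,D:2):1):0;")
        tree = build_upgma(dm)
        pm = patristic_matrix(tree)
        assert np.allclose(pm.d, dm.submatrix(pm.labels).d, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_random_ultrametric_matrices(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"T{i}" for i in range(7)]
        dm = _random_ultrametric_dm(labels, rng)
        pm = patristic_matrix(build_upgma(dm))
        assert np.allclose(pm.d, dm.submatrix(pm.labels).d, atol=1e-9)

    def test_output_always_ultrametric(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 6
            a = rng.uniform(1, 10, size=(n, n))
            d = (a + a.T) / 2
            np.fill_diagonal(d, 0)
            dm = DistanceMatrix([f"T{i}" for i in range(n)], d)
            assert is_ultrametric(build_upgma(dm), tol=1e-9)

    def test_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        n = 7
        a = rng.uniform(1, 10, size=(n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"T{i}" for i in range(n)], d)
        merges = upgma_merge_order(dm)
        z = average(squareform(d))
        assert np.allclose(sorted(m[2] for m in merges), sorted(z[:, 2] / 2), atol=1e-9)

    def test_deterministic_under_ties(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        dm = DistanceMatrix(["B", "A", "C"], d)
        t1 = tree_to_newick(build_upgma(dm))
        t2 = tree_to_newick(build_upgma(dm))
        assert t1 == t2
        assert upgma_merge_order(dm)[0][:2] == ("A", "B")  # lexicographic tie-break

    def test_packaged_matrix_first_merge(self):
        dm = sharing_to_distance(load_shared_breakpoint_counts())
        first = upgma_merge_order(dm)[0]
        assert set(first[:2]) == {"China_CHB", "Taiwan"}


class TestConsensus:
    def test_identical_trees(self):
        t = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        con = consensus_tree([t, t, t], method="strict")
        assert trees_isomorphic(con, t)

    def test_conflicting_trees_give_star(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        con = consensus_tree([t1, t2], method="strict")
        internal = [
            nd for nd in con.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert internal == []  # fully unresolved

    def test_nj_and_upgma_agree_on_ultrametric_input(self):
        rng = np.random.default_rng(4)
        dm = _random_ultrametric_dm([f"T{i}" for i in range(6)], rng)
        nj = build_nj(dm)
        up = build_upgma(dm)
        con = consensus_tree([nj, up], method="strict")
        assert trees_isomorphic(con, nj)
        assert trees_isomorphic(con, up)

    def test_mismatched_leaf_sets_rejected(self):
        t1 = dendropy.Tree.get(data="((A,B),C);", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),D);", schema="newick")
        with pytest.raises(ValueError, match="leaf"):
            consensus_tree([t1, t2])


class TestNewickIO:
    def test_two_leaf_tree_serialization(self, tmp_path):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 2], [2, 0]], float))
        tree = build_upgma(dm)
        s = tree_to_newick(tree)
        assert "A:1.0" in s and "B:1.0" in s and s.endswith(";")

    def test_round_trip_isomorphic_12_leaves(self, tmp_path):
        rng = np.random.default_rng(6)
        tree = dendropy.Tree.get(data=_random_tree_newick(12, rng), schema="newick")
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert trees_isomorphic(tree, back)
        assert np.allclose(
            patristic_matrix(tree).d, patristic_matrix(back).d, atol=1e-9
        )

    def test_zero_length_branch_serialized(self, tmp_path):
        t = dendropy.Tree.get(data="(A:0.0,B:1.0);", schema="newick")
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        assert ":0.0" in path.read_text()
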