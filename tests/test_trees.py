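import numpy as np
import pytest
from skbio import DistanceMatrix

from mlstkit import (AllelicProfile, ProfileTable, cut_tree,
                     distance_from_concatenates, distance_from_profiles,
                     neighbor_joining, upgma)
from mlstkit.errors import FormatError
from mlstkit.trees import is_ultrametric, write_newick

from _oracles import tree_metric


def _profile_table():
    vectors = [(1, 1, 1, 1, 1, 1, 1, 1),
               (1, 1, 1, 1, 1, 1, 1, 2),
               (2, 2, 2, 2, 2, 2, 2, 2)]
    profiles = [AllelicProfile(f"iso{i}", v, st=i + 1)
                for i, v in enumerate(vectors)]
    return ProfileTable(locus_names=tuple(f"l{i}" for i in range(8)),
                        profiles=profiles,
                        st_definitions={v: i + 1
                                        for i, v in enumerate(vectors)})


def _tip_distances(tree):
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


class TestDistances:
    def test_profile_distance_matrix_values(self):
        dm = distance_from_profiles(_profile_table())
        assert dm["ST1", "ST2"] == pytest.approx(0.125)
        assert dm["ST1", "ST3"] == pytest.approx(1.0)
        assert dm["ST1", "ST1"] == 0.0

    def test_concatenate_p_distance(self):
        seqs = {"locA": {"x": "AAAA", "y": "AAAT"},
                "locB": {"x": "CCCC", "y": "CCCG"}}
        dm = distance_from_concatenates(seqs)
        assert dm["x", "y"] == pytest.approx(2 / 8)

    def test_concatenate_missing_taxon_rejected(self):
        seqs = {"locA": {"x": "AAAA", "y": "AAAT"}, "locB": {"x": "CCCC"}}
        with pytest.raises(FormatError, match="missing locus"):
            distance_from_concatenates(seqs)


class TestUpgma:
    def test_two_taxa_join_height(self):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["a", "b"])
        tree = upgma(dm)
        assert tree.find("a").length == pytest.approx(0.2)
        assert tree.find("b").length == pytest.approx(0.2)

    def test_four_taxon_hand_agglomeration(self):
        # d(a,b)=2, d(c,d)=4, cross distances 10 -> ((a,b),(c,d))
        # heights: 1, 2, 5; verified by hand with average linkage
        dm = DistanceMatrix([[0, 2, 10, 10],
                             [2, 0, 10, 10],
                             [10, 10, 0, 4],
                             [10, 10, 4, 0]], ids=list("abcd"))
        tree = upgma(dm)
        d = _tip_distances(tree)
        assert d[("a", "b")] == pytest.approx(2)
        assert d[("c", "d")] == pytest.approx(4)
        assert d[("a", "c")] == pytest.approx(10)
        assert is_ultrametric(tree)

    def test_ultrametric_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 12))
            raw = rng.uniform(0.1, 2.0, size=(n, n))
            sym = (raw + raw.T) / 2
            np.fill_diagonal(sym, 0)
            tree = upgma(DistanceMatrix(sym,
                                        ids=[f"t{i}" for i in range(n)]))
            assert is_ultrametric(tree, tol=1e-9)

    def test_matches_scipy_average_linkage_heights(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform
        n = 10
        raw = rng.uniform(0.5, 3.0, size=(n, n))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0)
        tree = upgma(DistanceMatrix(sym, ids=[f"t{i}" for i in range(n)]))
        heights = sorted(
            round(node.children[0].length
                  + _depth_below(node.children[0]), 9)
            for node in tree.traverse() if not node.is_tip())
        scipy_heights = sorted(round(h / 2, 9)
                               for h in average(squareform(sym))[:, 2])
        assert heights == pytest.approx(scipy_heights)

    def test_invariant_under_taxon_reordering(self, rng):
        n = 8
        raw = rng.uniform(0.1, 2.0, size=(n, n))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0)
        ids = [f"t{i}" for i in range(n)]
        tree1 = upgma(DistanceMatrix(sym, ids=ids))
        perm = rng.permutation(n)
        tree2 = upgma(DistanceMatrix(sym[np.ix_(perm, perm)],
                                     ids=[ids[i] for i in perm]))
        d1 = _tip_distances(tree1)
        d2 = _tip_distances(tree2)
        for key in d1:
            assert d1[key] == pytest.approx(d2[key], abs=1e-9)


def _depth_below(node):
    if node.is_tip():
        return 0.0
    child = node.children[0]
    return child.length + _depth_below(child)


class TestNeighborJoining:
    def test_reconstructs_additive_metrics_exactly(self, rng):
        for _ in range(15):
            taxa, dmat, _ = tree_metric(6, rng)
            mat = np.zeros((6, 6))
            for i, a in enumerate(taxa):
                for j, b in enumerate(taxa):
                    if i != j:
                        mat[i, j] = dmat[frozenset((a, b))]
            tree = neighbor_joining(DistanceMatrix(mat, ids=taxa))
            d = _tip_distances(tree)
            for (a, b), val in d.items():
                assert val == pytest.approx(dmat[frozenset((a, b))],
                                            abs=1e-9)

    def test_agrees_with_skbio_nj(self, rng):
        from skbio.tree import nj
        taxa, dmat, _ = tree_metric(7, rng)
        mat = np.zeros((7, 7))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    mat[i, j] = dmat[frozenset((a, b))]
        dm = DistanceMatrix(mat, ids=taxa)
        ours = _tip_distances(neighbor_joining(dm))
        theirs = _tip_distances(nj(dm))
        for key in ours:
            assert ours[key] == pytest.approx(theirs[key], abs=1e-6)

    def test_negative_branches_clamped_with_warning(self):
        dm = DistanceMatrix([[0, 1, 1, 10],
                             [1, 0, 2, 9],
                             [1, 2, 0, 1],
                             [10, 9, 1, 0]], ids=list("abcd"))
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(dm)
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


class TestCutTree:
    def _tree(self):
        dm = DistanceMatrix([[0, 0.1, 0.9, 0.9],
                             [0.1, 0, 0.9, 0.9],
                             [0.9, 0.9, 0, 0.2],
                             [0.9, 0.9, 0.2, 0]], ids=list("abcd"))
        return upgma(dm)

    def test_k1_single_group(self):
        assert cut_tree(self._tree(), 1) == [["a", "b", "c", "d"]]

    def test_kn_singletons(self):
        assert cut_tree(self._tree(), 4) == [["a"], ["b"], ["c"], ["d"]]

    def test_two_cut_recovers_structure(self):
        assert cut_tree(self._tree(), 2) == [["a", "b"], ["c", "d"]]

    def test_planted_two_cluster_profiles(self, rng):
        # two clusters of profiles sharing most alleles within cluster
        vecs = []
        for base in ((1,) * 8, (5,) * 8):
            for i in range(4):
                v = list(base)
                v[i] = base[0] + 1
                vecs.append(tuple(v))
        profiles = [AllelicProfile(f"iso{i}", v, st=i + 1)
                    for i, v in enumerate(vecs)]
        table = ProfileTable(
            locus_names=tuple(f"l{i}" for i in range(8)),
            profiles=profiles,
            st_definitions={v: i + 1 for i, v in enumerate(vecs)})
        tree = upgma(distance_from_profiles(table))
        groups = cut_tree(tree, 2)
        assert sorted(map(len, groups)) == [4, 4]
        assert {"ST1", "ST2", "ST3", "ST4"} in map(set, groups)

    def test_out_of_range_k(self):
        with pytest.raises(FormatError):
            cut_tree(self._tree(), 0)


class TestNewickOutput:
    def test_six_decimal_branch_lengths(self, tmp_path):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["a", "b"])
        path = tmp_path / "t.nwk"
        write_newick(upgma(dm), path)
        text = path.read_text()
        assert text.endswith(";\n")
        assert "a:0.200000" in text and "b:0.200000" in text
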