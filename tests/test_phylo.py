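"""Poisson distances, neighbor joining and bootstrap supports."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famscan.phylo import (DistanceMatrix, MultipleAlignment,
                           SaturationError, bootstrap_supports,
                           distance_matrix, nj_tree, poisson_distance)

aa_row = st.text(alphabet="ARND-", min_size=4, max_size=40)


class TestPoissonDistance:
    def test_identical_rows(self):
        assert poisson_distance("ARND", "ARND") == 0.0

    def test_half_mismatches(self):
        assert poisson_distance("AAAA", "AARR") == \
            pytest.approx(0.693147, abs=1e-6)

    def test_pairwise_deletion_hand_count(self):
        # compared 4 columns (one gapped in A), 1 mismatch: p = 0.25
        assert poisson_distance("AR-ND", "AK-ND") == \
            pytest.approx(0.287682, abs=1e-6)

    def test_all_different_is_saturated(self):
        with pytest.raises(SaturationError):
            poisson_distance("AAAA", "RRRR")

    def test_no_shared_columns_is_undefined(self):
        with pytest.raises(SaturationError):
            poisson_distance("A-", "-A")

    @given(aa_row, aa_row)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        try:
            d1 = poisson_distance(a, b)
        except SaturationError:
            return
        assert d1 == poisson_distance(b, a)
        if d1 == 0.0:
            compared = [(x, y) for x, y in zip(a, b)
                        if x != "-" and y != "-"]
            assert all(x == y for x, y in compared)


def _path_lengths(tree):
    """Leaf-to-leaf path lengths via recursive traversal (oracle)."""
    out = {}

    def walk(node):
        if node.is_leaf():
            return {node.name: 0.0}
        below = {}
        groups = []
        for ch in node.children:
            sub = walk(ch)
            sub = {k: v + (ch.branch_length or 0.0)
                   for k, v in sub.items()}
            groups.append(sub)
            below.update(sub)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for x, dx in groups[i].items():
                    for y, dy in groups[j].items():
                        out[frozenset((x, y))] = dx + dy
        return below

    walk(tree.root)
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
        tree = nj_tree(dm)
        bl = {lf.name: lf.branch_length for lf in tree.leaves()}
        assert bl == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.]])))

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # generating tree: ((A:1,B:2):0.5 internal) (C:1.5, D:2.5)
        true_d = {frozenset("AB"): 3.0, frozenset("AC"): 3.0,
                  frozenset("AD"): 4.0, frozenset("BC"): 4.0,
                  frozenset("BD"): 5.0, frozenset("CD"): 4.0}
        ids = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                mat[i, j] = mat[j, i] = true_d[frozenset(ids[i] + ids[j])]
        tree = nj_tree(DistanceMatrix(ids, mat))
        paths = _path_lengths(tree)
        for key, val in true_d.items():
            assert paths[key] == pytest.approx(val, abs=1e-9)
        assert frozenset("AB") in tree.bipartitions() or \
            frozenset("CD") in tree.bipartitions()

    def test_additive_random_trees_recovered(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = 7
            ids = [f"t{i}" for i in range(n)]
            # oracle: leaf-pair path lengths accumulated while building a
            # random binary tree by recursive splitting
            tree_paths = {}

            def build2(taxa):
                if len(taxa) == 1:
                    return {taxa[0]: 0.0}
                cut = int(rng.integers(1, len(taxa)))
                left = build2(taxa[:cut])
                right = build2(taxa[cut:])
                bl_l = float(rng.uniform(0.05, 1.0))
                bl_r = float(rng.uniform(0.05, 1.0))
                left = {k: v + bl_l for k, v in left.items()}
                right = {k: v + bl_r for k, v in right.items()}
                for x, dx in left.items():
                    for y, dy in right.items():
                        tree_paths[frozenset((x, y))] = dx + dy
                left.update(right)
                return left

            build2(ids)
            mat = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    mat[i, j] = mat[j, i] = \
                        tree_paths[frozenset((ids[i], ids[j]))]
            tree = nj_tree(DistanceMatrix(ids, mat))
            paths = _path_lengths(tree)
            for key, val in tree_paths.items():
                assert paths[key] == pytest.approx(val, abs=1e-9)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(0)
        n = 6
        base = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (base + base.T) / 2 + np.eye(n)  # metric enough for NJ
        np.fill_diagonal(mat, 0.0)
        ids = [f"x{i}" for i in range(n)]
        t1 = nj_tree(DistanceMatrix(ids, mat))
        perm = list(rng.permutation(n))
        ids2 = [ids[i] for i in perm]
        mat2 = mat[np.ix_(perm, perm)]
        t2 = nj_tree(DistanceMatrix(ids2, mat2))
        assert set(t1.bipartitions()) == set(t2.bipartitions())

    def test_matches_biopython_topology(self):
        from Bio.Phylo.TreeConstruction import (DistanceMatrix as BioDM,
                                                DistanceTreeConstructor)
        rng = np.random.default_rng(5)
        n = 6
        ids = [f"s{i}" for i in range(n)]
        base = rng.uniform(0.2, 1.5, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0.0)
        ours = nj_tree(DistanceMatrix(ids, mat)).bipartitions()
        bio_dm = BioDM(names=ids, matrix=[
            [float(mat[i, j]) for j in range(i + 1)] for i in range(n)])
        bio_tree = DistanceTreeConstructor().nj(bio_dm)
        ref = min(ids)
        all_leaves = frozenset(ids)
        bio_bips = set()
        for cl in bio_tree.get_nonterminals():
            below = frozenset(t.name for t in cl.get_terminals())
            if 1 < len(below) < n - 1:
                key = below if ref not in below else all_leaves - below
                bio_bips.add(key)
        assert set(ours) == bio_bips


class TestBootstrap:
    def _aln(self):
        rows = ["MKVLWAALLVTFLAGCQA",
                "MKVLWAALLVTFLAGCQA",
                "MKVHWAELLVAFLAGCQA",
                "MKVHWAELLVAFLAGCQG",
                "QRVNWGSLLVQFLKGCSA",
                "QRVNWGSLLVQFLKGCTA"]
        return MultipleAlignment([f"t{i}" for i in range(6)], rows)

    def test_distinct_clade_gets_full_support(self):
        tree = bootstrap_supports(self._aln(), n_reps=50, seed=1)
        supports = {k: v.support for k, v in tree.bipartitions().items()}
        # t4/t5 differ from everything else at ~half the sites: their
        # bipartition should appear in every replicate
        assert supports[frozenset(["t4", "t5"])] == 100

    def test_supports_in_range_and_deterministic(self):
        t1 = bootstrap_supports(self._aln(), n_reps=100, seed=42)
        t2 = bootstrap_supports(self._aln(), n_reps=100, seed=42)
        s1 = {k: v.support for k, v in t1.bipartitions().items()}
        s2 = {k: v.support for k, v in t2.bipartitions().items()}
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1.values())

    def test_zero_replicates_leaves_tree_unsupported(self):
        tree = bootstrap_supports(self._aln(), n_reps=0, seed=0)
        assert all(v.support is None
                   for v in tree.bipartitions().values())

    def test_full_tree_matches_plain_nj(self):
        aln = self._aln()
        with_boot = bootstrap_supports(aln, n_reps=20, seed=0)
        plain = nj_tree(distance_matrix(aln))
        assert set(with_boot.bipartitions()) == set(plain.bipartitions())
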