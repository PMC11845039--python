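from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from pancomp.genome_io import ProteinSeq
from pancomp.pangenome import cluster_proteins, presence_matrix
from pancomp.taxonomy import (
    alignment_distance_matrix,
    assign_rank_pair,
    concatenate_alignments,
    is_clan,
    nj_tree,
    progressive_align,
    propose_family,
    rank_partition,
    select_marker_hits,
    similarity_to_distance,
)

from _oracles import is_clan_oracle


def random_binary_tree(rng, n_leaves):
    """Random topology with random positive branch lengths, via successive
    joining of subtree newick strings."""
    nodes = [f"t{i}:{rng.uniform(0.1, 1.0):.3f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 1.0):.3f}")
    nwk = nodes[0].rsplit(":", 1)[0] + ";"
    return TreeNode.read(io.StringIO(nwk))


class TestAssignRankPair:
    @pytest.mark.parametrize(
        "s,expected",
        [
            (99.9, "same_species"),  # the two sibling Teetrevirus genomes
            (96.4, "same_species"),
            (95.0, "same_species"),
            (89.0, "same_genus_new_species"),
            (70.0, "same_genus_new_species"),  # boundary inclusive
            (69.99, "distinct_genus"),
            (5.1, "distinct_genus"),
        ],
    )
    def test_demarcation(self, s, expected):
        assert assign_rank_pair(s) == expected

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            assign_rank_pair(bad)


class TestRankPartition:
    def test_two_genome_species(self):
        mat = np.array([[100.0, 96.4], [96.4, 100.0]])
        part = rank_partition(mat, ["KLB24", "KLB28"])
        assert part.genus["KLB24"] == part.genus["KLB28"]
        assert part.species["KLB24"] == part.species["KLB28"]

    def test_single_linkage_chaining(self):
        mat = np.array(
            [[100.0, 80.0, 40.0], [80.0, 100.0, 80.0], [40.0, 80.0, 100.0]]
        )
        part = rank_partition(mat, ["a", "b", "c"])
        assert len(set(part.genus.values())) == 1  # chained through b
        assert len(set(part.species.values())) == 3

    def test_all_distinct(self):
        mat = np.full((3, 3), 10.0)
        np.fill_diagonal(mat, 100.0)
        part = rank_partition(mat, ["a", "b", "c"])
        assert len(set(part.genus.values())) == 3

    def test_asymmetric_rejected(self):
        mat = np.array([[100.0, 80.0], [70.0, 100.0]])
        with pytest.raises(ValueError, match="symmetric"):
            rank_partition(mat, ["a", "b"])

    def test_species_refines_genus_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            m = rng.uniform(0, 100, size=(n, n))
            mat = (m + m.T) / 2
            np.fill_diagonal(mat, 100.0)
            part = rank_partition(mat, [f"g{i}" for i in range(n)])
            # two genomes in one species cluster share a genus cluster
            for a in part.species:
                for b in part.species:
                    if part.species[a] == part.species[b]:
                        assert part.genus[a] == part.genus[b]


class TestSelectMarkerHits:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["genome", "marker", "e_value", "gene"])

    def test_lower_evalue_wins(self):
        t = self._table(
            [("g1", "terL", 1e-5, "a"), ("g1", "terL", 1e-2, "b")]
        )
        out = select_marker_hits(t)
        assert list(out["gene"]) == ["a"]

    def test_boundary_evalue_discarded(self):
        t = self._table([("g1", "terL", 1e-3, "a")])
        assert select_marker_hits(t).empty

    def test_empty_table(self):
        assert select_marker_hits(self._table([])).empty

    def test_tie_broken_by_gene_id(self):
        t = self._table(
            [("g1", "terL", 1e-5, "b"), ("g1", "terL", 1e-5, "a")]
        )
        assert list(select_marker_hits(t)["gene"]) == ["a"]

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ValueError):
            select_marker_hits(self._table([("g1", "terL", 0.0, "a")]))


class TestNjTree:
    def test_additive_four_taxon_recovery(self):
        """Distances from ((A:1,B:2):1,(C:3,D:4)) are additive; NJ must
        reproduce the tree exactly (consistency), checked via the full
        tip-to-tip distance matrix and the AB|CD split."""
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(d, ids)
        td = tree.tip_tip_distances(ids)
        assert np.allclose(td.data, d)
        assert is_clan(tree, {"A", "B"})
        assert is_clan(tree, {"C", "D"})

    def test_three_taxa_star(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(d, ["a", "b", "c"])
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}
        td = tree.tip_tip_distances(["a", "b", "c"])
        assert np.allclose(td.data, d)

    def test_ultrametric_hierarchy_recovered(self):
        """8 taxa in a balanced species/genus/family hierarchy: every
        planted group is a clan of the NJ tree."""
        ids = [f"t{i}" for i in range(8)]
        d = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                if i // 2 == j // 2:
                    d[i, j] = 0.04
                elif i // 4 == j // 4:
                    d[i, j] = 0.4
                else:
                    d[i, j] = 1.2
        tree = nj_tree(d, ids)
        for k in range(4):
            assert is_clan(tree, {f"t{2*k}", f"t{2*k+1}"})
        assert is_clan(tree, {"t0", "t1", "t2", "t3"})
        assert is_clan(tree, {"t4", "t5", "t6", "t7"})

    def test_nan_rejected(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(d, ["a", "b", "c"])

    def test_branch_lengths_nonnegative(self, rng):
        m = rng.uniform(0.1, 1.0, size=(6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(d, [f"t{i}" for i in range(6)])
        assert all(
            (n.length or 0) >= 0 for n in tree.traverse() if n.length is not None
        )


class TestIsClan:
    def test_single_tip(self, rng):
        tree = random_binary_tree(rng, 6)
        assert is_clan(tree, {"t0"})

    def test_all_tips(self, rng):
        tree = random_binary_tree(rng, 6)
        assert is_clan(tree, {f"t{i}" for i in range(6)})

    def test_unknown_tip_rejected(self, rng):
        tree = random_binary_tree(rng, 5)
        with pytest.raises(KeyError):
            is_clan(tree, {"t0", "zzz"})

    def test_agrees_with_exhaustive_rooting_oracle(self, rng):
        """All 2^7 subsets of 10 random 7-leaf trees."""
        from itertools import combinations

        for _ in range(10):
            tree = random_binary_tree(rng, 7)
            leaves = [f"t{i}" for i in range(7)]
            for r in range(1, 8):
                for combo in combinations(leaves, r):
                    tips = set(combo)
                    assert is_clan(tree, tips) == is_clan_oracle(tree, tips)


class TestProposeFamily:
    def _build(self, rng, shared_universal=0):
        AA = "ACDEFGHIKLMNPQRSTVWY"
        rand_prot = lambda n: "".join(AA[i] for i in rng.integers(0, 20, n))
        universal = [rand_prot(90) for _ in range(shared_universal)]
        pool_a = [rand_prot(80) for _ in range(8)]
        pool_b = [rand_prot(80) for _ in range(8)]
        prots = []
        for k in range(4):
            for ci, s in enumerate(pool_a + universal):
                prots.append(ProteinSeq(f"a{ci}|gA{k}", f"gA{k}", s))
            for ci, s in enumerate(pool_b + universal):
                prots.append(ProteinSeq(f"b{ci}|gB{k}", f"gB{k}", s))
        pm = presence_matrix(cluster_proteins(prots))
        return pm

    def _tree(self, clean=True):
        if clean:
            nwk = "(((gA0:1,gA1:1):1,(gA2:1,gA3:1):1):2,((gB0:1,gB1:1):1,(gB2:1,gB3:1):1):2);"
        else:  # candidates interleaved across the two main clades
            nwk = "(((gA0:1,gB1:1):1,(gA2:1,gA3:1):1):2,((gB0:1,gA1:1):1,(gB2:1,gB3:1):1):2);"
        return TreeNode.read(io.StringIO(nwk))

    def test_passing_family(self, rng):
        pm = self._build(rng)
        cands = {f"gA{k}" for k in range(4)}
        nb = [{f"gB{k}" for k in range(4)}]
        prop = propose_family(cands, nb, pm, self._tree())
        assert prop.criterion_a and prop.criterion_b and prop.criterion_c
        assert prop.verdict
        assert prop.core_pct == pytest.approx(100.0)

    def test_non_monophyletic_fails_b(self, rng):
        pm = self._build(rng)
        cands = {f"gA{k}" for k in range(4)}
        nb = [{f"gB{k}" for k in range(4)}]
        prop = propose_family(cands, nb, pm, self._tree(clean=False))
        assert not prop.criterion_b
        assert not prop.verdict

    def test_shared_core_fails_c(self, rng):
        pm = self._build(rng, shared_universal=5)
        cands = {f"gA{k}" for k in range(4)}
        nb = [{f"gB{k}" for k in range(4)}]
        prop = propose_family(cands, nb, pm, self._tree())
        assert prop.shared_core_with_neighbors["neighbor0"] == 5
        assert not prop.criterion_c
        assert not prop.verdict

    def test_overlapping_sets_rejected(self, rng):
        pm = self._build(rng)
        with pytest.raises(ValueError):
            propose_family({"gA0"}, [{"gA0", "gB0"}], pm, self._tree())


class TestMarkerAlignment:
    def test_progressive_align_identical(self):
        seqs = {"a": "MKLV", "b": "MKLV", "c": "MKLV"}
        aln = progressive_align(seqs)
        assert set(aln.values()) == {"MKLV"}

    def test_progressive_align_with_indel(self):
        seqs = {"a": "MKLVANDE", "b": "MKLANDE", "c": "MKLVANDE"}
        aln = progressive_align(seqs)
        widths = {len(s) for s in aln.values()}
        assert len(widths) == 1
        assert aln["a"] == "MKLVANDE"
        assert aln["b"].replace("-", "") == "MKLANDE"

    def test_concatenate_and_distances(self):
        aln1 = {"a": "MKLV", "b": "MKLV"}
        aln2 = {"a": "DE", "b": "DD", "c": "DD"}
        cat = concatenate_alignments([aln1, aln2])
        assert cat["a"] == "MKLVDE"
        assert cat["c"] == "----DD"
        d, ids = alignment_distance_matrix(cat)
        assert ids == ["a", "b", "c"]
        assert d[ids.index("a"), ids.index("b")] == pytest.approx(1 / 6)

    def test_similarity_to_distance(self):
        assert similarity_to_distance(np.array([[100.0]]))[0, 0] == 0.0
        assert similarity_to_distance(np.array([[30.0]]))[0, 0] == pytest.approx(0.7)
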