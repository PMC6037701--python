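"""Sequence pipeline: alignment, Jukes-Cantor distances, UPGMA/WPGMA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anxmorph import sequences as seq
from conftest import clades


class TestFixtures:
    def test_twelve_family_members(self, annexin_records):
        assert len(annexin_records) == 12
        ids = {r.id for r in annexin_records}
        assert len(ids) == 12 and {"ANXA6", "ANXA13"} <= ids

    def test_accessions_and_alphabet(self, annexin_records):
        for r in annexin_records:
            assert r.accession == seq.ANNEXIN_ACCESSIONS[r.id]
            assert set(r.residues) <= set("ARNDCQEGHILKMFPSTWYVX")

    def test_double_core_member_is_longest(self, annexin_records):
        lengths = {r.id: len(r) for r in annexin_records}
        assert max(lengths, key=lengths.get) == "ANXA6"


class TestMultipleAlign:
    def test_identical_sequences_align_gap_free(self):
        recs = [seq.SeqRecord(id="a", residues="MKTAYIAK"), seq.SeqRecord(id="b", residues="MKTAYIAK")]
        aln = seq.multiple_align(recs)
        assert aln.rows == ("MKTAYIAK", "MKTAYIAK")

    def test_matches_exhaustive_pairwise_oracle(self):
        # oracle: Biopython global aligner with the same affine-gap convention
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        aligner.mode = "global"
        best = aligner.align("ACDE", "ACE")[0]
        aln = seq.multiple_align(
            [seq.SeqRecord(id="x", residues="ACDE"), seq.SeqRecord(id="y", residues="ACE")]
        )
        assert aln.rows == (str(best[0]), str(best[1])) == ("ACDE", "AC-E")

    def test_equal_length_rows(self, annexin_records):
        aln = seq.multiple_align(annexin_records[:4])
        assert len({len(r) for r in aln.rows}) == 1

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            seq.multiple_align([seq.SeqRecord(id="a", residues="MKT")])


class TestJukesCantor:
    @staticmethod
    def aln(*rows):
        return seq.Alignment(ids=tuple(f"s{i}" for i in range(len(rows))), rows=tuple(rows))

    def test_identical_rows_zero_distance(self):
        dm = seq.jukes_cantor_distance(self.aln("MKTA", "MKTA"))
        assert dm.d[0, 1] == 0.0

    def test_half_different_sites(self):
        # p = 0.5 -> d = -(19/20) ln(1 - 10/19) ~ 0.710
        dm = seq.jukes_cantor_distance(self.aln("A" * 10 + "C" * 10, "A" * 10 + "D" * 10))
        assert dm.d[0, 1] == pytest.approx(-(19 / 20) * math.log(1 - 10 / 19), rel=1e-12)
        assert dm.d[0, 1] == pytest.approx(0.710, abs=5e-4)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(seq.InfiniteDistanceError):
            seq.jukes_cantor_distance(self.aln("--AA", "CC--"))

    def test_saturated_pair_rejected(self):
        with pytest.raises(seq.InfiniteDistanceError):
            seq.jukes_cantor_distance(self.aln("ACDEFGHIKLMNPQRSTVWY", "CDEFGHIKLMNPQRSTVWYA"))

    def test_pairwise_deletion_skips_gapped_sites(self):
        dm = seq.jukes_cantor_distance(self.aln("AC-E", "ACDE"))
        assert dm.d[0, 1] == 0.0  # the gapped column is not compared

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 90), st.integers(1, 9))
    def test_monotone_in_p(self, n1, delta):
        n2 = min(n1 + delta, 94)
        row = lambda n: "A" * (100 - n) + "C" * n
        ref = "A" * 100
        d1 = seq.jukes_cantor_distance(self.aln(ref, row(n1))).d[0, 1]
        d2 = seq.jukes_cantor_distance(self.aln(ref, row(n2))).d[0, 1]
        assert d2 > d1 or (n1 == n2)


class TestClustering:
    def test_three_taxon_hand_agglomeration(self):
        dm = seq.DistanceMatrix(
            labels=("A", "B", "C"), d=np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
        )
        tree = seq.upgma(dm)
        assert seq.sister_pairs(tree) == {frozenset({"A", "B"})}
        # merge heights 1 then 4
        (inner,) = [c for c in tree.root.children if not c.is_leaf]
        assert inner.height == pytest.approx(1.0)
        assert tree.root.height == pytest.approx(4.0)

    def test_two_taxa_cherry_at_half_distance(self):
        dm = seq.DistanceMatrix(labels=("X", "Y"), d=np.array([[0, 3.0], [3.0, 0]]))
        tree = seq.upgma(dm)
        assert tree.root.height == pytest.approx(1.5)

    def test_weighted_vs_unweighted_final_heights(self):
        # sizes 3 vs 1 at the last merge separate UPGMA from WPGMA:
        # UPGMA: (10+10+4)/3 = 8 -> height 4; WPGMA: (10+4)/2 = 7 -> 3.5
        d = np.array(
            [[0, 2, 3, 10], [2, 0, 3, 10], [3, 3, 0, 4], [10, 10, 4, 0]], float
        )
        dm = seq.DistanceMatrix(labels=("A", "B", "C", "D"), d=d)
        up = seq.upgma(dm)
        wp = seq.upgma(dm, weighted=True)
        assert up.root.height == pytest.approx(4.0)
        assert wp.root.height == pytest.approx(3.5)
        assert clades(up.root) == clades(wp.root)

    def test_matches_scipy_average_linkage(self, rng):
        # independent oracle: scipy's UPGMA via cophenetic distances
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        n = 7
        m = rng.uniform(1, 10, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = tuple("abcdefg")
        tree = seq.upgma(seq.DistanceMatrix(labels=labels, d=m))
        Z = linkage(squareform(m), method="average")
        coph = squareform(cophenet(Z))
        for i in range(n):
            for j in range(i + 1, n):
                assert tree.cophenetic(labels[i], labels[j]) == pytest.approx(coph[i, j])

    def test_ultrametric_and_valid_newick(self, rng):
        import dendropy

        n = 6
        m = rng.uniform(1, 5, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = seq.upgma(seq.DistanceMatrix(labels=tuple("uvwxyz"), d=m))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        depths = []

        def depth_of(node, h=0.0):
            if node.is_leaf:
                depths.append(h)
            for c in node.children:
                depth_of(c, h + (node.height - c.height))

        depth_of(tree.root)
        assert np.allclose(depths, depths[0], atol=1e-9)
        assert {t.label for t in parsed.taxon_namespace} == set("uvwxyz")

    def test_sister_pairs_of_balanced_tree(self):
        d = np.array([[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], float)
        tree = seq.upgma(seq.DistanceMatrix(labels=("A", "B", "C", "D"), d=d))
        assert seq.sister_pairs(tree) == {frozenset({"A", "B"}), frozenset({"C", "D"})}


class TestSimulateDivergence:
    TREE = ([ ([("A", 0.05), ("B", 0.05)], 0.3), ([("C", 0.05), ("D", 0.05)], 0.3) ], 0.0)

    def test_zero_branches_identical_leaves(self):
        spec = ([("A", 0.0), ("B", 0.0)], 0.0)
        recs = seq.simulate_divergence(100, spec, seed=1)
        assert recs[0].residues == recs[1].residues

    def test_seed_reproducibility(self):
        r1 = seq.simulate_divergence(200, self.TREE, seed=7)
        r2 = seq.simulate_divergence(200, self.TREE, seed=7)
        assert [r.residues for r in r1] == [r.residues for r in r2]

    def test_cherry_recovery_rate(self):
        """Two short-branch cherries recovered in >= 95% of replicates."""
        hits = 0
        for rep in range(100):
            recs = seq.simulate_divergence(1000, self.TREE, seed=rep)
            aln = seq.Alignment(
                ids=tuple(r.id for r in recs), rows=tuple(r.residues for r in recs)
            )
            tree = seq.upgma(seq.jukes_cantor_distance(aln))
            if seq.sister_pairs(tree) == {frozenset("AB"), frozenset("CD")}:
                hits += 1
        assert hits >= 95


class TestAnnexinPipeline:
    def test_phenotype_pairs_are_cherries(self, annexin_trees):
        up, _ = annexin_trees
        cherries = seq.sister_pairs(up)
        assert frozenset({"ANXA1", "ANXA2"}) in cherries
        assert frozenset({"ANXA4", "ANXA5"}) in cherries
        assert frozenset({"ANXA7", "ANXA11"}) in cherries

    def test_double_core_member_has_no_sister(self, annexin_trees):
        up, wp = annexin_trees
        for tree in (up, wp):
            assert not any("ANXA6" in pair for pair in seq.sister_pairs(tree))

    def test_weighted_and_unweighted_topologies_agree(self, annexin_trees):
        up, wp = annexin_trees
        assert clades(up.root) == clades(wp.root)

    def test_pipeline_deterministic(self, annexin_records):
        def build():
            aln = seq.multiple_align(annexin_records)
            return seq.upgma(seq.jukes_cantor_distance(aln)).newick()

        assert build() == build()

    @pytest.mark.parametrize("matrix", ["BLOSUM50", "BLOSUM62", "BLOSUM80"])
    def test_cherries_robust_to_substitution_matrix(self, annexin_records, matrix):
        aln = seq.multiple_align(annexin_records, matrix=matrix)
        tree = seq.upgma(seq.jukes_cantor_distance(aln))
        cherries = seq.sister_pairs(tree)
        for pair in ({"ANXA1", "ANXA2"}, {"ANXA4", "ANXA5"}, {"ANXA7", "ANXA11"}):
            assert frozenset(pair) in cherries

    def test_synthesis_deterministic(self):
        a = seq.synthesize_annexin_family(seed=11)
        b = seq.synthesize_annexin_family(seed=11)
        assert [r.residues for r in a] == [r.residues for r in b]
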