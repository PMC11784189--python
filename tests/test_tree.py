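"""Newick round trips, JC distances, NJ recovery, rooting, monophyly, long branches."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from amfphylo.msa import Msa
from amfphylo.simulate import EvoSeq, evolve, make_root_seq, SimConfig, true_alignment
from amfphylo.tree import (
    bipartitions,
    is_monophyletic,
    jc_distance,
    long_branch_tips,
    mrca,
    nj_tree,
    parse_newick,
    read_distance_matrix,
    root_on_outgroup,
    same_topology,
    write_distance_matrix,
    write_newick,
)

from oracles import oracle_is_monophyletic, random_rooted_tree


class TestNewick:
    def test_minimal_parse(self):
        t = parse_newick("((A:1,B:1)90:0.5,C:2);")
        assert {x.name for x in t.tips()} == {"A", "B", "C"}
        internal = [n for n in t.non_tips() if n.support is not None]
        assert len(internal) == 1 and internal[0].support == 90

    def test_fractional_supports_rescaled(self):
        t = parse_newick("((A:1,B:1)0.95:0.5,C:2);")
        (node,) = [n for n in t.non_tips() if n.support is not None]
        assert node.support == pytest.approx(95.0)

    def test_round_trip_random_trees(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = random_rooted_tree(rng, [f"t{i}" for i in range(50)])
            for n in t.non_tips():
                n.support = float(rng.integers(50, 101))
            back = parse_newick(write_newick(t))
            assert same_topology(t, back)
            lengths_a = sorted((x.length or 0.0) for x in t.traverse())
            lengths_b = sorted((x.length or 0.0) for x in back.traverse())
            assert lengths_a == pytest.approx(lengths_b, abs=1e-9)
            sup_a = sorted(n.support for n in t.non_tips() if n.support is not None)
            sup_b = sorted(n.support for n in back.non_tips() if n.support is not None)
            assert sup_a == sup_b

    def test_malformed_newick_raises(self):
        with pytest.raises(Exception):
            parse_newick("(A,B")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate tip"):
            parse_newick("((A,A),B);")


class TestJcDistance:
    def test_identical_sequences_zero(self):
        msa = Msa(["a", "b"], ["ACGT", "ACGT"])
        assert jc_distance(msa)["a", "b"] == 0.0

    def test_closed_form(self):
        # p = 0.1 over 100 sites
        s1 = "A" * 100
        s2 = "C" * 10 + "A" * 90
        d = jc_distance(Msa(["a", "b"], [s1, s2]))["a", "b"]
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), rel=1e-9)

    def test_saturated_pair_hits_ceiling(self):
        s1 = "A" * 100
        s2 = "C" * 80 + "A" * 20
        assert jc_distance(Msa(["a", "b"], [s1, s2]))["a", "b"] == 5.0

    def test_no_overlap_errors(self):
        msa = Msa(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(ValueError, match="no overlapping"):
            jc_distance(msa)

    def test_gapped_columns_excluded(self):
        # mismatch only in a column where one row has a gap: distance 0
        msa = Msa(["a", "b"], ["ACG-", "ACGT"])
        assert jc_distance(msa)["a", "b"] == 0.0


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # distances from ((A:1,B:2):1,(C:3,D:1):1)
        dm = DistanceMatrix(
            [[0, 3, 6, 4], [3, 0, 7, 5], [6, 7, 0, 4], [4, 5, 4, 0]],
            ids=["A", "B", "C", "D"],
        )
        t = nj_tree(dm)
        assert bipartitions(t) == {frozenset({"A", "B"})} or bipartitions(t) == {
            frozenset({"C", "D"})
        }

    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=["A", "B", "C"])
        t = nj_tree(dm)
        lengths = {x.name: x.length for x in t.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_equal_distances_no_crash(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        t = nj_tree(DistanceMatrix(d, ids=list("ABCDE")))
        assert {x.name for x in t.tips()} == set("ABCDE")

    def test_fewer_than_three_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"]))

    def test_matches_skbio_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            ids = [f"t{i}" for i in range(n)]
            tree = random_rooted_tree(rng, ids)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = tree.find(ids[i]).distance(tree.find(ids[j]))
            dm = DistanceMatrix(d, ids=ids)
            assert same_topology(nj_tree(dm), skbio_nj(dm))

    def test_nj_on_jc_distances_recovers_simulated_topology(self):
        # low-divergence sequence evolution on known 8-taxon trees
        cfg = SimConfig(seed=0)
        recovered = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            ids = [f"t{i}" for i in range(8)]
            truth = random_rooted_tree(rng, ids, with_lengths=False)
            for n in truth.traverse(include_self=False):
                n.length = float(rng.uniform(0.02, 0.08))
            root_seq = make_root_seq(cfg, rng)
            seqs = {}
            seq_at = {id(truth): root_seq}
            for node in truth.preorder(include_self=False):
                seq_at[id(node)] = evolve(seq_at[id(node.parent)], node.length, rng)
                if node.is_tip():
                    seqs[node.name] = seq_at[id(node)]
            aln = true_alignment(seqs)
            if same_topology(nj_tree(jc_distance(aln)), truth):
                recovered += 1
        assert recovered >= 0.95 * n_rep


class TestRooting:
    def test_single_outgroup_tip(self):
        t = parse_newick("((A:1,B:1):1,(C:1,P1:1):1);")
        rooted = root_on_outgroup(t, {"P1"})
        og_side = [ch for ch in rooted.children
                   if {x.name for x in ch.tips(include_self=True)} == {"P1"}]
        assert len(og_side) == 1

    def test_outgroup_cherry(self):
        t = parse_newick("(((A:1,B:1):1,C:1):1,(P1:1,P2:1):1);")
        rooted = root_on_outgroup(t, {"P1", "P2"})
        sides = [frozenset(x.name for x in ch.tips(include_self=True))
                 for ch in rooted.children]
        assert frozenset({"P1", "P2"}) in sides

    def test_rooting_preserves_bipartitions(self):
        rng = np.random.default_rng(11)
        t = random_rooted_tree(rng, [f"t{i}" for i in range(12)] + ["P1", "P2"])
        before = bipartitions(t)
        rooted = root_on_outgroup(t, {"P1", "P2"})
        assert bipartitions(rooted) == before

    def test_non_monophyletic_outgroup_warns_and_roots(self, caplog):
        t = parse_newick("((P1:1,A:1):1,(P2:1,B:1):1);")
        with caplog.at_level("WARNING"):
            rooted = root_on_outgroup(t, {"P1", "P2"})
        assert "not a connected cluster" in caplog.text
        assert {x.name for x in rooted.tips()} == {"A", "B", "P1", "P2"}

    def test_invalid_outgroup_errors(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(ValueError):
            root_on_outgroup(t, set())
        with pytest.raises(ValueError):
            root_on_outgroup(t, {"A", "B", "C"})


class TestMonophyly:
    def test_hand_cases(self):
        t = parse_newick("((A,B),C);")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})
        assert is_monophyletic(t, {"A"})

    def test_unknown_tip_errors(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="unknown tip"):
            is_monophyletic(t, {"A", "Z"})

    def test_mrca_of_all_tips_is_root(self):
        t = parse_newick("((A,B),(C,D));")
        assert mrca(t, {"A", "B", "C", "D"}).is_root()

    def test_agreement_with_bruteforce_enumeration(self):
        rng = np.random.default_rng(21)
        names = [f"t{i}" for i in range(20)]
        for _ in range(20):
            t = random_rooted_tree(rng, names)
            for _ in range(50):
                k = int(rng.integers(1, 20))
                tipset = set(rng.choice(names, size=k, replace=False))
                assert is_monophyletic(t, tipset) == oracle_is_monophyletic(t, tipset)


class TestLongBranches:
    def test_star_tree_outlier_flagged(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:10);")
        assert long_branch_tips(t, factor=5) == ["E"]

    def test_uniform_lengths_no_flags(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        assert long_branch_tips(t, factor=5) == []

    def test_infinite_factor_no_flags(self):
        t = parse_newick("(A:1,B:1,C:100,D:1);")
        assert long_branch_tips(t, factor=math.inf) == []

    def test_all_zero_lengths_warn_empty(self, caplog):
        t = parse_newick("(A:0,B:0,C:0);")
        with caplog.at_level("WARNING"):
            assert long_branch_tips(t) == []
        assert "zero" in caplog.text

    def test_clade_scope_flags_internal_edges(self):
        t = parse_newick("((A:1,B:1):20,(C:1,D:1):1);")
        assert long_branch_tips(t, factor=5, scope="clades") == [("A", "B")]


def test_distance_matrix_tsv_round_trip(tmp_path):
    dm = DistanceMatrix([[0, 1.5, 2], [1.5, 0, 3], [2, 3, 0]], ids=["a", "b", "c"])
    write_distance_matrix(dm, tmp_path / "d.tsv")
    back = read_distance_matrix(tmp_path / "d.tsv")
    assert list(back.ids) == ["a", "b", "c"]
    assert np.allclose(back.data, dm.data)
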