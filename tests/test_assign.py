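"""Monophyly-based annotation: worked examples, oracle agreement, diagnostics."""

import numpy as np
import pytest

from amfphylo.assign import (
    annotate_diagnostics,
    annotate_queries,
    apply_novel_clades,
    assign_taxonomy,
    detect_novel_clades,
    filter_off_target,
    read_assignments,
    write_assignments,
)
from amfphylo.msa import Msa
from amfphylo.refset import ReferenceRecord
from amfphylo.tree import parse_newick, root_on_outgroup

from oracles import oracle_assign, oracle_novel_clades, random_rooted_tree


def _ref(seq_id, order, family, genus, species=""):
    return ReferenceRecord(
        seq_id=seq_id, sequence="ACGT", order_=order,
        family=family, genus=genus, species=species,
    )


def _random_instance(rng, n_tips=None):
    """Random rooted tree with a random reference subset and lineages."""
    n = n_tips or int(rng.integers(4, 26))
    names = [f"t{i}" for i in range(n)]
    tree = random_rooted_tree(rng, names)
    n_ref = int(rng.integers(1, n))
    ref_ids = list(rng.choice(names, size=n_ref, replace=False))
    refs = []
    for rid in ref_ids:
        order = f"O{rng.integers(1, 3)}"
        family = f"{order}F{rng.integers(1, 3)}"
        genus = f"{family}G{rng.integers(1, 3)}"
        species = f"{genus} sp{rng.integers(1, 3)}" if rng.random() < 0.8 else ""
        refs.append(_ref(rid, order, family, genus, species))
    return tree, refs


class TestWorkedExamples:
    def test_funneliformis_coronatus_species_level(self, funneliformis_case):
        tree, refs = funneliformis_case
        assignments = assign_taxonomy(tree, refs)
        assert {a.asv_id for a in assignments} == {"ASV166", "ASV177", "ASV178", "ASV179"}
        for a in assignments:
            assert a.rank == "species"
            assert a.taxon == "Funneliformis coronatus"

    def test_asv174_between_rhizophagus_species_genus_level(self, rhizophagus_case):
        tree, refs = rhizophagus_case
        (a,) = assign_taxonomy(tree, refs)
        assert a.asv_id == "ASV174"
        assert a.rank == "genus"
        assert a.taxon == "Rhizophagus"

    def test_single_query_sister_to_single_reference(self):
        tree = parse_newick("((Q1,R1),R2);")
        refs = [
            _ref("R1", "O1", "F1", "G1", "G1 alpha"),
            _ref("R2", "O1", "F1", "G2", "G2 beta"),
        ]
        (a,) = assign_taxonomy(tree, refs)
        assert (a.rank, a.taxon) == ("species", "G1 alpha")


class TestAssignContracts:
    def test_no_reference_tips_errors(self):
        tree = parse_newick("((Q1,Q2),Q3);")
        with pytest.raises(ValueError, match="no reference tips"):
            assign_taxonomy(tree, [_ref("R9", "O1", "F1", "G1")])

    def test_genus_only_reference_contributes_at_genus(self):
        tree = parse_newick("((Q1,(R1,R2)),R3);")
        refs = [
            _ref("R1", "O1", "F1", "G1", "G1 alpha"),
            _ref("R2", "O1", "F1", "G1", ""),  # genus-level evidence only
            _ref("R3", "O1", "F1", "G2", "G2 beta"),
        ]
        (a,) = assign_taxonomy(tree, refs)
        assert (a.rank, a.taxon) == ("species", "G1 alpha")

    def test_order_level_disagreement_is_unknown(self):
        tree = parse_newick("((Q1,R1),R2);")
        refs = [
            _ref("R1", "O1", "F1", "G1", "G1 alpha"),
            _ref("R2", "O2", "F9", "G9", "G9 zeta"),
        ]
        assignments = assign_taxonomy(tree, refs)
        q1 = next(a for a in assignments if a.asv_id == "Q1")
        # housing clade of Q1 is the cherry -> species; a basal query would
        # reach the root where the orders disagree
        assert q1.rank == "species"
        tree2 = parse_newick("(Q1,(R1,R2));")
        (a,) = assign_taxonomy(tree2, refs)
        assert (a.rank, a.taxon) == ("unclassified", "unknown")

    def test_min_support_walks_past_weak_nodes(self):
        tree = parse_newick("(((Q1,R1)40,R2)95,R3);")
        refs = [
            _ref("R1", "O1", "F1", "G1", "G1 alpha"),
            _ref("R2", "O1", "F1", "G1", "G1 beta"),
            _ref("R3", "O1", "F2", "G2", "G2 gamma"),
        ]
        (a,) = assign_taxonomy(tree, refs)
        assert (a.rank, a.taxon) == ("species", "G1 alpha")
        (a,) = assign_taxonomy(tree, refs, min_support=80)
        assert (a.rank, a.taxon) == ("genus", "G1")

    def test_determinism_byte_identical_tables(self, tmp_path, funneliformis_case):
        tree, refs = funneliformis_case
        for i in (1, 2):
            write_assignments(assign_taxonomy(tree, refs), tmp_path / f"a{i}.tsv")
        assert (tmp_path / "a1.tsv").read_bytes() == (tmp_path / "a2.tsv").read_bytes()

    def test_species_assignments_name_reference_species(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            tree, refs = _random_instance(rng)
            known = {r.species for r in refs if r.species}
            for a in assign_taxonomy(tree, refs):
                if a.rank == "species":
                    assert a.taxon in known

    def test_agreement_with_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            tree, refs = _random_instance(rng)
            lineage_of = {r.seq_id: (r.order_, r.family, r.genus, r.species) for r in refs}
            expected = oracle_assign(tree, lineage_of)
            got = {a.asv_id: (a.rank, a.taxon) for a in assign_taxonomy(tree, refs)}
            assert got == expected


class TestNovelClades:
    def test_query_only_clade_found(self):
        tree = parse_newick("(((Q1,Q2),(Q3,(Q4,(Q5,Q6)))),(R1,Q7));")
        clades = detect_novel_clades(tree, {"R1"})
        assert len(clades) == 1
        assert clades[0].member_ids == ("Q1", "Q2", "Q3", "Q4", "Q5", "Q6")

    def test_every_query_sister_to_reference_none(self):
        tree = parse_newick("((Q1,R1),(Q2,R2));")
        assert detect_novel_clades(tree, {"R1", "R2"}) == []

    def test_nested_query_clades_only_maximal(self):
        tree = parse_newick("((((Q1,Q2),Q3),R1),R2);")
        clades = detect_novel_clades(tree, {"R1", "R2"})
        assert [c.member_ids for c in clades] == [("Q1", "Q2", "Q3")]

    def test_agreement_with_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            tree, refs = _random_instance(rng)
            ref_ids = {r.seq_id for r in refs}
            got = {frozenset(c.member_ids) for c in detect_novel_clades(tree, ref_ids)}
            assert got == oracle_novel_clades(tree, ref_ids)


class TestDiagnostics:
    def test_private_insertion_counted_on_novel_members(self):
        tree = parse_newick(
            "(((Q1:2,Q2:2):0.2,(R1:0.05,R2:0.05):0.05):0.05,"
            "(R3:0.05,R4:0.05):0.05);"
        )
        refs = [
            _ref("R1", "O1", "F1", "G1", "G1 alpha"),
            _ref("R2", "O1", "F1", "G1", "G1 beta"),
            _ref("R3", "O1", "F1", "G2", "G2 gamma"),
            _ref("R4", "O1", "F1", "G2", "G2 delta"),
        ]
        base = "ACGTACGTACGTACGTACGT"
        ins = "GGGGGGGGGGGG"
        with_ins = base[:10] + ins + base[10:]
        without = base[:10] + "-" * 12 + base[10:]
        msa = Msa(
            ["Q1", "Q2", "R1", "R2", "R3", "R4"],
            [with_ins, with_ins, without, without, without, without],
        )
        assignments = annotate_queries(tree, refs, msa=msa)
        novel = [a for a in assignments if a.novel_clade_id]
        assert {a.asv_id for a in novel} == {"Q1", "Q2"}
        assert all(a.exclusive_insertion_cols == 12 for a in novel)
        assert all(a.long_branch for a in novel)

    def test_clean_tree_no_diagnostics(self):
        tree = parse_newick("((Q1:0.1,R1:0.1):0.1,R2:0.1);")
        refs = [
            _ref("R1", "O1", "F1", "G1", "G1 alpha"),
            _ref("R2", "O1", "F1", "G2", "G2 beta"),
        ]
        msa = Msa(["Q1", "R1", "R2"], ["ACGT", "ACGT", "ACGT"])
        for a in annotate_queries(tree, refs, msa=msa):
            assert not a.long_branch and a.exclusive_insertion_cols == 0

    def test_tip_mismatch_lists_difference(self):
        tree = parse_newick("((Q1,R1),R2);")
        msa = Msa(["Q1", "R1"], ["AC", "AC"])
        with pytest.raises(ValueError, match="R2"):
            annotate_diagnostics([], tree, msa)


class TestOffTarget:
    def test_ingroup_kept_outgroup_side_removed(self):
        # Qbad nests among the outgroup tips, so the rooted outgroup-side
        # subtree carries it along
        t = parse_newick("(((Q1,R1),R2),((P1,Qbad),P2));")
        rooted = root_on_outgroup(t, {"P1", "P2"})
        assignments = assign_taxonomy(
            rooted,
            [
                _ref("R1", "O1", "F1", "G1", "G1 alpha"),
                _ref("R2", "O1", "F1", "G2", "G2 beta"),
                _ref("P1", "Paraglomerales", "Paraglomeraceae", "Paraglomus"),
                _ref("P2", "Paraglomerales", "Paraglomeraceae", "Paraglomus"),
            ],
        )
        kept, removed = filter_off_target(assignments, rooted)
        assert {a.asv_id for a in kept} == {"Q1"}
        assert {a.asv_id for a in removed} == {"Qbad"}


def test_assignment_table_round_trip(tmp_path, funneliformis_case):
    tree, refs = funneliformis_case
    assignments = annotate_queries(tree, refs)
    write_assignments(assignments, tmp_path / "a.tsv")
    assert read_assignments(tmp_path / "a.tsv") == assignments
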