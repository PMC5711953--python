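"""Dollo polarization and trichotomy counting."""

from collections import Counter

import pytest

from blindtree import (
    AMBIGUOUS,
    CLEAN,
    INSUFFICIENT_OUTGROUP,
    UNINFORMATIVE,
    MarkerMatrix,
    NodeSpec,
    SpeciesTree,
    TrifurcationSpec,
    ascertainment_report,
    count_trifurcation,
    polarization_table,
    polarize_all,
    polarize_marker,
    ratio_count_for_clade,
    read_matrix,
)
from blindtree.errors import FormatError, MappingError, SpecError
from blindtree.fixture import CORE_NOTA, NOTA, REFERENCE, WALLABIA
from blindtree.matrix import ABSENT, MISSING, PRESENT


class TestSpeciesTree:
    def test_basal_polytomy_refused_without_outgroup(self):
        with pytest.raises(FormatError, match="outgroup"):
            SpeciesTree.read_newick("(A,B,(C,D));")

    def test_outgroup_roots_an_unrooted_tree(self):
        tree = SpeciesTree.read_newick("(A,B,(C,D));", outgroup="A")
        assert tree.is_clade(frozenset({"B", "C", "D"}))

    def test_clade_queries(self):
        tree = SpeciesTree.read_newick("((A,(B,C)),D);")
        assert tree.mrca_clade({"B", "C"}) == frozenset({"B", "C"})
        assert tree.mrca_clade({"A", "C"}) == frozenset({"A", "B", "C"})
        lineages = tree.deeper_lineages({"B", "C"})
        assert lineages == [frozenset({"A"}), frozenset({"D"})]


def toy_setup():
    tree = SpeciesTree.read_newick("((((A,B),C),D),E);")
    calls = {
        "all": {t: PRESENT for t in "ABCDE"},
        "one": {"A": PRESENT, "B": ABSENT, "C": ABSENT, "D": ABSENT, "E": ABSENT},
        "clean": {"A": PRESENT, "B": PRESENT, "C": ABSENT, "D": ABSENT, "E": ABSENT},
        "conflict": {"A": PRESENT, "B": ABSENT, "C": PRESENT, "D": ABSENT, "E": ABSENT},
        "shallow": {"A": PRESENT, "B": PRESENT, "C": ABSENT, "D": MISSING, "E": MISSING},
    }
    matrix = MarkerMatrix.from_dict(calls, taxa=list("ABCDE"))
    return matrix, tree


class TestPolarizeMarker:
    def test_statuses_on_a_toy_matrix(self):
        matrix, tree = toy_setup()
        assert polarize_marker(matrix, tree, "all").status == UNINFORMATIVE
        assert polarize_marker(matrix, tree, "one").status == UNINFORMATIVE
        clean = polarize_marker(matrix, tree, "clean")
        assert clean.status == CLEAN and clean.branch == frozenset({"A", "B"})
        conflict = polarize_marker(matrix, tree, "conflict")
        assert conflict.status == AMBIGUOUS and "B" in conflict.conflict_note
        shallow = polarize_marker(matrix, tree, "shallow")
        assert shallow.status == INSUFFICIENT_OUTGROUP and shallow.depends_on_missing

    def test_stringency_zero_accepts_shallow_verification(self):
        matrix, tree = toy_setup()
        assert polarize_marker(matrix, tree, "shallow", stringency=1).status == CLEAN

    def test_strict_successive_requires_the_nearest_lineages(self):
        tree = SpeciesTree.read_newick("((((A,B),C),D),E);")
        calls = {"gap": {"A": PRESENT, "B": PRESENT, "C": MISSING, "D": ABSENT, "E": ABSENT}}
        matrix = MarkerMatrix.from_dict(calls, taxa=list("ABCDE"))
        assert polarize_marker(matrix, tree, "gap").status == CLEAN
        strict = polarize_marker(matrix, tree, "gap", strict_successive=True)
        assert strict.status == INSUFFICIENT_OUTGROUP

    def test_unknown_locus_and_unmapped_taxa(self):
        matrix, tree = toy_setup()
        with pytest.raises(KeyError):
            polarize_marker(matrix, tree, "nope")
        small_tree = SpeciesTree.read_newick("((A,B),C);")
        with pytest.raises(MappingError):
            polarize_marker(matrix, small_tree, "clean")

    def test_every_locus_gets_exactly_one_status(self, kangaroo_matrix, kangaroo_tree):
        markers = polarize_all(kangaroo_matrix, kangaroo_tree)
        counts = Counter(m.status for m in markers)
        assert sum(counts.values()) == len(kangaroo_matrix.loci)
        assert counts == {CLEAN: 20, AMBIGUOUS: 8, INSUFFICIENT_OUTGROUP: 1}

    def test_polarization_independent_of_row_and_column_order(self, kangaroo_matrix, kangaroo_tree):
        shuffled = MarkerMatrix(
            kangaroo_matrix.data.iloc[::-1, ::-1].copy(),
            polymorphic=kangaroo_matrix.polymorphic,
        )
        base = {m.locus: (m.status, m.branch) for m in polarize_all(kangaroo_matrix, kangaroo_tree)}
        redo = {m.locus: (m.status, m.branch) for m in polarize_all(shuffled, kangaroo_tree)}
        assert base == redo

    def test_clean_markers_sit_on_the_reference_lineage(self, kangaroo_polarized):
        # single-reference ascertainment: every clean branch contains the reference
        assert ascertainment_report(kangaroo_polarized, REFERENCE) == []

    def test_report_table_lists_every_locus(self, kangaroo_polarized):
        table = polarization_table(kangaroo_polarized)
        assert table.count("\n") == len(kangaroo_polarized) + 1
        assert "C1\tAMBIGUOUS" in table


class TestCountTrifurcation:
    def test_published_node_counts(self, kangaroo_polarized, kangaroo_tree, kangaroo_nodes):
        expected = {
            "(i)": "[2 1 X]",
            "(ii)": "[6 1 X]",
            "(iii)": "[8 0 X]",
            "(iv)": "[9 1 X]",
            "(v)": "[3 1 X]",
            "(vi)": "[3 0 X]",
            "(vii)": "[1 0 X]",
            "(viii)": "[4 0 X]",
        }
        for node in kangaroo_nodes:
            tally = count_trifurcation(kangaroo_polarized, node, kangaroo_tree)
            assert str(tally.count) == expected[node.label], node.label

    def test_published_ratio_patterns(self, kangaroo_polarized, kangaroo_tree, kangaroo_nodes):
        expected = {"(ii)": "(6,2)", "(iii)": "(8,0)", "(iv)": "(9,2)", "(viii)": "(4,0)"}
        for node in kangaroo_nodes:
            tally = count_trifurcation(kangaroo_polarized, node, kangaroo_tree)
            if node.label in expected:
                assert str(tally.ratio) == expected[node.label], node.label
            else:
                assert tally.ratio is None

    def test_resolvable_ambiguous_markers_reported_separately(
        self, kangaroo_polarized, kangaroo_tree, kangaroo_nodes
    ):
        node_ii = next(n for n in kangaroo_nodes if n.label == "(ii)")
        tally = count_trifurcation(
            kangaroo_polarized, node_ii, kangaroo_tree, include_ambiguous=True
        )
        assert str(tally.count) == "[6 1 X]"  # the clean count is untouched
        assert sorted(tally.ambiguous_resolved["t1"]) == ["C1", "C5", "C6", "C7", "C8"]
        assert tally.ambiguous_resolved["t2"] == ["C2"]
        assert str(tally.combined_count()) == "[11 2 X]"

    def test_less_stringent_locus_excluded_from_counting(
        self, kangaroo_polarized, kangaroo_tree, kangaroo_nodes
    ):
        node_vii = next(n for n in kangaroo_nodes if n.label == "(vii)")
        tally = count_trifurcation(kangaroo_polarized, node_vii, kangaroo_tree)
        assert "K136" in tally.insufficient

    def test_empty_tally(self, kangaroo_tree):
        spec = TrifurcationSpec(
            clade_a=frozenset({"M_eugenii", "M_parma"}),
            clade_b=frozenset({"M_agilis"}),
            clade_c=frozenset({"M_rufogriseus"}),
            reference_taxon="M_eugenii",
        )
        tally = count_trifurcation([], spec, kangaroo_tree)
        assert str(tally.count) == "[0 0 X]"

    def test_unrealizable_spec_is_an_error(self):
        with pytest.raises(SpecError):
            TrifurcationSpec(
                clade_a=frozenset({"A"}), clade_b=frozenset({"A", "B"}),
                clade_c=frozenset({"C"}), reference_taxon="A",
            )
        with pytest.raises(SpecError):
            TrifurcationSpec(
                clade_a=frozenset({"A"}), clade_b=frozenset({"B"}),
                clade_c=frozenset({"C"}), reference_taxon="Z",
            )

    def test_fully_observed_regime_counts_all_three_slots(self):
        tree = SpeciesTree.read_newick("(((A,B),C),D);")
        calls = {
            "m1": {"A": PRESENT, "B": PRESENT, "C": ABSENT, "D": ABSENT},
            "m2": {"A": PRESENT, "B": ABSENT, "C": PRESENT, "D": ABSENT},
            "m3": {"A": ABSENT, "B": PRESENT, "C": PRESENT, "D": ABSENT},
        }
        matrix = MarkerMatrix.from_dict(calls, taxa=list("ABCD"))
        polarized = polarize_all(matrix, tree)
        spec = TrifurcationSpec(
            clade_a=frozenset("A"), clade_b=frozenset("B"), clade_c=frozenset("C"),
            reference_taxon=None, tested="ab",
        )
        tally = count_trifurcation(polarized, spec, tree, stringency=1)
        assert str(tally.count) == "[1 1 1]"


class TestRatioCountForClade:
    def test_reference_sister_clade(self, kangaroo_polarized, kangaroo_tree):
        ratio = ratio_count_for_clade(
            kangaroo_polarized,
            frozenset(WALLABIA) | frozenset(NOTA),
            kangaroo_tree,
            reference_taxon=REFERENCE,
        )
        assert str(ratio) == "(6,2)"

    def test_masked_clade_aggregates_successive_branches(
        self, kangaroo_polarized, kangaroo_tree
    ):
        ratio = ratio_count_for_clade(
            kangaroo_polarized,
            frozenset(NOTA),
            kangaroo_tree,
            reference_taxon=REFERENCE,
            ignore=frozenset(WALLABIA),
        )
        assert str(ratio) == "(8,0)"

    def test_clade_without_markers_is_untestable(self, kangaroo_tree):
        ratio = ratio_count_for_clade(
            [], frozenset(CORE_NOTA), kangaroo_tree, reference_taxon=REFERENCE
        )
        assert ratio.total == 0

    def test_clade_must_contain_reference(self, kangaroo_polarized, kangaroo_tree):
        with pytest.raises(SpecError):
            ratio_count_for_clade(
                kangaroo_polarized, frozenset({"M_giganteus", "M_fuliginosus"}),
                kangaroo_tree, reference_taxon=REFERENCE,
            )
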