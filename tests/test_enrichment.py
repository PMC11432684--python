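"""Interactor expansion, ontology/annotation loading, and the enrichment test."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from ncaxis.enrichment import (
    EXPERIMENTAL_EVIDENCE_CODES,
    enrich,
    expand_interactors,
    holm_adjust,
    load_annotations,
    load_ontology,
)
from ncaxis.io_tables import GeneSet

from _helpers import make_table


class TestExpandInteractors:
    def test_first_degree_partners(self):
        biogrid = make_table([
            ("G1", "other", "P1", "protein"),
            ("G1", "other", "P2", "protein"),
            ("G3", "other", "P4", "protein"),
        ])
        out = expand_interactors(GeneSet(members={"G1"}), biogrid)
        assert out.members == {"G1", "P1", "P2"}
        assert out.metadata["contributions"] == {"G1": ["P1", "P2"]}

    def test_empty_input_gives_empty_output(self):
        biogrid = make_table([("G1", "other", "P1", "protein")])
        assert len(expand_interactors(GeneSet(members=set()), biogrid)) == 0

    def test_self_pair_contributes_nothing(self):
        biogrid = make_table([("G1", "other", "G1", "protein")])
        out = expand_interactors(GeneSet(members={"G1"}), biogrid)
        assert out.members == {"G1"}


OBO_CHAIN = """format-version: 1.2

[Term]
id: GO:0000003
name: grandparent
namespace: biological_process

[Term]
id: GO:0000002
name: parent
namespace: biological_process
is_a: GO:0000003 ! grandparent

[Term]
id: GO:0000001
name: child
namespace: biological_process
is_a: GO:0000002 ! parent

[Term]
id: GO:0000009
name: lonely
namespace: molecular_function

[Term]
id: GO:0000666
name: gone
namespace: biological_process
is_obsolete: true
"""


def gaf_line(gene, term, evidence="IDA", qualifier=""):
    return (f"db\t{gene}\t{gene}\t{qualifier}\t{term}\tREF:1\t{evidence}\t\tP\t\t\t"
            f"protein\ttaxon:9606\t20240101\tdb\t\t\n")


@pytest.fixture
def chain_ontology(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(OBO_CHAIN)
    return load_ontology(path)


class TestOntologyAndAnnotations:
    def test_annotation_propagates_to_all_ancestors(self, tmp_path, chain_ontology):
        gaf = tmp_path / "a.gaf"
        gaf.write_text("!gaf-version: 2.2\n" + gaf_line("g", "GO:0000001"))
        ann = load_annotations(gaf, chain_ontology)
        for term in ("GO:0000001", "GO:0000002", "GO:0000003"):
            assert "g" in ann.genes_for(term)

    def test_parentless_term_annotates_itself_only(self, tmp_path, chain_ontology):
        gaf = tmp_path / "a.gaf"
        gaf.write_text("!gaf-version: 2.2\n" + gaf_line("g", "GO:0000009"))
        ann = load_annotations(gaf, chain_ontology)
        assert ann.term_to_genes == {"GO:0000009": {"g"}}

    def test_iea_excluded_under_experimental_filter(self, tmp_path, chain_ontology):
        gaf = tmp_path / "a.gaf"
        gaf.write_text(
            "!gaf-version: 2.2\n"
            + gaf_line("g1", "GO:0000001", evidence="IEA")
            + gaf_line("g2", "GO:0000001", evidence="IMP")
        )
        ann = load_annotations(gaf, chain_ontology, EXPERIMENTAL_EVIDENCE_CODES)
        assert ann.population == {"g2"}
        assert ann.n_filtered_evidence == 1

    def test_obsolete_and_unknown_terms_skipped_with_count(self, tmp_path, chain_ontology):
        gaf = tmp_path / "a.gaf"
        gaf.write_text(
            "!gaf-version: 2.2\n"
            + gaf_line("g1", "GO:0000666")
            + gaf_line("g2", "GO:9999999")
            + gaf_line("g3", "GO:0000001")
        )
        ann = load_annotations(gaf, chain_ontology)
        assert ann.n_skipped_unknown_term == 2
        assert "GO:0000666" not in ann.term_to_genes

    def test_not_qualifier_skipped(self, tmp_path, chain_ontology):
        gaf = tmp_path / "a.gaf"
        gaf.write_text("!gaf-version: 2.2\n" + gaf_line("g", "GO:0000001", qualifier="NOT|involved_in"))
        ann = load_annotations(gaf, chain_ontology)
        assert ann.population == set()
        assert ann.n_skipped_qualifier == 1

    def test_part_of_propagates_like_is_a(self, tmp_path):
        obo = tmp_path / "p.obo"
        obo.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000010\nname: whole\n"
            "namespace: cellular_component\n\n[Term]\nid: GO:0000011\nname: part\n"
            "namespace: cellular_component\nrelationship: part_of GO:0000010 ! whole\n"
        )
        ontology = load_ontology(obo)
        assert ontology.ancestors("GO:0000011") == {"GO:0000010"}

    def test_cyclic_parent_graph_rejected(self, tmp_path):
        obo = tmp_path / "cycle.obo"
        obo.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000020\nname: a\n"
            "is_a: GO:0000021\n\n[Term]\nid: GO:0000021\nname: b\nis_a: GO:0000020\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            load_ontology(obo)

    def test_propagation_invariant_on_loaded_set(self, default_fixture):
        paths, _ = default_fixture
        ontology = load_ontology(paths["obo"])
        ann = load_annotations(paths["gaf"], ontology)
        for term, genes in ann.term_to_genes.items():
            for parent in ontology.ancestors(term):
                assert genes <= ann.genes_for(parent)


def enumerated_tail(pop_size, pop_count, study_size, study_count):
    """Exact right-tail hypergeometric probability by combinatorial enumeration."""
    numerator = sum(
        math.comb(pop_count, i) * math.comb(pop_size - pop_count, study_size - i)
        for i in range(study_count, min(pop_count, study_size) + 1)
        if study_size - i <= pop_size - pop_count
    )
    return numerator / math.comb(pop_size, study_size)


def tiny_annotation_set(term_gene_map, population):
    from ncaxis.enrichment import AnnotationSet

    return AnnotationSet(
        term_to_genes={t: set(g) for t, g in term_gene_map.items()},
        evidence_filter=set(EXPERIMENTAL_EVIDENCE_CODES),
        population=set(population),
    )


class TestEnrich:
    def test_term_covering_population_is_never_significant(self):
        population = {f"g{i}" for i in range(40)}
        ann = tiny_annotation_set({"GO:X": population}, population)
        study = GeneSet(members={f"g{i}" for i in range(8)})
        (result,) = enrich(study, ann)
        assert result.p_raw == pytest.approx(1.0)
        assert not result.significant

    def test_p_raw_equals_combinatorial_tail(self):
        population = {f"g{i}" for i in range(100)}
        annotated = {f"g{i}" for i in range(10)}
        study = GeneSet(members={f"g{i}" for i in range(5)} | {f"g{i}" for i in range(90, 95)})
        # study has 5 annotated of 10; population 100 with 10 annotated
        ann = tiny_annotation_set({"GO:X": annotated}, population)
        (result,) = enrich(study, ann)
        assert result.study_count == 5
        expected = enumerated_tail(100, 10, 10, 5)
        assert result.p_raw == pytest.approx(expected, abs=1e-12)

    def test_counts_respect_invariants(self):
        population = {f"g{i}" for i in range(30)}
        ann = tiny_annotation_set(
            {"GO:X": {f"g{i}" for i in range(12)}}, population
        )
        study = GeneSet(members={f"g{i}" for i in range(6)})
        (result,) = enrich(study, ann)
        assert 0.0 <= result.p_raw <= result.p_adjusted <= 1.0
        assert result.study_count <= min(result.study_size, result.pop_count)

    def test_study_genes_outside_population_dropped_with_warning(self):
        population = {f"g{i}" for i in range(20)}
        ann = tiny_annotation_set({"GO:X": {f"g{i}" for i in range(5)}}, population)
        study = GeneSet(members={"g0", "g1", "ALIEN"})
        with pytest.warns(UserWarning, match="dropped"):
            (result,) = enrich(study, ann)
        assert result.study_size == 2

    def test_empty_study_after_intersection_warns_and_is_empty(self):
        ann = tiny_annotation_set({"GO:X": {"g0"}}, {"g0"})
        with pytest.warns(UserWarning):
            assert enrich(GeneSet(members={"ALIEN"}), ann) == []

    def test_min_study_count_gates_testing(self):
        population = {f"g{i}" for i in range(20)}
        ann = tiny_annotation_set({"GO:X": {"g0"}}, population)
        study = GeneSet(members={"g0", "g1"})
        assert enrich(study, ann, min_study_count=2) == []


class TestHolm:
    def test_step_down_recurrence_on_worked_example(self):
        raw = [0.001, 0.01, 0.04]
        adjusted = holm_adjust(raw)
        assert adjusted == pytest.approx([0.003, 0.02, 0.04])
        assert adjusted == sorted(adjusted)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = random.Random(42)
        for _ in range(30):
            m = rng.randint(1, 25)
            raw = [rng.random() ** rng.choice((1, 3, 6)) for _ in range(m)]
            expected = multipletests(raw, method="holm")[1]
            got = holm_adjust(raw)
            assert got == pytest.approx(list(expected), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    def test_invariants(self, raw, rnd):
        m = len(raw)
        adjusted = holm_adjust(raw)
        shuffled_idx = list(range(m))
        rnd.shuffle(shuffled_idx)
        re_adjusted = holm_adjust([raw[i] for i in shuffled_idx])
        for pos, i in enumerate(shuffled_idx):
            assert re_adjusted[pos] == pytest.approx(adjusted[i])  # order invariance
        for p, q in zip(raw, adjusted):
            assert q >= p  # never smaller than raw
            assert q <= min(1.0, m * p) + 1e-15  # plain Bonferroni bounds Holm
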