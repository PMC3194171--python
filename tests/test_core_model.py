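import pytest

from dispkb import (
    Fact,
    InstanceDecl,
    KnowledgeBase,
    OntKind,
    TypeDecl,
)
from dispkb.core_model import (
    CycleError,
    DerivedRelationAsserted,
    DuplicateIdentifier,
    KindClashError,
    UnknownIdentifier,
)


def make_kb():
    kb = KnowledgeBase()
    kb.add_type(TypeDecl("Disposition-to-bleed", OntKind.DISPOSITION))
    kb.add_type(TypeDecl("Haemophilia", OntKind.DISPOSITION,
                         frozenset({"Disposition-to-bleed"})))
    kb.add_type(TypeDecl("Glass", OntKind.MATERIAL_ENTITY))
    kb.add_type(TypeDecl("Breaking", OntKind.PROCESS))
    return kb


class TestTaxonomy:
    def test_reflexive_closure_of_fresh_type(self):
        kb = KnowledgeBase()
        kb.add_type(TypeDecl("Fragility", OntKind.DISPOSITION))
        assert kb.ancestors("Fragility") == {"Fragility"}

    def test_transitive_closure_through_parent(self):
        kb = make_kb()
        assert kb.ancestors("Haemophilia") >= {"Haemophilia", "Disposition-to-bleed"}

    def test_cycle_rejected(self):
        kb = make_kb()
        with pytest.raises(CycleError):
            kb.add_is_a("Disposition-to-bleed", "Haemophilia")
        with pytest.raises(CycleError):
            kb.add_is_a("Glass", "Glass")

    def test_cross_kind_parentage_rejected(self):
        kb = make_kb()
        with pytest.raises(KindClashError):
            kb.add_type(TypeDecl("Dropping", OntKind.PROCESS,
                                 frozenset({"Glass"})))

    def test_duplicate_name_rejected(self):
        kb = make_kb()
        with pytest.raises(DuplicateIdentifier):
            kb.add_type(TypeDecl("Glass", OntKind.MATERIAL_ENTITY))

    @pytest.mark.parametrize("a,b,expected", [
        ("Haemophilia", "Haemophilia", True),           # reflexivity
        ("Haemophilia", "Disposition-to-bleed", True),  # declared edge
        ("Breaking", "Haemophilia", False),             # no path
    ])
    def test_is_subtype(self, a, b, expected):
        assert make_kb().is_subtype(a, b) is expected

    def test_is_subtype_unknown_identifier(self):
        with pytest.raises(UnknownIdentifier):
            make_kb().is_subtype("Haemophilia", "NoSuch")


class TestInstances:
    def test_instance_of_closure_is_upward(self):
        kb = make_kb()
        kb.add_instance(InstanceDecl("d1", frozenset({"Haemophilia"})))
        assert "d1" in kb.instances_of("Disposition-to-bleed")

    def test_instances_of_empty_kb(self):
        kb = KnowledgeBase()
        kb.add_type(TypeDecl("Empty", OntKind.PROCESS))
        assert kb.instances_of("Empty") == set()

    def test_disjoint_kinds_do_not_mix(self):
        kb = make_kb()
        kb.add_instance(InstanceDecl("g1", frozenset({"Glass"})))
        kb.add_instance(InstanceDecl("p1", frozenset({"Breaking"})))
        assert kb.instances_of("Glass") == {"g1"}
        assert kb.instances_of("Breaking") == {"p1"}

    def test_kind_of_instance(self):
        kb = make_kb()
        kb.add_instance(InstanceDecl("g1", frozenset({"Glass"})))
        kb.add_instance(InstanceDecl("p1", frozenset({"Breaking"})))
        assert kb.kind_of_instance("g1") is OntKind.MATERIAL_ENTITY
        assert kb.kind_of_instance("p1") is OntKind.PROCESS

    def test_kind_clash_raises(self):
        kb = make_kb()
        kb.add_type(TypeDecl("SomeQuality", OntKind.QUALITY))
        kb.add_instance(InstanceDecl("x", frozenset({"SomeQuality", "Breaking"})))
        with pytest.raises(KindClashError):
            kb.kind_of_instance("x")

    def test_multiple_instantiation_same_kind_allowed(self):
        # one disposition instance typed under two disposition types
        kb = make_kb()
        kb.add_type(TypeDecl("OtherDisp", OntKind.DISPOSITION))
        kb.add_instance(InstanceDecl("d", frozenset({"Haemophilia", "OtherDisp"})))
        assert kb.kind_of_instance("d") is OntKind.DISPOSITION


class TestFacts:
    def test_derived_only_relations_rejected_when_asserted(self):
        kb = make_kb()
        kb.add_instance(InstanceDecl("g1", frozenset({"Glass"})))
        kb.add_instance(InstanceDecl("d1", frozenset({"Haemophilia"})))
        for rel in ("has_disposition", "has_trigger_D"):
            with pytest.raises(DerivedRelationAsserted):
                kb.add_fact(Fact(rel, "g1", "d1"))

    def test_fact_requires_declared_instances(self):
        kb = make_kb()
        kb.add_instance(InstanceDecl("g1", frozenset({"Glass"})))
        with pytest.raises(UnknownIdentifier):
            kb.add_fact(Fact("inheres_in", "ghost", "g1"))

    def test_asserted_skolem_prefix_rejected(self):
        kb = make_kb()
        with pytest.raises(Exception):
            kb.add_instance(InstanceDecl("__sk.fake", frozenset({"Glass"})))


class TestClosureProperties:
    def test_closure_idempotent_and_monotone(self):
        # re-adding closure-level information changes nothing; adding a new
        # instance never removes memberships
        kb = make_kb()
        kb.add_instance(InstanceDecl("d1", frozenset({"Haemophilia"})))
        before = {t: kb.instances_of(t) for t in kb.types}
        kb.add_instance(InstanceDecl("d2", frozenset({"Disposition-to-bleed"})))
        after = {t: kb.instances_of(t) for t in kb.types}
        for t in before:
            assert before[t] <= after[t]

    def test_late_is_a_edge_recloses_instances(self):
        kb = KnowledgeBase()
        kb.add_type(TypeDecl("A", OntKind.DISPOSITION))
        kb.add_type(TypeDecl("B", OntKind.DISPOSITION))
        kb.add_instance(InstanceDecl("x", frozenset({"B"})))
        assert "x" not in kb.instances_of("A")
        kb.add_is_a("B", "A")
        assert "x" in kb.instances_of("A")
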