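import pytest

from dispkb import (
    Fact,
    InstanceDecl,
    KnowledgeBase,
    OntKind,
    TypeDecl,
    build_worked_example,
)
from dispkb.core_model import KBError
from dispkb.instance_reasoner import saturate
from dispkb import multitrack, type_semantics as ts
from conftest import random_corpus


@pytest.fixture
def tablet_kb():
    kb = build_worked_example("aspirin")
    kb2, _ = saturate(kb)
    return kb2


class TestAllSome:
    def test_essential_disposition_holds_after_saturation(self, tablet_kb):
        assert ts.holds_type_has_disposition(tablet_kb, "Aspirin",
                                             "PainReliefDisposition")

    def test_patient_without_allergy_is_counterexample(self):
        kb = build_worked_example("penicillin_allergy")
        res = ts.holds_type_has_disposition(kb, "Patient", "PenicillinAllergy")
        assert not res and res.counterexamples == ("patient2",)

    def test_vacuous_for_uninstantiated_subject(self):
        kb = build_worked_example("penicillin_allergy")
        kb.add_type(TypeDecl("Mosquito", OntKind.MATERIAL_ENTITY))
        assert ts.holds_type_has_disposition(kb, "Mosquito", "PenicillinAllergy")

    def test_inheres_in_common_supertype_not_sibling(self, tablet_kb):
        # pain relief inheres in tablets (aspirin or paracetamol), so the
        # claim holds at Tablet but fails at Aspirin
        assert ts.holds_type_inheres_in(tablet_kb, "PainReliefDisposition", "Tablet")
        res = ts.holds_type_inheres_in(tablet_kb, "PainReliefDisposition", "Aspirin")
        assert not res and "pr1" in res.counterexamples

    def test_kind_mismatch_rejected(self, tablet_kb):
        with pytest.raises(KBError):
            ts.holds_type_has_disposition(tablet_kb, "PainRelief", "Tablet")


class TestValueRestrictions:
    def test_unrealized_disposition_vacuously_true(self, match_kb):
        # zero realization facts: the restriction holds by design
        assert ts.holds_value_restriction_realization(
            match_kb, "Inflammability", "Inflammation")

    def test_off_type_realization_is_counterexample(self, match_kb):
        match_kb.add_type(TypeDecl("Dissolving", OntKind.PROCESS))
        match_kb.add_instance(InstanceDecl("r1", frozenset({"Dissolving"})))
        match_kb.add_fact(Fact("has_realization", "m_disp", "r1"))
        res = ts.holds_value_restriction_realization(
            match_kb, "Inflammability", "Inflammation")
        assert not res and res.counterexamples == ("r1",)

    def test_multitrack_union_covers_both_tracks(self):
        kb = build_worked_example("litmus")
        star = multitrack.make_union(kb, ("BlueShift", "RedShift"))
        assert ts.holds_value_restriction_realization(
            kb, "LitmusResponsiveness", star)

    def test_trigger_restriction_on_haemophilia(self):
        kb2, _ = saturate(build_worked_example("haemophilia"))
        assert ts.holds_value_restriction_trigger_D(kb2, "Haemophilia", "Lesion")

    def test_off_type_trigger_is_counterexample(self):
        kb = build_worked_example("patellar")
        kb.add_type(TypeDecl("Sneeze", OntKind.PROCESS))
        kb.add_instance(InstanceDecl("sneeze1", frozenset({"Sneeze"})))
        kb.add_fact(Fact("has_trigger_R", "jerk1", "sneeze1"))
        res = ts.holds_value_restriction_trigger_D(
            kb, "PatellarReflexDisposition", "PatellarTap")
        assert not res and res.counterexamples == ("sneeze1",)

    def test_weakening_to_supertype_stays_true(self, match_kb):
        # monotone in the object type under is_a
        match_kb.add_type(TypeDecl("Combustion", OntKind.PROCESS))
        match_kb.add_is_a("Inflammation", "Combustion")
        kb2, _ = saturate(match_kb)
        assert ts.holds_value_restriction_realization(kb2, "Inflammability",
                                                      "Inflammation")
        assert ts.holds_value_restriction_realization(kb2, "Inflammability",
                                                      "Combustion")


class TestAllSomeTriggerR:
    def test_every_bleeding_has_a_lesion_trigger(self):
        kb2, _ = saturate(build_worked_example("haemophilia"))
        assert ts.holds_allsome_trigger_R(kb2, "Bleeding", "Lesion")

    def test_untriggered_realization_is_counterexample(self):
        kb = build_worked_example("haemophilia")
        kb.add_instance(InstanceDecl("bleed_x", frozenset({"Bleeding"})))
        kb.add_fact(Fact("has_realization", "h_disp", "bleed_x"))
        res = ts.holds_allsome_trigger_R(kb, "Bleeding", "Lesion")
        assert not res and res.counterexamples == ("bleed_x",)

    def test_vacuous_with_no_realization_instances(self, match_kb):
        assert ts.holds_allsome_trigger_R(match_kb, "Inflammation", "Striking")


class TestVacuityLaw:
    def test_all_checks_true_on_instance_free_kb(self, match_kb):
        kb = match_kb
        for x in list(kb.instances):
            del kb.instances[x]
        kb._facts.clear()
        assert ts.holds_type_has_disposition(kb, "Match", "Inflammability")
        assert ts.holds_type_inheres_in(kb, "Inflammability", "Match")
        assert ts.holds_value_restriction_realization(kb, "Inflammability",
                                                      "Inflammation")
        assert ts.holds_value_restriction_trigger_D(kb, "Inflammability",
                                                    "Striking")
        assert ts.holds_allsome_trigger_R(kb, "Inflammation", "Striking")


class TestCounterexamples:
    def test_counterexamples_recheck_as_ground_facts(self):
        kb = build_worked_example("penicillin_allergy")
        res = ts.holds_type_has_disposition(kb, "Patient", "PenicillinAllergy")
        for x in res.counterexamples:
            # each is a concrete Patient instance bearing no allergy
            assert kb.instance_is_of(x, "Patient")
            assert not any(
                "PenicillinAllergy" in kb.instances[f.subject].types
                for f in kb.facts_with("inheres_in", object=x))


class TestInduceClaims:
    def test_match_fixture_supports_realization_claim(self, match_kb):
        kb2, _ = saturate(match_kb)
        claims = ts.induce_type_claims(kb2)
        assert ts.TypeRelationClaim(
            "type_has_realization", "Inflammability", "Inflammation") in claims

    def test_empty_kb_yields_no_claims(self):
        assert ts.induce_type_claims(KnowledgeBase()) == set()

    def test_induced_claims_recheck_true(self):
        for kb in random_corpus(15):
            kb2, _ = saturate(kb)
            for claim in ts.induce_type_claims(kb2):
                assert ts.check_claim(kb2, claim)
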