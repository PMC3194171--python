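import pytest

from dispkb import (
    DispositionAxiom,
    Fact,
    InstanceDecl,
    KnowledgeBase,
    OntKind,
    TypeDecl,
    build_worked_example,
)
from dispkb.instance_reasoner import (
    SkolemPolicy,
    apply_base_principle,
    apply_bearer_principle,
    apply_realization_principle,
    derive_has_disposition,
    derive_trigger_D,
    saturate,
)
from conftest import make_match_kb, random_corpus


def _atoms(kb):
    return kb.atom_set()


class TestDefinitionalRules:
    def test_has_disposition_from_inherence(self, match_kb):
        facts = derive_has_disposition(match_kb)
        assert {f.atom for f in facts} == {("has_disposition", "match1", "m_disp")}

    def test_quality_inherence_yields_no_has_disposition(self):
        kb = KnowledgeBase()
        kb.add_type(TypeDecl("Salt", OntKind.MATERIAL_ENTITY))
        kb.add_type(TypeDecl("NaClStructure", OntKind.QUALITY))
        kb.add_instance(InstanceDecl("salt1", frozenset({"Salt"})))
        kb.add_instance(InstanceDecl("q1", frozenset({"NaClStructure"})))
        kb.add_fact(Fact("inheres_in", "q1", "salt1"))
        assert derive_has_disposition(kb) == set()

    def test_trigger_D_through_realization(self):
        kb = build_worked_example("patellar")
        atoms = {f.atom for f in derive_trigger_D(kb)}
        # repeated triggering: one derived trigger per distinct tap
        assert atoms == {("has_trigger_D", "reflex1", "tap1"),
                         ("has_trigger_D", "reflex1", "tap2")}

    def test_no_trigger_fact_no_trigger_D(self):
        kb = build_worked_example("patellar").copy()
        del kb._facts[("has_trigger_R", "jerk1", "tap1")]
        del kb._facts[("has_trigger_R", "jerk2", "tap2")]
        assert derive_trigger_D(kb) == set()


class TestRealizationPrinciple:
    def test_match_is_realized_when_struck(self, match_kb):
        kb2, traces = apply_realization_principle(match_kb)
        sk = "__sk.REAL9.m_disp.strike1.Inflammation"
        assert sk in kb2.instances
        assert kb2.instances[sk].provenance == "skolem"
        assert kb2.instance_is_of(sk, "Inflammation")
        assert kb2.has_fact("has_realization", "m_disp", sk)
        assert kb2.has_fact("has_trigger_R", sk, "strike1")

    def test_haemophilia_bleeding_realized_on_lesion(self):
        kb2, _ = saturate(build_worked_example("haemophilia"))
        bleeds = kb2.instances_of("Bleeding")
        assert len(bleeds) == 1
        (r,) = bleeds
        assert kb2.has_fact("has_trigger_R", r, "lesion1")

    def test_unrealized_without_trigger_instance(self, match_kb):
        del match_kb.instances["strike1"]
        kb2, traces = apply_realization_principle(match_kb)
        assert not kb2.facts_with("has_realization")
        assert not traces

    def test_asserted_realization_suppresses_skolem(self):
        kb2, _ = saturate(build_worked_example("patellar"))
        assert not [x for x in kb2.instances if x.startswith("__sk.")]

    def test_surefire_without_trigger_types_warns_and_skips(self):
        kb = KnowledgeBase()
        kb.add_type(TypeDecl("Nucleus", OntKind.MATERIAL_ENTITY))
        kb.add_type(TypeDecl("DecayDisposition", OntKind.DISPOSITION))
        kb.add_type(TypeDecl("Decay", OntKind.PROCESS))
        kb.add_axiom(DispositionAxiom("DecayDisposition", ("Decay",),
                                      trigger_types=(), surefire=True))
        kb.add_instance(InstanceDecl("n1", frozenset({"Nucleus"})))
        kb.add_instance(InstanceDecl("d1", frozenset({"DecayDisposition"})))
        kb.add_fact(Fact("inheres_in", "d1", "n1"))
        with pytest.warns(UserWarning, match="no trigger"):
            kb2, _ = saturate(kb)
        assert not kb2.facts_with("has_realization")


class TestBearerPrinciple:
    def test_bearer_participates_in_skolem_realization(self, match_kb):
        kb2, _ = saturate(match_kb)
        sk = "__sk.REAL9.m_disp.strike1.Inflammation"
        assert kb2.has_fact("has_participant", sk, "match1")

    def test_bearerless_disposition_skipped(self, match_kb):
        del match_kb._facts[("inheres_in", "m_disp", "match1")]
        kb2, _ = saturate(match_kb)
        assert not kb2.facts_with("has_realization")
        assert not kb2.facts_with("has_participant")

    def test_asserted_realizations_of_surefire_get_participants(self):
        kb2, _ = saturate(build_worked_example("patellar"))
        assert kb2.has_fact("has_participant", "jerk1", "patient1")
        assert kb2.has_fact("has_participant", "jerk2", "patient1")

    def test_shared_process_gets_both_bearers_no_converse(self):
        # two dispositions of two bearers realized by one asserted process:
        # both bearers participate; no disposition is inferred from the process
        kb = KnowledgeBase()
        kb.add_type(TypeDecl("Key", OntKind.MATERIAL_ENTITY))
        kb.add_type(TypeDecl("Lock", OntKind.MATERIAL_ENTITY))
        kb.add_type(TypeDecl("OpeningDisposition", OntKind.DISPOSITION))
        kb.add_type(TypeDecl("Turning", OntKind.PROCESS))
        kb.add_type(TypeDecl("Opening", OntKind.PROCESS))
        kb.add_axiom(DispositionAxiom("OpeningDisposition", ("Opening",),
                                      ("Turning",), surefire=True))
        kb.add_instance(InstanceDecl("key1", frozenset({"Key"})))
        kb.add_instance(InstanceDecl("lock1", frozenset({"Lock"})))
        kb.add_instance(InstanceDecl("dk", frozenset({"OpeningDisposition"})))
        kb.add_instance(InstanceDecl("dl", frozenset({"OpeningDisposition"})))
        kb.add_instance(InstanceDecl("turn1", frozenset({"Turning"})))
        kb.add_instance(InstanceDecl("open1", frozenset({"Opening"})))
        kb.add_fact(Fact("inheres_in", "dk", "key1"))
        kb.add_fact(Fact("inheres_in", "dl", "lock1"))
        kb.add_fact(Fact("has_realization", "dk", "open1"))
        kb.add_fact(Fact("has_realization", "dl", "open1"))
        kb.add_fact(Fact("has_trigger_R", "open1", "turn1"))
        kb2, _ = saturate(kb)
        assert kb2.has_fact("has_participant", "open1", "key1")
        assert kb2.has_fact("has_participant", "open1", "lock1")
        # no new has_realization facts pointing at open1 beyond the asserted two
        assert len(kb2.facts_with("has_realization", object="open1")) == 2


class TestBasePrinciple:
    def test_salt_structure_brings_solubility(self):
        kb = build_worked_example("salt_solubility")
        kb2, _ = apply_base_principle(kb)
        sk = "__sk.BASE8.NaClStructure.WaterSolubility.salt1"
        assert sk in kb2.instances
        assert kb2.instance_is_of(sk, "WaterSolubility")
        assert kb2.has_fact("inheres_in", sk, "salt1")

    def test_idempotent(self):
        kb2, _ = saturate(build_worked_example("salt_solubility"))
        kb3, traces = saturate(kb2)
        assert kb3 == kb2 and not traces

    def test_asserted_witness_suppresses_skolem(self):
        kb = build_worked_example("salt_solubility")
        kb.add_instance(InstanceDecl("sol1", frozenset({"WaterSolubility"})))
        kb.add_fact(Fact("inheres_in", "sol1", "salt1"))
        kb2, _ = apply_base_principle(kb)
        assert not [x for x in kb2.instances if x.startswith("__sk.BASE8")]

    def test_two_base_types_each_yield_a_disposition(self):
        # distinct base-quality types of the same disposition type each
        # ground their own witness
        kb = build_worked_example("salt_solubility")
        kb.add_type(TypeDecl("CrystalLattice", OntKind.QUALITY))
        kb.add_axiom(DispositionAxiom(
            "WaterSolubility", ("Dissolution",), ("Immersion",),
            bearer_type="Salt", base_type="CrystalLattice", surefire=True))
        kb.add_instance(InstanceDecl("salt2", frozenset({"Salt"})))
        kb.add_instance(InstanceDecl("q2", frozenset({"CrystalLattice"})))
        kb.add_fact(Fact("inheres_in", "q2", "salt2"))
        kb2, _ = saturate(kb)
        assert "__sk.BASE8.NaClStructure.WaterSolubility.salt1" in kb2.instances
        assert "__sk.BASE8.CrystalLattice.WaterSolubility.salt2" in kb2.instances


class TestEssentialDispositions:
    def test_every_aspirin_gets_a_pain_relief_disposition(self):
        kb2, _ = saturate(build_worked_example("aspirin"))
        sk = "__sk.ESS2.Aspirin.PainReliefDisposition.asp1"
        assert sk in kb2.instances
        assert kb2.has_fact("has_disposition", "asp1", sk)
        # the paracetamol's asserted disposition is untouched
        assert kb2.has_fact("has_disposition", "para1", "pr1")


class TestSaturation:
    def test_empty_kb(self):
        kb2, traces = saturate(KnowledgeBase())
        assert kb2 == KnowledgeBase() and not traces

    def test_salt_cascade_base_then_realization_then_bearer(self):
        kb2, traces = saturate(build_worked_example("salt_solubility"))
        rules = [t.rule for t in traces]
        assert rules.index("BASE8") < rules.index("REAL9") < rules.index("BEARER10")
        d = "__sk.BASE8.NaClStructure.WaterSolubility.salt1"
        r = f"__sk.REAL9.{d}.imm1.Dissolution"
        assert kb2.has_fact("has_participant", r, "salt1")
        assert kb2.has_fact("has_trigger_D", d, "imm1")

    def test_monotone_and_idempotent_on_random_corpus(self):
        for kb in random_corpus(60):
            kb2, _ = saturate(kb)
            assert _atoms(kb) <= _atoms(kb2)
            kb3, traces = saturate(kb2)
            assert kb3 == kb2 and not traces

    def test_rule_order_independent(self):
        from dispkb.instance_reasoner import (
            _base_pass, _bearer_pass, _essential_pass, _realization_pass,
            _run_definitional,
        )
        policy = SkolemPolicy()
        orders = [
            ("ess", "base", "real", "bearer", "def"),
            ("def", "bearer", "real", "base", "ess"),
            ("real", "def", "ess", "bearer", "base"),
        ]
        passes = {
            "ess": lambda kb, tr: _essential_pass(kb, policy, tr),
            "base": lambda kb, tr: _base_pass(kb, policy, tr),
            "real": lambda kb, tr: _realization_pass(kb, policy, tr),
            "bearer": lambda kb, tr: _bearer_pass(kb, policy, tr),
            "def": lambda kb, tr: _run_definitional(kb, tr),
        }
        for kb in random_corpus(25):
            results = []
            for order in orders:
                k = kb.copy()
                tr = []
                while any([passes[name](k, tr) for name in order]):
                    pass
                results.append((_atoms(k), frozenset(k.instances)))
            assert results[0] == results[1] == results[2]

    def test_derived_facts_have_traces(self, match_kb):
        kb2, traces = saturate(match_kb)
        traced = {t.derived for t in traces}
        for f in kb2.facts:
            if f.provenance == "derived":
                assert f.atom in traced
        for x, inst in kb2.instances.items():
            if inst.provenance == "skolem":
                assert ("instance", x) in traced

    def test_no_skolem_mode_reports_without_creating(self, match_kb):
        kb2, traces = saturate(match_kb, SkolemPolicy(enabled=False))
        assert set(kb2.instances) == set(match_kb.instances)
        pending = [t for t in traces if not t.applied]
        assert any(t.rule == "REAL9" for t in pending)
        # definitional facts still derived
        assert kb2.has_fact("has_disposition", "match1", "m_disp")

    def test_skolem_names_replay_stable(self, match_kb):
        kb_a, _ = saturate(match_kb.copy())
        kb_b, _ = saturate(match_kb.copy())
        assert set(kb_a.instances) == set(kb_b.instances)
        assert _atoms(kb_a) == _atoms(kb_b)
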