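"""Worked-example knowledge bases and seeded random KB generation.

The catalogue encodes classic disposition scenarios from the applied
ontology literature — a match's inflammability, a haemophiliac's
tendency to bleed on lesion, penicillin hypersensitivity (the trigger is
the exposure *event*, not the substance), Gram-stainability of
Gram-positive bacteria, the patellar reflex (repeatedly triggerable),
water-solubility of salt grounded in the NaCl molecular structure, the
litmus paper's two-track colour response, multi-track multi-trigger
fragility, an essential pain-relief disposition of aspirin, and a
dormant infectious disease (disorder present, trigger absent, nothing
realized).  Identifier choices are this package's own; each fixture
carries a comment stating the scenario.

:func:`generate_random_kb` builds small, structurally valid KBs for
property testing: identical parameters give bitwise-identical KBs, and a
fresh KB validates with zero violations both before and after
saturation.  :func:`mutate_kb` injects exactly one structural fault and
reports the violation code the validator must raise for it.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass

from .core_model import (
    DispositionAxiom,
    Fact,
    InstanceDecl,
    KBError,
    KnowledgeBase,
    OntKind,
    TypeDecl,
)
from .io_formats import kb_from_document

ME, QU, DI, PR = (k.value for k in OntKind)


def _doc(types, axioms, instances, facts, comment=""):
    return {
        "format_version": "1.0",
        "types": [{"name": n, "kind": k, "parents": p} for n, k, p in types],
        "axioms": axioms,
        "instances": [{"name": n, "types": t} for n, t in instances],
        "facts": [{"relation": r, "subject": s, "object": o} for r, s, o in facts],
    }


WORKED_EXAMPLES: dict[str, dict] = {
    "match": _doc(
        types=[("Match", ME, []), ("Inflammability", DI, []),
               ("Striking", PR, []), ("Inflammation", PR, [])],
        axioms=[{"disposition_type": "Inflammability",
                 "realization_types": ["Inflammation"],
                 "trigger_types": ["Striking"],
                 "bearer_type": "Match", "surefire": True,
                 "comment": "a match inflames when struck"}],
        instances=[("match1", ["Match"]), ("m_disp", ["Inflammability"]),
                   ("strike1", ["Striking"])],
        facts=[("inheres_in", "m_disp", "match1")],
    ),
    "haemophilia": _doc(
        types=[("Patient", ME, []), ("Haemophilia", DI, []),
               ("Lesion", PR, []), ("Bleeding", PR, [])],
        axioms=[{"disposition_type": "Haemophilia",
                 "realization_types": ["Bleeding"],
                 "trigger_types": ["Lesion"],
                 "bearer_type": "Patient", "surefire": True,
                 "comment": "tendency to bleed on lesion without proper coagulation"}],
        instances=[("patient1", ["Patient"]), ("h_disp", ["Haemophilia"]),
                   ("lesion1", ["Lesion"])],
        facts=[("inheres_in", "h_disp", "patient1")],
    ),
    "penicillin_allergy": _doc(
        types=[("Patient", ME, []), ("PenicillinAllergy", DI, []),
               ("PenicillinExposure", PR, []), ("AllergicReaction", PR, [])],
        axioms=[{"disposition_type": "PenicillinAllergy",
                 "realization_types": ["AllergicReaction"],
                 "trigger_types": ["PenicillinExposure"],
                 "bearer_type": "Patient", "surefire": True,
                 "comment": "hypersensitivity; the trigger is the exposure "
                            "event between patient and allergen, not the substance"}],
        instances=[("patient1", ["Patient"]), ("patient2", ["Patient"]),
                   ("allergy1", ["PenicillinAllergy"]),
                   ("exposure1", ["PenicillinExposure"])],
        facts=[("inheres_in", "allergy1", "patient1")],
    ),
    "gram_stain": _doc(
        types=[("GramPositiveSample", ME, []), ("GramStainability", DI, []),
               ("GramStaining", PR, []), ("BlueStaining", PR, [])],
        axioms=[{"disposition_type": "GramStainability",
                 "realization_types": ["BlueStaining"],
                 "trigger_types": ["GramStaining"],
                 "bearer_type": "GramPositiveSample", "surefire": True,
                 "comment": "a Gram-positive sample turns dark blue when Gram-stained"}],
        instances=[("sample1", ["GramPositiveSample"]),
                   ("stain_disp", ["GramStainability"]),
                   ("staining1", ["GramStaining"])],
        facts=[("inheres_in", "stain_disp", "sample1")],
    ),
    "patellar": _doc(
        types=[("Patient", ME, []), ("PatellarReflexDisposition", DI, []),
               ("PatellarTap", PR, []), ("KneeJerk", PR, [])],
        axioms=[{"disposition_type": "PatellarReflexDisposition",
                 "realization_types": ["KneeJerk"],
                 "trigger_types": ["PatellarTap"],
                 "bearer_type": "Patient", "surefire": True,
                 "comment": "knee-jerk reflex; triggerable repeatedly, one jerk per tap"}],
        instances=[("patient1", ["Patient"]),
                   ("reflex1", ["PatellarReflexDisposition"]),
                   ("tap1", ["PatellarTap"]), ("tap2", ["PatellarTap"]),
                   ("jerk1", ["KneeJerk"]), ("jerk2", ["KneeJerk"])],
        facts=[("inheres_in", "reflex1", "patient1"),
               ("has_realization", "reflex1", "jerk1"),
               ("has_trigger_R", "jerk1", "tap1"),
               ("has_realization", "reflex1", "jerk2"),
               ("has_trigger_R", "jerk2", "tap2")],
    ),
    "salt_solubility": _doc(
        types=[("Salt", ME, []), ("NaClStructure", QU, []),
               ("WaterSolubility", DI, []),
               ("Immersion", PR, []), ("Dissolution", PR, [])],
        axioms=[{"disposition_type": "WaterSolubility",
                 "realization_types": ["Dissolution"],
                 "trigger_types": ["Immersion"],
                 "bearer_type": "Salt", "base_type": "NaClStructure",
                 "surefire": True,
                 "comment": "solubility grounded in the NaCl molecular structure; "
                            "base brings the disposition, immersion realizes it"}],
        instances=[("salt1", ["Salt"]), ("q1", ["NaClStructure"]),
                   ("imm1", ["Immersion"])],
        facts=[("inheres_in", "q1", "salt1")],
    ),
    "litmus": _doc(
        types=[("LitmusPaper", ME, []), ("LitmusResponsiveness", DI, []),
               ("SolutionContact", PR, []),
               ("BlueShift", PR, []), ("RedShift", PR, [])],
        axioms=[{"disposition_type": "LitmusResponsiveness",
                 "realization_types": ["BlueShift", "RedShift"],
                 "trigger_types": ["SolutionContact"],
                 "bearer_type": "LitmusPaper", "surefire": True,
                 "comment": "two-track colour response: blue or red depending "
                            "on the pH of the contacted solution"}],
        instances=[("paper1", ["LitmusPaper"]),
                   ("litmus_disp", ["LitmusResponsiveness"]),
                   ("dip_acid", ["SolutionContact"]),
                   ("dip_base", ["SolutionContact"]),
                   ("red1", ["RedShift"]), ("blue1", ["BlueShift"])],
        facts=[("inheres_in", "litmus_disp", "paper1"),
               ("has_realization", "litmus_disp", "red1"),
               ("has_trigger_R", "red1", "dip_acid"),
               ("has_realization", "litmus_disp", "blue1"),
               ("has_trigger_R", "blue1", "dip_base")],
    ),
    "fragility_multitrack": _doc(
        types=[("Glass", ME, []), ("Fragility", DI, []),
               ("Striking", PR, []), ("Throwing", PR, []),
               ("Breaking", PR, []), ("Cracking", PR, []),
               ("Splintering", PR, [])],
        axioms=[{"disposition_type": "Fragility",
                 "realization_types": ["Breaking", "Cracking", "Splintering"],
                 "trigger_types": ["Striking", "Throwing"],
                 "bearer_type": "Glass", "surefire": True,
                 "comment": "multi-track, multi-trigger: a fragile glass may "
                            "break, crack or splinter when struck or thrown"}],
        instances=[("glass1", ["Glass"]), ("frag1", ["Fragility"]),
                   ("strike1", ["Striking"])],
        facts=[("inheres_in", "frag1", "glass1")],
    ),
    "aspirin": _doc(
        types=[("Tablet", ME, []), ("Aspirin", ME, ["Tablet"]),
               ("Paracetamol", ME, ["Tablet"]),
               ("PainReliefDisposition", DI, []),
               ("Ingestion", PR, []), ("PainRelief", PR, [])],
        axioms=[{"disposition_type": "PainReliefDisposition",
                 "realization_types": ["PainRelief"],
                 "trigger_types": ["Ingestion"],
                 "bearer_type": "Tablet", "essential_of": "Aspirin",
                 "surefire": True,
                 "comment": "pain relief is essential to aspirin; bearers of the "
                            "same disposition type may be tablets of different types"}],
        instances=[("asp1", ["Aspirin"]), ("para1", ["Paracetamol"]),
                   ("pr1", ["PainReliefDisposition"])],
        facts=[("inheres_in", "pr1", "para1")],
    ),
    "disease": _doc(
        types=[("Organism", ME, []), ("PathogenColonization", QU, []),
               ("InfectiousDisease", DI, []),
               ("ImmuneChallenge", PR, []), ("DiseaseCourse", PR, [])],
        axioms=[{"disposition_type": "InfectiousDisease",
                 "realization_types": ["DiseaseCourse"],
                 "trigger_types": ["ImmuneChallenge"],
                 "bearer_type": "Organism",
                 "base_type": "PathogenColonization", "surefire": True,
                 "comment": "disorder (colonization quality) as base of the disease "
                            "disposition, course of disease as realization; with no "
                            "trigger instance the disease stays dormant"}],
        instances=[("host1", ["Organism"]),
                   ("colonization1", ["PathogenColonization"])],
        facts=[("inheres_in", "colonization1", "host1")],
    ),
}


def fixture_names() -> list[str]:
    return sorted(WORKED_EXAMPLES)


def build_worked_example(name: str) -> KnowledgeBase:
    """Build a catalogue fixture by name; unknown names raise KeyError."""
    if name not in WORKED_EXAMPLES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}")
    return kb_from_document(copy.deepcopy(WORKED_EXAMPLES[name]))


# -------------------------------------------------------------- random KBs


@dataclass(frozen=True)
class RandomKBParams:
    seed: int = 0
    n_material: int = 2          # number of bearer instances
    n_disposition_types: int = 2
    n_process_types: int = 3
    p_trigger: float = 0.5       # chance a disposition's trigger type is instantiated
    p_multitrack: float = 0.25   # chance an axiom is multi-track / multi-trigger
    max_tracks: int = 3
    p_base: float = 0.3          # chance an axiom is grounded in a base quality
    p_asserted_realization: float = 0.3
    p_subtype: float = 0.3       # chance a disposition type specializes another


def generate_random_kb(params: RandomKBParams) -> KnowledgeBase:
    """Deterministic small KB with the requested shape.

    Every axiom is surefire; trigger instances appear with probability
    ``p_trigger``, so with ``p_trigger=0`` saturation adds no realization
    at all (dispositions stay unrealized).  Realization and trigger types
    are drawn from disjoint pools, and a specializing disposition type
    inherits its parent's tracks, so the generated KB validates with zero
    violations before and after saturation.
    """
    if params.n_disposition_types > 0 and params.n_process_types < 2:
        raise KBError("need at least 2 process types to form trigger and "
                      "realization pools")
    rng = random.Random(params.seed)
    kb = KnowledgeBase()
    kb.add_type(TypeDecl("Mat", OntKind.MATERIAL_ENTITY))
    n_real_pool = max(1, params.n_process_types // 2 + params.n_process_types % 2)
    proc = [f"P{i}" for i in range(params.n_process_types)]
    for p in proc:
        kb.add_type(TypeDecl(p, OntKind.PROCESS))
    real_pool, trig_pool = proc[:n_real_pool], proc[n_real_pool:]
    if not trig_pool:
        trig_pool = real_pool[-1:]
        real_pool = real_pool[:-1] or trig_pool

    disp_types = [f"D{i}" for i in range(params.n_disposition_types)]
    axiom_of: dict[str, DispositionAxiom] = {}
    for i, D in enumerate(disp_types):
        parent = None
        if i > 0 and rng.random() < params.p_subtype:
            parent = disp_types[rng.randrange(i)]
        kb.add_type(TypeDecl(D, OntKind.DISPOSITION,
                             frozenset({parent} if parent else ())))
        if parent is not None:
            # a specialization keeps its parent's tracks, so the two value
            # restrictions cannot disagree on shared instances
            pax = axiom_of[parent]
            realizations, triggers = pax.realization_types, pax.trigger_types
        else:
            k = 1
            if rng.random() < params.p_multitrack and len(real_pool) >= 2:
                k = rng.randint(2, min(params.max_tracks, len(real_pool)))
            realizations = tuple(sorted(rng.sample(real_pool, k)))
            kt = 1
            if rng.random() < params.p_multitrack and len(trig_pool) >= 2:
                kt = rng.randint(2, min(params.max_tracks, len(trig_pool)))
            triggers = tuple(sorted(rng.sample(trig_pool, kt)))
        base = None
        if rng.random() < params.p_base:
            base = f"Q_{D}"
            kb.add_type(TypeDecl(base, OntKind.QUALITY))
        ax = DispositionAxiom(
            disposition_type=D, realization_types=realizations,
            trigger_types=triggers, bearer_type="Mat", base_type=base,
            surefire=True)
        kb.add_axiom(ax)
        axiom_of[D] = ax

    bearers = [f"b{i}" for i in range(params.n_material)]
    for b in bearers:
        kb.add_instance(InstanceDecl(b, frozenset({"Mat"})))

    counter = 0
    for D in disp_types:
        ax = axiom_of[D]
        if bearers and rng.random() < 0.7:
            d = f"d{counter}"
            counter += 1
            kb.add_instance(InstanceDecl(d, frozenset({D})))
            kb.add_fact(Fact("inheres_in", d, rng.choice(bearers)))
            if rng.random() < params.p_asserted_realization:
                r = f"r{counter}"
                t = f"t{counter}"
                counter += 1
                kb.add_instance(InstanceDecl(r, frozenset({rng.choice(ax.realization_types)})))
                kb.add_instance(InstanceDecl(t, frozenset({rng.choice(ax.trigger_types)})))
                kb.add_fact(Fact("has_realization", d, r))
                kb.add_fact(Fact("has_trigger_R", r, t))
        if ax.base_type and bearers and rng.random() < 0.7:
            q = f"q{counter}"
            counter += 1
            kb.add_instance(InstanceDecl(q, frozenset({ax.base_type})))
            kb.add_fact(Fact("inheres_in", q, rng.choice(bearers)))
        if rng.random() < params.p_trigger:
            t = f"t{counter}"
            counter += 1
            kb.add_instance(InstanceDecl(t, frozenset({rng.choice(ax.trigger_types)})))
    return kb


# ----------------------------------------------------------- fault injection

FAULTS = (
    "wrong-realization-type",
    "missing-trigger",
    "bearerless-disposition",
    "reversed-participant",
    "asserted-derived-relation",
)


class FaultNotApplicable(KBError):
    pass


def _first_axiom_with_disposition(kb: KnowledgeBase):
    for ax in sorted(kb.axioms, key=lambda a: a.key()):
        insts = sorted(kb.instances_of(ax.disposition_type))
        if insts:
            return ax, insts[0]
    return None, None


def mutate_kb(kb: KnowledgeBase, fault: str, seed: int = 0
              ) -> tuple[KnowledgeBase, str]:
    """Inject exactly one structural fault; returns the mutated KB and the
    violation code the validator is expected to raise (and nothing else).
    """
    if fault not in FAULTS:
        raise KeyError(f"unknown fault {fault!r}; available: {', '.join(FAULTS)}")
    kb = kb.copy()
    ax, d = _first_axiom_with_disposition(kb)

    if fault == "wrong-realization-type":
        if d is None:
            raise FaultNotApplicable("no instantiated disposition axiom")
        if "AnomalousProcess" not in kb.types:
            kb.add_type(TypeDecl("AnomalousProcess", OntKind.PROCESS))
        kb.add_instance(InstanceDecl("anomalous_r", frozenset({"AnomalousProcess"})))
        kb.add_fact(Fact("has_realization", d, "anomalous_r"))
        return kb, "VR_REAL"

    if fault == "missing-trigger":
        if d is None or not ax.trigger_types:
            raise FaultNotApplicable("no instantiated, triggered disposition axiom")
        r_type = ax.realization_types[0]
        kb.add_instance(InstanceDecl("untriggered_r", frozenset({r_type})))
        kb.add_fact(Fact("has_realization", d, "untriggered_r"))
        return kb, "AS_TRIG"

    if fault == "bearerless-disposition":
        kb.add_type(TypeDecl("OrphanDisposition", OntKind.DISPOSITION))
        kb.add_instance(InstanceDecl("orphan_disp", frozenset({"OrphanDisposition"})))
        return kb, "BEAR1"

    if fault == "reversed-participant":
        materials = sorted(
            x for x in kb.instances
            if kb.kind_of_instance(x) is OntKind.MATERIAL_ENTITY)
        processes = sorted(
            x for x in kb.instances
            if kb.kind_of_instance(x) is OntKind.PROCESS)
        if not materials or not processes:
            raise FaultNotApplicable("needs a material and a process instance")
        kb.add_fact(Fact("has_participant", materials[0], processes[0]))
        return kb, "SQ3"

    if fault == "asserted-derived-relation":
        dispositions = sorted(
            x for x in kb.instances
            if kb.kind_of_instance(x) is OntKind.DISPOSITION)
        materials = sorted(
            x for x in kb.instances
            if kb.kind_of_instance(x) is OntKind.MATERIAL_ENTITY)
        if not dispositions or not materials:
            raise FaultNotApplicable("needs a disposition and a material instance")
        # the store refuses asserted definitional facts, so the fault must
        # enter through the unchecked path the loader never uses
        kb._add_fact_unchecked(
            Fact("has_disposition", materials[0], dispositions[0]))
        return kb, "ASSERTED_DERIVED"

    raise AssertionError("unreachable")
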