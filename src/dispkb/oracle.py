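"""Independent brute-force semantics: a ground first-order evaluator and a
naive fixpoint, used as the test oracle for the reasoner and validator.

Quantification is substitutional over the finite instance domain of the
knowledge base (declared plus skolem instances).  This deliberately
matches the closed-world validator: a "possible but absent" realization
is outside the formal model, so an unrealized disposition makes the
realization value-restriction vacuously true rather than unknown.

:func:`naive_fixpoint` re-derives the saturation of a knowledge base by
full rescans with no indexing, no stratification and no shared code with
:mod:`dispkb.instance_reasoner` beyond the skolem naming function (shared
on purpose, so the two derivations are comparable atom for atom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .core_model import (
    DEPENDENT_KINDS,
    Fact,
    InstanceDecl,
    KnowledgeBase,
    OntKind,
)
from .instance_reasoner import default_skolem_name

Term = str  # a "?var" or an instance identifier


# ------------------------------------------------------------------ formulas


@dataclass(frozen=True)
class Atom:
    relation: str
    subject: Term
    object: Term


@dataclass(frozen=True)
class IsInstance:
    term: Term
    type: str  # declared type or union


@dataclass(frozen=True)
class KindIs:
    term: Term
    kind: OntKind


@dataclass(frozen=True)
class Not:
    body: "GroundFormula"


@dataclass(frozen=True)
class And:
    parts: tuple


@dataclass(frozen=True)
class Or:
    parts: tuple


@dataclass(frozen=True)
class Implies:
    left: "GroundFormula"
    right: "GroundFormula"


@dataclass(frozen=True)
class Iff:
    left: "GroundFormula"
    right: "GroundFormula"


@dataclass(frozen=True)
class ForAll:
    var: str
    body: "GroundFormula"


@dataclass(frozen=True)
class Exists:
    var: str
    body: "GroundFormula"


GroundFormula = Union[Atom, IsInstance, KindIs, Not, And, Or, Implies, Iff,
                      ForAll, Exists]


def conj(*parts: GroundFormula) -> And:
    return And(tuple(parts))


def disj(*parts: GroundFormula) -> Or:
    return Or(tuple(parts))


def _resolve(term: Term, env: dict[str, str]) -> str:
    if term.startswith("?"):
        try:
            return env[term]
        except KeyError:
            raise KeyError(f"unbound variable {term}") from None
    return term


def eval(kb: KnowledgeBase, f: GroundFormula,
         env: Optional[dict[str, str]] = None) -> bool:
    """Truth of *f* under substitutional quantification over kb's
    instances.  Side-effect free; terminates on any finite store."""
    env = env or {}
    if isinstance(f, Atom):
        s, o = _resolve(f.subject, env), _resolve(f.object, env)
        for x in (s, o):
            if x not in kb.instances:
                raise KeyError(f"unknown instance {x!r}")
        return kb.has_fact(f.relation, s, o)
    if isinstance(f, IsInstance):
        return kb.instance_is_of(_resolve(f.term, env), f.type)
    if isinstance(f, KindIs):
        x = _resolve(f.term, env)
        return any(kb.types[t].kind is f.kind for t in kb.instances[x].types)
    if isinstance(f, Not):
        return not eval(kb, f.body, env)
    if isinstance(f, And):
        return all(eval(kb, p, env) for p in f.parts)
    if isinstance(f, Or):
        return any(eval(kb, p, env) for p in f.parts)
    if isinstance(f, Implies):
        return (not eval(kb, f.left, env)) or eval(kb, f.right, env)
    if isinstance(f, Iff):
        return eval(kb, f.left, env) is eval(kb, f.right, env)
    if isinstance(f, (ForAll, Exists)):
        domain = sorted(kb.instances)
        results = (eval(kb, f.body, {**env, f.var: x}) for x in domain)
        return all(results) if isinstance(f, ForAll) else any(results)
    raise TypeError(f"not a formula: {f!r}")


# -------------------------------------------------- transcription of the laws


def law_has_disposition() -> GroundFormula:
    """has_disposition is exactly inverse inherence of disposition
    instances."""
    return ForAll("?x", ForAll("?d", Iff(
        Atom("has_disposition", "?x", "?d"),
        conj(KindIs("?d", OntKind.DISPOSITION), Atom("inheres_in", "?d", "?x")),
    )))


def law_trigger_D() -> GroundFormula:
    """has_trigger_D is exactly triggering-through-a-realization."""
    return ForAll("?d", ForAll("?t", Iff(
        Atom("has_trigger_D", "?d", "?t"),
        Exists("?r", conj(Atom("has_realization", "?d", "?r"),
                          Atom("has_trigger_R", "?r", "?t"))),
    )))


def law_base(kb: KnowledgeBase, axiom) -> GroundFormula:
    """Base principle for one axiom: every borne instance of the base
    quality comes with a disposition instance in the same bearer."""
    D, Q = axiom.disposition_type, axiom.base_type
    return ForAll("?q", Implies(
        IsInstance("?q", Q),
        ForAll("?b", Implies(
            Atom("inheres_in", "?q", "?b"),
            Exists("?d", conj(IsInstance("?d", D),
                              Atom("inheres_in", "?d", "?b"))),
        )),
    ))


def law_essential(kb: KnowledgeBase, axiom) -> GroundFormula:
    """All-some essential disposition: every instance of the host kind
    bears an instance of the disposition type."""
    D, A = axiom.disposition_type, axiom.essential_of
    return ForAll("?x", Implies(
        IsInstance("?x", A),
        Exists("?d", conj(IsInstance("?d", D), Atom("inheres_in", "?d", "?x"))),
    ))


def law_realization(kb: KnowledgeBase, axiom) -> GroundFormula:
    """Surefire realization principle, instance-level strengthening: for
    every borne instance of the disposition type and every instance of
    the trigger type there is a realization in the declared track(s),
    triggered by that very trigger."""
    from . import multitrack

    D = axiom.disposition_type
    T = multitrack.trigger_scope(kb, axiom)
    R = multitrack.realization_scope(kb, axiom)
    return ForAll("?d", Implies(
        conj(IsInstance("?d", D), Exists("?b", Atom("inheres_in", "?d", "?b"))),
        ForAll("?t", Implies(
            IsInstance("?t", T),
            Exists("?r", conj(IsInstance("?r", R),
                              Atom("has_realization", "?d", "?r"),
                              Atom("has_trigger_R", "?r", "?t"))),
        )),
    ))


def law_bearer(kb: KnowledgeBase, axiom) -> GroundFormula:
    """Bearer principle: the realization the surefire principle guarantees
    has the disposition's bearer as a participant."""
    from . import multitrack

    D = axiom.disposition_type
    T = multitrack.trigger_scope(kb, axiom)
    R = multitrack.realization_scope(kb, axiom)
    return ForAll("?d", ForAll("?b", Implies(
        conj(IsInstance("?d", D), Atom("inheres_in", "?d", "?b")),
        ForAll("?t", Implies(
            IsInstance("?t", T),
            Exists("?r", conj(IsInstance("?r", R),
                              Atom("has_realization", "?d", "?r"),
                              Atom("has_trigger_R", "?r", "?t"),
                              Atom("has_participant", "?r", "?b"))),
        )),
    )))


# ------------------------------------------------------------- naive fixpoint


def naive_fixpoint(kb: KnowledgeBase, naming=default_skolem_name) -> KnowledgeBase:
    """Saturate by repeated full rescans with no indexing.

    Rule semantics mirror the reasoner's specification — per-axiom,
    per-premise skolem witnesses with asserted-witness suppression — but
    the code is a flat, unoptimized restatement written against the rule
    descriptions, not against the reasoner.
    """
    kb = kb.copy()
    while _one_round(kb, naming):
        pass
    return kb


def _one_round(kb: KnowledgeBase, naming) -> bool:
    changed = False
    facts = list(kb.facts)
    instances = dict(kb.instances)

    def kind(x):
        return {kb.types[t].kind for t in kb.instances[x].types}

    def add_fact(rel, s, o):
        nonlocal changed
        if not kb.has_fact(rel, s, o):
            kb.add_fact(Fact(rel, s, o, provenance="derived"))
            changed = True

    def add_skolem(name, type_):
        nonlocal changed
        if name not in kb.instances:
            kb.add_instance(InstanceDecl(name, frozenset({type_}),
                                         provenance="skolem"))
            changed = True
            return True
        return False

    # definitional: has_disposition
    for f in facts:
        if f.relation == "inheres_in" and OntKind.DISPOSITION in kind(f.subject):
            add_fact("has_disposition", f.object, f.subject)
    # definitional: has_trigger_D
    for f in facts:
        if f.relation != "has_realization":
            continue
        for g in facts:
            if g.relation == "has_trigger_R" and g.subject == f.object:
                add_fact("has_trigger_D", f.subject, g.object)

    from . import multitrack

    def asserted_witness(D, b):
        return any(
            f.relation == "inheres_in" and f.object == b
            and kb.instances[f.subject].provenance == "asserted"
            and D in kb.instances[f.subject].types
            for f in kb.facts
        )

    for ax in sorted(kb.axioms, key=lambda a: a.key()):
        D = ax.disposition_type
        # essential dispositions
        if ax.essential_of:
            for x in sorted(instances):
                if not kb.instance_is_of(x, ax.essential_of):
                    continue
                if asserted_witness(D, x):
                    continue
                name = naming("ESS2", ax.essential_of, D, x)
                if add_skolem(name, D):
                    add_fact("inheres_in", name, x)
        # base principle
        if ax.base_type:
            for q in sorted(instances):
                if not kb.instance_is_of(q, ax.base_type):
                    continue
                for f in facts:
                    if f.relation != "inheres_in" or f.subject != q:
                        continue
                    b = f.object
                    if asserted_witness(D, b):
                        continue
                    name = naming("BASE8", ax.base_type, D, b)
                    if add_skolem(name, D):
                        add_fact("inheres_in", name, b)
        # realization + bearer principles (surefire, triggered)
        if ax.surefire and ax.trigger_types:
            T = multitrack.trigger_scope(kb, ax)
            R = multitrack.realization_scope(kb, ax)
            first = ax.realization_types[0]
            if first in kb.unions:
                first = kb.unions[first][0]
            rule = "REAL13" if R in kb.unions else "REAL9"
            for d in sorted(kb.instances):
                if not kb.instance_is_of(d, D):
                    continue
                bearers = sorted(
                    f.object for f in kb.facts
                    if f.relation == "inheres_in" and f.subject == d
                )
                if not bearers:
                    continue
                for t in sorted(kb.instances):
                    if not kb.instance_is_of(t, T):
                        continue
                    witnessed = any(
                        f.relation == "has_realization" and f.subject == d
                        and kb.has_fact("has_trigger_R", f.object, t)
                        and kb.instance_is_of(f.object, R)
                        for f in kb.facts
                    )
                    if not witnessed:
                        name = naming(rule, d, t, first)
                        add_skolem(name, first)
                        add_fact("has_realization", d, name)
                        add_fact("has_trigger_R", name, t)
        # bearer principle over every realization of a surefire disposition
        if ax.surefire:
            for d in sorted(kb.instances):
                if not kb.instance_is_of(d, D):
                    continue
                for f in list(kb.facts):
                    if f.relation != "has_realization" or f.subject != d:
                        continue
                    for g in list(kb.facts):
                        if g.relation == "inheres_in" and g.subject == d:
                            add_fact("has_participant", f.object, g.object)
    return changed


# ----------------------------------------------------- exhaustive ground check


def ground_validate(kb: KnowledgeBase) -> list[tuple[str, tuple[str, ...]]]:
    """Exhaustive closed-world check, enumerating ground instantiations of
    every validated formula; returns (code, entities) pairs comparable to
    the validator's report."""
    from . import multitrack

    out: list[tuple[str, tuple[str, ...]]] = []

    def kinds(x):
        return {kb.types[t].kind for t in kb.instances[x].types}

    square = {
        "inheres_in": ("SQ1", DEPENDENT_KINDS, {OntKind.MATERIAL_ENTITY}),
        "has_realization": ("SQ2", {OntKind.DISPOSITION}, {OntKind.PROCESS}),
        "has_participant": ("SQ3", {OntKind.PROCESS}, {OntKind.MATERIAL_ENTITY}),
        "has_trigger_R": ("SQ4", {OntKind.PROCESS}, {OntKind.PROCESS}),
    }
    for f in kb.facts:
        if f.relation in square:
            code, sk, ok_ = square[f.relation]
            if not (kinds(f.subject) & sk) or not (kinds(f.object) & ok_):
                out.append((code, (f.subject, f.object)))
        if f.relation in ("has_disposition", "has_trigger_D") and f.provenance == "asserted":
            out.append(("ASSERTED_DERIVED", (f.relation, f.subject, f.object)))
    for ax in kb.axioms:
        if ax.base_type is not None:
            if (kb.types[ax.base_type].kind is not OntKind.QUALITY
                    or kb.types[ax.disposition_type].kind is not OntKind.DISPOSITION):
                out.append(("SQ5", (ax.base_type, ax.disposition_type)))
    for x in sorted(kb.instances):
        if kinds(x) & DEPENDENT_KINDS:
            bearers = sorted(f.object for f in kb.facts
                             if f.relation == "inheres_in" and f.subject == x)
            if not bearers:
                out.append(("BEAR1", (x,)))
            elif len(bearers) > 1:
                out.append(("BEAR2", (x, *bearers)))
    for x in sorted(kb.instances):
        if kb.instances[x].provenance == "asserted" and x.startswith("__sk."):
            out.append(("SKOLEM_NAME", (x,)))

    def cx(code, witnesses, ax):
        if witnesses:
            out.append((code, tuple(sorted(set(witnesses)))))

    for ax in kb.axioms:
        D = ax.disposition_type
        R = multitrack.realization_scope(kb, ax)
        T = multitrack.trigger_scope(kb, ax)
        if ax.essential_of:
            bad = [x for x in kb.instances_of(ax.essential_of)
                   if not eval(kb, Exists("?d", conj(
                       IsInstance("?d", D), Atom("inheres_in", "?d", x))))]
            cx("AS_ESSENTIAL", bad, ax)
        if ax.bearer_type:
            bad = [d for d in kb.instances_of(D)
                   if not eval(kb, Exists("?b", conj(
                       IsInstance("?b", ax.bearer_type),
                       Atom("inheres_in", d, "?b"))))]
            cx("AS_BEARER", bad, ax)
        bad = [f.object for d in kb.instances_of(D)
               for f in kb.facts_with("has_realization", subject=d)
               if not eval(kb, IsInstance(f.object, R))]
        cx("VR_REAL", bad, ax)
        if T is not None:
            bad = []
            for d in kb.instances_of(D):
                for r_fact in kb.facts_with("has_realization", subject=d):
                    for g in kb.facts_with("has_trigger_R", subject=r_fact.object):
                        if not eval(kb, IsInstance(g.object, T)):
                            bad.append(g.object)
            cx("VR_TRIG", bad, ax)
            for r_type in dict.fromkeys(ax.realization_types):
                bad = [r for r in kb.instances_of(r_type)
                       if not eval(kb, Exists("?t", conj(
                           IsInstance("?t", T),
                           Atom("has_trigger_R", r, "?t"))))]
                cx("AS_TRIG", bad, ax)
    return sorted(out)
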