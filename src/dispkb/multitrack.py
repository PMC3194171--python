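"""Union-class compilation for multi-track / multi-trigger dispositions.

A multi-track disposition admits several realization types (a fragile
glass may break, crack or splinter); a multi-trigger disposition admits
several trigger types (striking, throwing onto a hard surface).  Both are
reduced to the single-track machinery by forming the union class of the
alternative process types: membership in a union is derived member-wise
and never asserted, and unions never enter the asserted ``is_a`` taxonomy.

Union names are generated deterministically from the sorted member list,
so recompiling the same axiom always yields the same union.
"""

from __future__ import annotations

from dataclasses import replace

from .core_model import (
    DispositionAxiom,
    KBError,
    KnowledgeBase,
    OntKind,
    UNION_PREFIX,
)


def union_name(members: tuple[str, ...]) -> str:
    return UNION_PREFIX + "+".join(sorted(set(members)))


def make_union(kb: KnowledgeBase, members) -> str:
    """Register (or fetch) the union class of ≥2 declared process types.

    Returns the generated union name.  ``kb.instances_of(name)`` computes
    the member-wise union of extensions; members need not be disjoint, and
    an instance of several members is counted once.
    """
    members = tuple(members)
    if len(set(members)) < 2:
        raise KBError("a union type needs at least two distinct members")
    for m in members:
        if kb.kind_of_type(m) is not OntKind.PROCESS:
            raise KBError(f"union member {m!r} is not a process type")
    name = union_name(members)
    if name not in kb.unions:
        kb.register_union(name, tuple(sorted(set(members))))
    return name


def compile_axiom(kb: KnowledgeBase, axiom: DispositionAxiom) -> DispositionAxiom:
    """Reduce a multi-track / multi-trigger axiom to singleton unions.

    Single-track axioms are returned unchanged (the identity case), so
    running every axiom through this compiler is always safe.
    """
    realizations = axiom.realization_types
    triggers = axiom.trigger_types
    if len(set(realizations)) >= 2:
        realizations = (make_union(kb, realizations),)
    if len(set(triggers)) >= 2:
        triggers = (make_union(kb, triggers),)
    if realizations == axiom.realization_types and triggers == axiom.trigger_types:
        return axiom
    return replace(axiom, realization_types=realizations, trigger_types=triggers)


def realization_scope(kb: KnowledgeBase, axiom: DispositionAxiom) -> str:
    """The type (possibly a union) every realization of the axiom must fall
    under: the single realization type, or the union of all tracks."""
    if len(set(axiom.realization_types)) == 1:
        return axiom.realization_types[0]
    return make_union(kb, axiom.realization_types)


def trigger_scope(kb: KnowledgeBase, axiom: DispositionAxiom) -> str | None:
    """The type (possibly a union) every trigger of the axiom must fall
    under, or ``None`` for trigger-free axioms."""
    if not axiom.trigger_types:
        return None
    if len(set(axiom.trigger_types)) == 1:
        return axiom.trigger_types[0]
    return make_union(kb, axiom.trigger_types)
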