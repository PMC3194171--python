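"""Typed storage for a disposition knowledge base.

The model follows the BFO-style "category square" relating a material
bearer, a base quality, a disposition and a realization process.  A
:class:`KnowledgeBase` holds four stores:

* a taxonomy of :class:`TypeDecl` records, each assigned to exactly one of
  the four top-level :class:`OntKind` categories, with an acyclic ``is_a``
  graph whose reflexive–transitive closure is materialized eagerly;
* :class:`InstanceDecl` particulars, whose ``instance_of`` sets are closed
  upward under ``is_a``;
* ground binary :class:`Fact` atoms over a fixed relation vocabulary;
* type-level :class:`DispositionAxiom` records binding a disposition type
  to its bearer, base, trigger(s) and realization(s).

Two relations, ``has_disposition`` and ``has_trigger_D``, are definitional
(they are derivable from inherence and trigger/realization facts) and may
never be asserted; the store enforces this at insertion time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional


class OntKind(enum.Enum):
    """The four fixed top-level categories of the model."""

    MATERIAL_ENTITY = "material_entity"
    QUALITY = "quality"
    DISPOSITION = "disposition"
    PROCESS = "process"


#: Kinds whose instances are dependent continuants and therefore need a bearer.
DEPENDENT_KINDS = frozenset({OntKind.QUALITY, OntKind.DISPOSITION})

#: The fixed particular-level relation vocabulary.
RELATIONS = (
    "inheres_in",
    "has_participant",
    "has_realization",
    "has_trigger_R",
    "has_disposition",
    "has_trigger_D",
)

#: Relations that are definitional and may only carry provenance "derived".
DERIVED_ONLY_RELATIONS = frozenset({"has_disposition", "has_trigger_D"})

#: Reserved prefix for reasoner-created (skolem) instances.
SKOLEM_PREFIX = "__sk."

#: Reserved prefix for generated union types.
UNION_PREFIX = "__u."


class KBError(Exception):
    """Base class for knowledge-base structural errors."""


class UnknownIdentifier(KBError):
    pass


class DuplicateIdentifier(KBError):
    pass


class CycleError(KBError):
    pass


class KindClashError(KBError):
    pass


class DerivedRelationAsserted(KBError):
    pass


@dataclass(frozen=True)
class TypeDecl:
    """A named class with an ontological kind and ``is_a`` parents."""

    name: str
    kind: OntKind
    parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        _check_identifier(self.name)
        object.__setattr__(self, "parents", frozenset(self.parents))


@dataclass(frozen=True)
class InstanceDecl:
    """A named particular with its (closed) ``instance_of`` type set."""

    name: str
    types: frozenset[str]
    provenance: str = "asserted"  # or "skolem"

    def __post_init__(self) -> None:
        _check_identifier(self.name)
        object.__setattr__(self, "types", frozenset(self.types))
        if self.provenance not in ("asserted", "skolem"):
            raise KBError(f"bad instance provenance {self.provenance!r}")


@dataclass(frozen=True)
class Fact:
    """A ground binary atom ``relation(subject, object)``."""

    relation: str
    subject: str
    object: str
    provenance: str = "asserted"  # or "derived"

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise KBError(f"unknown relation {self.relation!r}")
        if self.provenance not in ("asserted", "derived"):
            raise KBError(f"bad fact provenance {self.provenance!r}")

    @property
    def atom(self) -> tuple[str, str, str]:
        return (self.relation, self.subject, self.object)


@dataclass(frozen=True)
class DispositionAxiom:
    """A type-level disposition axiom.

    Binds a disposition type to its bearer type, base quality type, trigger
    process type(s) and realization process type(s).  ``surefire`` marks
    dispositions that are necessarily realized whenever a trigger occurs.
    ``essential_of`` names a material-entity type all of whose instances
    bear the disposition essentially (the all-some reading).
    """

    disposition_type: str
    realization_types: tuple[str, ...]
    trigger_types: tuple[str, ...] = ()
    bearer_type: Optional[str] = None
    base_type: Optional[str] = None
    surefire: bool = False
    essential_of: Optional[str] = None
    comment: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "realization_types", tuple(self.realization_types))
        object.__setattr__(self, "trigger_types", tuple(self.trigger_types))
        if len(self.realization_types) < 1:
            raise KBError("an axiom needs at least one realization type")

    @property
    def single_track(self) -> bool:
        return len(self.trigger_types) <= 1 and len(self.realization_types) == 1

    def key(self) -> tuple:
        return (
            self.disposition_type,
            self.realization_types,
            self.trigger_types,
            self.bearer_type or "",
            self.base_type or "",
            self.surefire,
            self.essential_of or "",
        )


def _check_identifier(name: str) -> None:
    if not name or any(c.isspace() for c in name):
        raise KBError(f"identifier {name!r} is empty or contains whitespace")


class KnowledgeBase:
    """Mutable store of types, instances, facts and axioms.

    Subsumption (``is_a``) and instantiation (``instance_of``) closures are
    materialized eagerly on every insertion, so queries never recompute
    them.  Union types (see :mod:`dispkb.multitrack`) live in a separate
    registry; their membership is derived, never asserted.
    """

    def __init__(self) -> None:
        self.types: dict[str, TypeDecl] = {}
        self.instances: dict[str, InstanceDecl] = {}
        self.axioms: list[DispositionAxiom] = []
        # atom -> provenance ("asserted" wins over "derived")
        self._facts: dict[tuple[str, str, str], str] = {}
        # type name -> reflexive-transitive is_a ancestor set
        self._ancestors: dict[str, frozenset[str]] = {}
        # union type name -> ordered member tuple
        self.unions: dict[str, tuple[str, ...]] = {}

    # ------------------------------------------------------------------ types

    def add_type(self, decl: TypeDecl) -> "KnowledgeBase":
        if decl.name in self.types or decl.name in self.unions:
            raise DuplicateIdentifier(f"type {decl.name!r} already declared")
        ancestors = {decl.name}
        for p in sorted(decl.parents):
            if p == decl.name:
                raise CycleError(f"type {decl.name!r} cannot be its own parent")
            if p not in self.types:
                raise UnknownIdentifier(f"parent type {p!r} of {decl.name!r} not declared")
            if self.types[p].kind is not decl.kind:
                raise KindClashError(
                    f"type {decl.name!r} ({decl.kind.value}) cannot be a child of "
                    f"{p!r} ({self.types[p].kind.value})"
                )
            ancestors |= self._ancestors[p]
        # A fresh name can never close a cycle; the parents-exist check above
        # already guarantees acyclicity, self-parentage aside.
        self.types[decl.name] = decl
        self._ancestors[decl.name] = frozenset(ancestors)
        return self

    def add_is_a(self, child: str, parent: str) -> "KnowledgeBase":
        """Add an ``is_a`` edge between two declared types.

        Rejects cycles (``parent`` already below ``child``) and cross-kind
        parentage; recomputes the affected ancestor closures.
        """
        for t in (child, parent):
            if t not in self.types:
                raise UnknownIdentifier(f"type {t!r} not declared")
        if child in self._ancestors[parent] or child == parent:
            raise CycleError(f"{child!r} is_a {parent!r} would close a cycle")
        if self.types[child].kind is not self.types[parent].kind:
            raise KindClashError(f"{child!r} and {parent!r} have different kinds")
        decl = self.types[child]
        self.types[child] = replace(decl, parents=decl.parents | {parent})
        # recompute closures for the child and everything below it
        order = sorted(self.types)
        changed = True
        while changed:
            changed = False
            for name in order:
                d = self.types[name]
                anc = {name}
                for p in d.parents:
                    anc |= self._ancestors[p]
                if frozenset(anc) != self._ancestors[name]:
                    self._ancestors[name] = frozenset(anc)
                    changed = True
        for name, inst in list(self.instances.items()):
            closed: set[str] = set()
            for t in inst.types:
                closed |= self._ancestors[t]
            self.instances[name] = replace(inst, types=frozenset(closed))
        return self

    def ancestors(self, t: str) -> frozenset[str]:
        """Reflexive-transitive ``is_a`` closure of a declared type."""
        if t not in self._ancestors:
            raise UnknownIdentifier(f"type {t!r} not declared")
        return self._ancestors[t]

    def is_subtype(self, a: str, b: str) -> bool:
        """True iff *b* is in the reflexive-transitive ``is_a`` closure of *a*."""
        if b in self.unions:
            return any(self.is_subtype(a, m) for m in self.unions[b])
        if b not in self.types:
            raise UnknownIdentifier(f"type {b!r} not declared")
        return b in self.ancestors(a)

    def kind_of_type(self, t: str) -> OntKind:
        if t in self.unions:
            return OntKind.PROCESS  # unions are only formed over process types
        if t not in self.types:
            raise UnknownIdentifier(f"type {t!r} not declared")
        return self.types[t].kind

    # -------------------------------------------------------------- instances

    def add_instance(self, decl: InstanceDecl) -> "KnowledgeBase":
        if decl.name in self.instances:
            raise DuplicateIdentifier(f"instance {decl.name!r} already declared")
        if decl.provenance == "asserted" and decl.name.startswith(SKOLEM_PREFIX):
            raise KBError(f"asserted instance {decl.name!r} uses the reserved skolem prefix")
        closed: set[str] = set()
        for t in decl.types:
            closed |= self.ancestors(t)  # raises on unknown types
        self.instances[decl.name] = replace(decl, types=frozenset(closed))
        return self

    def add_instance_type(self, name: str, t: str) -> None:
        """Extend an existing instance's type set (closure maintained)."""
        inst = self.instances.get(name)
        if inst is None:
            raise UnknownIdentifier(f"instance {name!r} not declared")
        self.instances[name] = replace(inst, types=inst.types | self.ancestors(t))

    def instances_of(self, t: str) -> set[str]:
        """All instances whose closed ``instance_of`` set contains *t*.

        Union types resolve to the member-wise union of their members'
        extensions.
        """
        if t in self.unions:
            out: set[str] = set()
            for m in self.unions[t]:
                out |= self.instances_of(m)
            return out
        if t not in self.types:
            raise UnknownIdentifier(f"type {t!r} not declared")
        return {x.name for x in self.instances.values() if t in x.types}

    def instance_is_of(self, x: str, t: str) -> bool:
        inst = self.instances.get(x)
        if inst is None:
            raise UnknownIdentifier(f"instance {x!r} not declared")
        if t in self.unions:
            return any(m in inst.types for m in self.unions[t])
        return t in inst.types

    def kind_of_instance(self, x: str) -> OntKind:
        """The unique :class:`OntKind` of *x*'s types (error on clash)."""
        inst = self.instances.get(x)
        if inst is None:
            raise UnknownIdentifier(f"instance {x!r} not declared")
        kinds = {self.types[t].kind for t in inst.types}
        if not kinds:
            raise KBError(f"instance {x!r} has no types")
        if len(kinds) > 1:
            raise KindClashError(
                f"instance {x!r} is typed under {len(kinds)} disjoint kinds: "
                + ", ".join(sorted(k.value for k in kinds))
            )
        return next(iter(kinds))

    # ------------------------------------------------------------------ facts

    def add_fact(self, fact: Fact) -> "KnowledgeBase":
        if fact.relation in DERIVED_ONLY_RELATIONS and fact.provenance == "asserted":
            raise DerivedRelationAsserted(
                f"{fact.relation} is definitional and may not be asserted"
            )
        return self._add_fact_unchecked(fact)

    def _add_fact_unchecked(self, fact: Fact) -> "KnowledgeBase":
        # bypasses the derived-only guard; used by fault injection only
        for x in (fact.subject, fact.object):
            if x not in self.instances:
                raise UnknownIdentifier(f"fact refers to unknown instance {x!r}")
        prev = self._facts.get(fact.atom)
        if prev != "asserted":
            self._facts[fact.atom] = fact.provenance
        return self

    def has_fact(self, relation: str, subject: str, object: str) -> bool:
        return (relation, subject, object) in self._facts

    @property
    def facts(self) -> list[Fact]:
        return [
            Fact(r, s, o, provenance=p)
            for (r, s, o), p in sorted(self._facts.items())
        ]

    def facts_with(self, relation: str, subject: Optional[str] = None,
                   object: Optional[str] = None) -> list[Fact]:
        return [
            f for f in self.facts
            if f.relation == relation
            and (subject is None or f.subject == subject)
            and (object is None or f.object == object)
        ]

    def atom_set(self) -> frozenset[tuple[str, str, str]]:
        """The ground atom set, ignoring provenance — the oracle comparator."""
        return frozenset(self._facts)

    # ----------------------------------------------------------------- axioms

    def add_axiom(self, axiom: DispositionAxiom) -> "KnowledgeBase":
        if self.kind_of_type(axiom.disposition_type) is not OntKind.DISPOSITION:
            raise KindClashError(f"{axiom.disposition_type!r} is not a disposition type")
        for r in axiom.realization_types:
            if self.kind_of_type(r) is not OntKind.PROCESS:
                raise KindClashError(f"realization type {r!r} is not a process type")
        for t in axiom.trigger_types:
            if self.kind_of_type(t) is not OntKind.PROCESS:
                raise KindClashError(f"trigger type {t!r} is not a process type")
        if axiom.base_type is not None and self.kind_of_type(axiom.base_type) is not OntKind.QUALITY:
            raise KindClashError(f"base type {axiom.base_type!r} is not a quality type")
        for b in (axiom.bearer_type, axiom.essential_of):
            if b is not None and self.kind_of_type(b) is not OntKind.MATERIAL_ENTITY:
                raise KindClashError(f"{b!r} is not a material-entity type")
        self.axioms.append(axiom)
        return self

    # ------------------------------------------------------------------ misc

    def bearers_of(self, x: str) -> list[str]:
        """Bearers of a dependent-continuant instance (via ``inheres_in``)."""
        return sorted(f.object for f in self.facts_with("inheres_in", subject=x))

    def register_union(self, name: str, members: tuple[str, ...]) -> None:
        if name in self.types:
            raise DuplicateIdentifier(f"{name!r} already names a declared type")
        self.unions[name] = tuple(members)

    def copy(self) -> "KnowledgeBase":
        kb = KnowledgeBase()
        kb.types = dict(self.types)
        kb.instances = dict(self.instances)
        kb.axioms = list(self.axioms)
        kb._facts = dict(self._facts)
        kb._ancestors = dict(self._ancestors)
        kb.unions = dict(self.unions)
        return kb

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        # the union registry is a derived cache, not asserted content
        return (
            self.types == other.types
            and self.instances == other.instances
            and self._facts == other._facts
            and sorted(a.key() for a in self.axioms) == sorted(a.key() for a in other.axioms)
        )


def add_type(kb: KnowledgeBase, decl: TypeDecl) -> KnowledgeBase:
    return kb.add_type(decl)


def is_subtype(kb: KnowledgeBase, a: str, b: str) -> bool:
    return kb.is_subtype(a, b)


def instances_of(kb: KnowledgeBase, t: str) -> set[str]:
    return kb.instances_of(t)


def kind_of_instance(kb: KnowledgeBase, x: str) -> OntKind:
    return kb.kind_of_instance(x)
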