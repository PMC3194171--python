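"""Type-level disposition relations: all-some checks and value restrictions.

Two semantic schemes coexist, and which one a relation gets is forced by
the science.  *All-some* relations ("every instance of A bears some
instance of D") fit essential dispositions, inherence and the
trigger-of-realization link, because the witness must actually exist.
*Value restrictions* ("whenever an instance of D is realized, the
realization is of type R") fit the realization and disposition-trigger
links, because a disposition may never be realized at all — an unrealized
disposition is a feature of the model, not a data error, so those checks
are vacuously true on unrealized data.

All checks read the knowledge base closed-world: a missing witness is a
counterexample, not an unknown.  Every ``False`` verdict carries concrete
counterexample instances that can be re-checked as ground facts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core_model import KBError, KnowledgeBase, OntKind
from .instance_reasoner import derive_trigger_D

ALL_SOME = "ALL_SOME"
VALUE_RESTRICTION = "VALUE_RESTRICTION"

#: Fixed semantics per type-level relation.
RELATION_SEMANTICS = {
    "type_has_disposition": ALL_SOME,
    "type_inheres_in": ALL_SOME,
    "type_has_trigger_R": ALL_SOME,
    "type_has_realization": VALUE_RESTRICTION,
    "type_has_trigger_D": VALUE_RESTRICTION,
}


@dataclass(frozen=True)
class TypeRelationClaim:
    relation: str
    subject: str
    object: str

    @property
    def semantics(self) -> str:
        return RELATION_SEMANTICS[self.relation]

    def format(self) -> str:
        return f"{self.relation}({self.subject}, {self.object})"


@dataclass(frozen=True)
class CheckResult:
    holds: bool
    counterexamples: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.holds


def _require_kind(kb: KnowledgeBase, t: str, kind: OntKind, role: str) -> None:
    if t in kb.unions:
        if kind is OntKind.PROCESS:
            return
        raise KBError(f"{role} {t!r} is a process union, expected {kind.value}")
    if kb.kind_of_type(t) is not kind:
        raise KBError(f"{role} {t!r} has kind {kb.kind_of_type(t).value}, expected {kind.value}")


def holds_type_has_disposition(kb: KnowledgeBase, A: str, D: str) -> CheckResult:
    """Essential-disposition check: every instance of *A* bears some
    instance of *D* (all-some; vacuously true for uninstantiated *A*)."""
    _require_kind(kb, A, OntKind.MATERIAL_ENTITY, "subject")
    _require_kind(kb, D, OntKind.DISPOSITION, "object")
    bad = []
    for x in sorted(kb.instances_of(A)):
        borne = any(
            D in kb.instances[f.subject].types
            for f in kb.facts_with("inheres_in", object=x)
        )
        if not borne:
            bad.append(x)
    return CheckResult(not bad, tuple(sorted(set(bad))))


def holds_type_inheres_in(kb: KnowledgeBase, D: str, B: str) -> CheckResult:
    """Every instance of disposition type *D* inheres in some instance of
    material-entity type *B*."""
    _require_kind(kb, D, OntKind.DISPOSITION, "subject")
    _require_kind(kb, B, OntKind.MATERIAL_ENTITY, "object")
    bad = []
    for d in sorted(kb.instances_of(D)):
        ok = any(B in kb.instances[b].types for b in kb.bearers_of(d))
        if not ok:
            bad.append(d)
    return CheckResult(not bad, tuple(sorted(set(bad))))


def holds_value_restriction_realization(kb: KnowledgeBase, D: str, R: str) -> CheckResult:
    """Whenever an instance of *D* is realized, the realization falls
    under *R* (which may be a union of tracks).  True when no realization
    facts exist — unrealized dispositions are admissible."""
    _require_kind(kb, D, OntKind.DISPOSITION, "subject")
    _require_kind(kb, R, OntKind.PROCESS, "object")
    bad = []
    for d in sorted(kb.instances_of(D)):
        for f in kb.facts_with("has_realization", subject=d):
            if not kb.instance_is_of(f.object, R):
                bad.append(f.object)
    return CheckResult(not bad, tuple(sorted(set(bad))))


def holds_value_restriction_trigger_D(kb: KnowledgeBase, D: str, T: str) -> CheckResult:
    """Whenever an instance of *D* has a (derived) trigger, the trigger
    falls under *T*.  Runs the trigger derivation itself, so it is valid
    on both raw and saturated stores."""
    _require_kind(kb, D, OntKind.DISPOSITION, "subject")
    _require_kind(kb, T, OntKind.PROCESS, "object")
    trig = derive_trigger_D(kb)
    bad = []
    for d in sorted(kb.instances_of(D)):
        for f in sorted(trig, key=lambda f: f.atom):
            if f.subject == d and not kb.instance_is_of(f.object, T):
                bad.append(f.object)
    return CheckResult(not bad, tuple(sorted(set(bad))))


def holds_allsome_trigger_R(kb: KnowledgeBase, R: str, T: str) -> CheckResult:
    """Every realization instance of type *R* was triggered by some
    instance of *T* (all-some: an untriggered realization on record is a
    modelling fault for single-trigger dispositions)."""
    _require_kind(kb, R, OntKind.PROCESS, "subject")
    _require_kind(kb, T, OntKind.PROCESS, "object")
    bad = []
    for r in sorted(kb.instances_of(R)):
        ok = any(
            kb.instance_is_of(f.object, T)
            for f in kb.facts_with("has_trigger_R", subject=r)
        )
        if not ok:
            bad.append(r)
    return CheckResult(not bad, tuple(sorted(set(bad))))


_CHECKS = {
    "type_has_disposition": holds_type_has_disposition,
    "type_inheres_in": holds_type_inheres_in,
    "type_has_realization": holds_value_restriction_realization,
    "type_has_trigger_D": holds_value_restriction_trigger_D,
    "type_has_trigger_R": holds_allsome_trigger_R,
}

_SUBJECT_KIND = {
    "type_has_disposition": OntKind.MATERIAL_ENTITY,
    "type_inheres_in": OntKind.DISPOSITION,
    "type_has_realization": OntKind.DISPOSITION,
    "type_has_trigger_D": OntKind.DISPOSITION,
    "type_has_trigger_R": OntKind.PROCESS,
}

_OBJECT_KIND = {
    "type_has_disposition": OntKind.DISPOSITION,
    "type_inheres_in": OntKind.MATERIAL_ENTITY,
    "type_has_realization": OntKind.PROCESS,
    "type_has_trigger_D": OntKind.PROCESS,
    "type_has_trigger_R": OntKind.PROCESS,
}


def check_claim(kb: KnowledgeBase, claim: TypeRelationClaim) -> CheckResult:
    return _CHECKS[claim.relation](kb, claim.subject, claim.object)


def _nonvacuous(kb: KnowledgeBase, claim: TypeRelationClaim) -> bool:
    """A claim counts only if some instance actually witnesses the pattern
    (an empty subject extension, or zero relevant facts, is vacuous)."""
    rel, S = claim.relation, claim.subject
    if not kb.instances_of(S):
        return False
    if rel == "type_has_realization":
        return any(kb.facts_with("has_realization", subject=d) for d in kb.instances_of(S))
    if rel == "type_has_trigger_D":
        trig = derive_trigger_D(kb)
        return any(f.subject in kb.instances_of(S) for f in trig)
    return True


def induce_type_claims(kb: KnowledgeBase) -> set[TypeRelationClaim]:
    """Report the type-level claims the instance data supports.

    Brute-forces every declared type pair through the checks, keeps only
    non-vacuously true claims, and filters object types to the most
    specific ones (supertype claims follow by monotonicity and would
    otherwise flood the report; incomparable most-specific types are all
    kept).
    """
    by_kind: dict[OntKind, list[str]] = {k: [] for k in OntKind}
    for t in kb.types.values():
        by_kind[t.kind].append(t.name)
    out: set[TypeRelationClaim] = set()
    for rel, check in _CHECKS.items():
        for s in sorted(by_kind[_SUBJECT_KIND[rel]]):
            true_objects = []
            for o in sorted(by_kind[_OBJECT_KIND[rel]]):
                claim = TypeRelationClaim(rel, s, o)
                if _nonvacuous(kb, claim) and check(kb, s, o):
                    true_objects.append(o)
            # keep only the most specific object types
            for o in true_objects:
                if any(o != o2 and kb.is_subtype(o2, o) for o2 in true_objects):
                    continue
                out.add(TypeRelationClaim(rel, s, o))
    return out
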