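"""Closed-world structural validation of a disposition knowledge base.

Checks fall into three groups:

* the **category square** — each particular-level relation must connect
  the right top-level kinds (a disposition inheres in a material entity,
  a realization is a process with material participants, triggers are
  processes acting on processes, a base is a quality of a disposition);
* **bearer existence** — dependent continuants (qualities, dispositions)
  cannot exist unborne, and carry exactly one bearer;
* **axiom conformance** — every declared disposition axiom is checked
  against the instance data with the appropriate all-some or
  value-restriction semantics, plus the load-time rules (definitional
  relations must not be asserted; reserved skolem names must not appear
  asserted).

Violations are warnings, not failures: a faulty store stays inspectable.
Reports are deterministically ordered (code, then entity ids) so output
is diff-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core_model import (
    DEPENDENT_KINDS,
    DERIVED_ONLY_RELATIONS,
    DispositionAxiom,
    KnowledgeBase,
    OntKind,
    SKOLEM_PREFIX,
)
from . import multitrack, type_semantics


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    entities: tuple[str, ...]
    axiom: Optional[DispositionAxiom] = None

    def sort_key(self) -> tuple:
        return (self.code, self.entities)

    def format(self) -> str:
        return f"{self.code}\t" + "\t".join(self.entities)


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def codes(self) -> list[str]:
        return [v.code for v in self.violations]

    def format(self) -> str:
        if self.ok:
            return "OK: 0 violations"
        return "\n".join(v.format() for v in self.violations)


def _kind(kb: KnowledgeBase, x: str) -> Optional[OntKind]:
    try:
        return kb.kind_of_instance(x)
    except Exception:
        return None


_SQUARE = {
    # relation -> (code, allowed subject kinds, allowed object kinds)
    "inheres_in": ("SQ1", DEPENDENT_KINDS, {OntKind.MATERIAL_ENTITY}),
    "has_realization": ("SQ2", {OntKind.DISPOSITION}, {OntKind.PROCESS}),
    "has_participant": ("SQ3", {OntKind.PROCESS}, {OntKind.MATERIAL_ENTITY}),
    "has_trigger_R": ("SQ4", {OntKind.PROCESS}, {OntKind.PROCESS}),
}


def check_category_square(kb: KnowledgeBase) -> list[Violation]:
    """Domain/range discipline of the fundamental relations (SQ1–SQ5)."""
    out: list[Violation] = []
    for f in kb.facts:
        spec = _SQUARE.get(f.relation)
        if spec is None:
            continue
        code, subj_kinds, obj_kinds = spec
        ks, ko = _kind(kb, f.subject), _kind(kb, f.object)
        if ks not in subj_kinds or ko not in obj_kinds:
            out.append(Violation(
                code,
                f"{f.relation}({f.subject}, {f.object}) violates the "
                f"category square",
                (f.subject, f.object),
            ))
    for ax in kb.axioms:
        if ax.base_type is not None:
            ok = (kb.kind_of_type(ax.base_type) is OntKind.QUALITY
                  and kb.kind_of_type(ax.disposition_type) is OntKind.DISPOSITION)
            if not ok:
                out.append(Violation(
                    "SQ5",
                    f"base_of axiom {ax.base_type} -> {ax.disposition_type} "
                    f"is not quality -> disposition",
                    (ax.base_type, ax.disposition_type),
                    axiom=ax,
                ))
    return sorted(out, key=Violation.sort_key)


def check_bearers(kb: KnowledgeBase) -> list[Violation]:
    """Dependent continuants need exactly one bearer: BEAR1 flags unborne
    quality/disposition instances, BEAR2 flags multiple inherence."""
    out: list[Violation] = []
    for x in sorted(kb.instances):
        if _kind(kb, x) not in DEPENDENT_KINDS:
            continue
        bearers = kb.bearers_of(x)
        if len(bearers) == 0:
            out.append(Violation(
                "BEAR1", f"dependent continuant {x} has no bearer", (x,)))
        elif len(bearers) > 1:
            out.append(Violation(
                "BEAR2",
                f"dependent continuant {x} has {len(bearers)} bearers",
                (x, *bearers)))
    return sorted(out, key=Violation.sort_key)


def check_asserted_derived(kb: KnowledgeBase) -> list[Violation]:
    """Definitional relations carry provenance "derived" by construction;
    an asserted one can only enter through fault injection or a broken
    loader, and is reported as ASSERTED_DERIVED."""
    out = []
    for f in kb.facts:
        if f.relation in DERIVED_ONLY_RELATIONS and f.provenance == "asserted":
            out.append(Violation(
                "ASSERTED_DERIVED",
                f"{f.relation} is definitional and may not be asserted",
                (f.relation, f.subject, f.object)))
    for x, inst in sorted(kb.instances.items()):
        if inst.provenance == "asserted" and x.startswith(SKOLEM_PREFIX):
            out.append(Violation(
                "SKOLEM_NAME",
                f"asserted instance {x} uses the reserved skolem prefix",
                (x,)))
    return sorted(out, key=Violation.sort_key)


def check_axioms(kb: KnowledgeBase) -> list[Violation]:
    """Axiom conformance with the correct semantics per relation:

    * AS_ESSENTIAL — every instance of the host kind bears the disposition
      (all-some, essential dispositions);
    * AS_BEARER — every disposition instance inheres in the declared
      bearer type (all-some inherence);
    * VR_REAL — realizations stay within the declared track(s) (value
      restriction; vacuous when unrealized);
    * VR_TRIG — derived triggers stay within the declared trigger type(s);
    * AS_TRIG — every realization instance of a declared track has a
      trigger of the declared type (all-some, single-/multi-trigger).
    """
    out: list[Violation] = []
    for ax in kb.axioms:
        D = ax.disposition_type
        r_scope = multitrack.realization_scope(kb, ax)
        t_scope = multitrack.trigger_scope(kb, ax)
        if ax.essential_of:
            res = type_semantics.holds_type_has_disposition(kb, ax.essential_of, D)
            if not res:
                out.append(Violation(
                    "AS_ESSENTIAL",
                    f"instances of {ax.essential_of} without a {D} disposition",
                    res.counterexamples, axiom=ax))
        if ax.bearer_type:
            res = type_semantics.holds_type_inheres_in(kb, D, ax.bearer_type)
            if not res:
                out.append(Violation(
                    "AS_BEARER",
                    f"instances of {D} without a bearer of type {ax.bearer_type}",
                    res.counterexamples, axiom=ax))
        res = type_semantics.holds_value_restriction_realization(kb, D, r_scope)
        if not res:
            out.append(Violation(
                "VR_REAL",
                f"realizations of {D} outside {r_scope}",
                res.counterexamples, axiom=ax))
        if t_scope is not None:
            res = type_semantics.holds_value_restriction_trigger_D(kb, D, t_scope)
            if not res:
                out.append(Violation(
                    "VR_TRIG",
                    f"triggers of {D} outside {t_scope}",
                    res.counterexamples, axiom=ax))
            for r_type in dict.fromkeys(ax.realization_types):
                res = type_semantics.holds_allsome_trigger_R(kb, r_type, t_scope)
                if not res:
                    out.append(Violation(
                        "AS_TRIG",
                        f"instances of {r_type} with no trigger of type {t_scope}",
                        res.counterexamples, axiom=ax))
    return sorted(out, key=Violation.sort_key)


def validate(kb: KnowledgeBase) -> ValidationReport:
    """Run every check; the report is deterministic and ordered by
    (code, entities)."""
    violations = (
        check_asserted_derived(kb)
        + check_category_square(kb)
        + check_bearers(kb)
        + check_axioms(kb)
    )
    return ValidationReport(sorted(violations, key=Violation.sort_key))
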