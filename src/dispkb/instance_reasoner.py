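"""Forward-chaining derivation of instance-level disposition facts.

Two kinds of rules run to a least fixpoint:

* **definitional** rules, which add derived facts over existing instances:
  ``has_disposition(x, d)`` whenever a disposition instance *d* inheres in
  *x* (rule ``DEF1``), and ``has_trigger_D(d, t)`` whenever some
  realization of *d* was triggered by *t* (rule ``DEF5``);

* **generative** rules, which skolemize the existential conclusions of the
  surefire principles: every base-quality instance brings a disposition
  instance with it (``BASE8``), every essential disposition type endows
  each instance of its host kind with a disposition instance (``ESS2``),
  a surefire disposition with a present trigger is realized (``REAL9``,
  or ``REAL13`` for multi-track axioms, where the skolem is instantiated
  at the first listed track), and the bearer participates in the
  realization (``BEARER10``).

Skolem names are a deterministic function of the rule id and the premise
identifiers, so saturation is replay-stable: the same input produces the
same instances, bit for bit, on every run.  Dispositions whose trigger
never occurs stay unrealized — the rules never invent triggers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional
import warnings

from .core_model import (
    DispositionAxiom,
    Fact,
    InstanceDecl,
    KnowledgeBase,
    OntKind,
    SKOLEM_PREFIX,
)
from . import multitrack


def default_skolem_name(rule: str, *premise_ids: str) -> str:
    """``__sk.<rule>.<premise ids>`` — replay-stable, collision-free."""
    return SKOLEM_PREFIX + rule + "." + ".".join(premise_ids)


@dataclass(frozen=True)
class SkolemPolicy:
    """Controls whether generative rules create witnesses.

    With ``enabled=False`` the generative rules run in report-only mode:
    they emit traces describing the witnesses they *would* create without
    touching the store (the definitional rules still derive facts).
    """

    enabled: bool = True
    naming: Callable[..., str] = default_skolem_name


@dataclass(frozen=True)
class DerivationTrace:
    """One derivation step: what was derived, by which rule, from what."""

    rule: str  # DEF1 | DEF5 | ESS2 | BASE8 | REAL9 | REAL13 | BEARER10
    derived: tuple  # a fact atom (rel, s, o) or ("instance", name)
    premises: tuple[str, ...]
    applied: bool = True

    def format(self) -> str:
        if self.derived[0] == "instance":
            head = f"instance {self.derived[1]}"
        else:
            r, s, o = self.derived
            head = f"{r}({s}, {o})"
        tail = f"{self.rule}({', '.join(self.premises)})"
        arrow = "<-" if self.applied else "<?"
        return f"{head} {arrow} {tail}"


# --------------------------------------------------------------------- rules


def derive_has_disposition(kb: KnowledgeBase) -> set[Fact]:
    """Facts forced by the definition of ``has_disposition``: the inverse
    of inherence, restricted to disposition instances."""
    out: set[Fact] = set()
    for f in kb.facts_with("inheres_in"):
        d = f.subject
        if any(kb.types[t].kind is OntKind.DISPOSITION for t in kb.instances[d].types):
            out.add(Fact("has_disposition", f.object, d, provenance="derived"))
    return out


def derive_trigger_D(kb: KnowledgeBase) -> set[Fact]:
    """Facts forced by the definition of ``has_trigger_D``: a disposition
    is triggered by whatever triggered any of its realizations.  A
    disposition realized several times (a repeatedly evoked reflex) gets
    one fact per distinct trigger."""
    out: set[Fact] = set()
    for f in kb.facts_with("has_realization"):
        for g in kb.facts_with("has_trigger_R", subject=f.object):
            out.add(Fact("has_trigger_D", f.subject, g.object, provenance="derived"))
    return out


def _surefire_axioms(kb: KnowledgeBase) -> list[DispositionAxiom]:
    return sorted(
        (a for a in kb.axioms if a.surefire),
        key=lambda a: a.key(),
    )


def _asserted_disposition_witness(kb: KnowledgeBase, disp_type: str, bearer: str) -> bool:
    for f in kb.facts_with("inheres_in", object=bearer):
        d = kb.instances.get(f.subject)
        if d is not None and d.provenance == "asserted" and disp_type in d.types:
            return True
    return False


def _new_skolem(kb: KnowledgeBase, name: str, type_: str, rule: str,
                premises: tuple[str, ...], traces: list[DerivationTrace],
                apply: bool) -> bool:
    if name in kb.instances:
        return False
    traces.append(DerivationTrace(rule, ("instance", name), premises, applied=apply))
    if apply:
        kb.add_instance(InstanceDecl(name, frozenset({type_}), provenance="skolem"))
    return True


def _add_derived(kb: KnowledgeBase, atom: tuple[str, str, str], rule: str,
                 premises: tuple[str, ...], traces: list[DerivationTrace],
                 apply: bool) -> bool:
    if kb.has_fact(*atom):
        return False
    traces.append(DerivationTrace(rule, atom, premises, applied=apply))
    if apply:
        kb.add_fact(Fact(*atom, provenance="derived"))
    return True


def _run_definitional(kb: KnowledgeBase, traces: list[DerivationTrace]) -> bool:
    changed = False
    for f in sorted(derive_has_disposition(kb), key=lambda f: f.atom):
        changed |= _add_derived(kb, f.atom, "DEF1", (f.object, f.subject), traces, True)
    for f in sorted(derive_trigger_D(kb), key=lambda f: f.atom):
        changed |= _add_derived(kb, f.atom, "DEF5", (f.subject, f.object), traces, True)
    return changed


def apply_base_principle(kb: KnowledgeBase, policy: SkolemPolicy = SkolemPolicy()
                         ) -> tuple[KnowledgeBase, list[DerivationTrace]]:
    kb = kb.copy()
    traces: list[DerivationTrace] = []
    _base_pass(kb, policy, traces)
    return kb, traces


def _base_pass(kb: KnowledgeBase, policy: SkolemPolicy,
               traces: list[DerivationTrace]) -> bool:
    """Every instance of a base quality brings a disposition instance of
    the based type with it, inhering in the quality's bearer."""
    changed = False
    for ax in sorted((a for a in kb.axioms if a.base_type), key=lambda a: a.key()):
        for q in sorted(kb.instances_of(ax.base_type)):
            bearers = kb.bearers_of(q)
            if not bearers:
                continue  # unborne quality: the validator flags it
            for b in bearers:
                if _asserted_disposition_witness(kb, ax.disposition_type, b):
                    continue
                name = policy.naming("BASE8", ax.base_type, ax.disposition_type, b)
                made = _new_skolem(kb, name, ax.disposition_type, "BASE8",
                                   (q, b), traces, policy.enabled)
                if made and policy.enabled:
                    kb.add_fact(Fact("inheres_in", name, b, provenance="derived"))
                    changed = True
    return changed


def _essential_pass(kb: KnowledgeBase, policy: SkolemPolicy,
                    traces: list[DerivationTrace]) -> bool:
    """All-some reading of essential dispositions: every instance of the
    host kind receives a disposition instance (skolemized if absent)."""
    changed = False
    for ax in sorted((a for a in kb.axioms if a.essential_of), key=lambda a: a.key()):
        for x in sorted(kb.instances_of(ax.essential_of)):
            if _asserted_disposition_witness(kb, ax.disposition_type, x):
                continue
            name = policy.naming("ESS2", ax.essential_of, ax.disposition_type, x)
            made = _new_skolem(kb, name, ax.disposition_type, "ESS2",
                               (x,), traces, policy.enabled)
            if made and policy.enabled:
                kb.add_fact(Fact("inheres_in", name, x, provenance="derived"))
                changed = True
    return changed


def apply_realization_principle(kb: KnowledgeBase, policy: SkolemPolicy = SkolemPolicy()
                                ) -> tuple[KnowledgeBase, list[DerivationTrace]]:
    kb = kb.copy()
    traces: list[DerivationTrace] = []
    _realization_pass(kb, policy, traces)
    return kb, traces


def _realization_tracks(kb: KnowledgeBase, ax: DispositionAxiom) -> tuple[str, str, str]:
    """(rule id, scope type every realization falls under, type the skolem
    is instantiated at).  Multi-track skolems take the first listed track;
    union membership then follows derivationally."""
    scope = multitrack.realization_scope(kb, ax)
    first = ax.realization_types[0]
    if first in kb.unions:
        first = kb.unions[first][0]
    rule = "REAL13" if scope in kb.unions else "REAL9"
    return rule, scope, first


def _realization_pass(kb: KnowledgeBase, policy: SkolemPolicy,
                      traces: list[DerivationTrace]) -> bool:
    """Surefire realization principle: disposition present, trigger
    present, bearer present → the realization happens (skolem witness,
    unless a matching realization is already on record)."""
    changed = False
    for ax in _surefire_axioms(kb):
        if not ax.trigger_types:
            warnings.warn(
                f"surefire axiom for {ax.disposition_type!r} has no trigger "
                "types; trigger-free realization is not modelled, rule skipped",
                stacklevel=2,
            )
            continue
        rule, r_scope, r_first = _realization_tracks(kb, ax)
        t_scope = multitrack.trigger_scope(kb, ax)
        for d in sorted(kb.instances_of(ax.disposition_type)):
            if not kb.bearers_of(d):
                continue  # bearerless: deferred to the validator
            for t in sorted(kb.instances_of(t_scope)):
                if _realized_witness(kb, d, t, r_scope):
                    continue
                name = policy.naming(rule, d, t, r_first)
                made = _new_skolem(kb, name, r_first, rule, (d, t), traces,
                                   policy.enabled)
                if policy.enabled and name in kb.instances:
                    a1 = ("has_realization", d, name)
                    a2 = ("has_trigger_R", name, t)
                    changed |= _add_derived(kb, a1, rule, (d, t), traces, True)
                    changed |= _add_derived(kb, a2, rule, (d, t), traces, True)
                changed |= made and policy.enabled
    return changed


def _realized_witness(kb: KnowledgeBase, d: str, t: str, r_scope: str) -> bool:
    for f in kb.facts_with("has_realization", subject=d):
        if kb.has_fact("has_trigger_R", f.object, t) and kb.instance_is_of(f.object, r_scope):
            return True
    return False


def apply_bearer_principle(kb: KnowledgeBase, policy: SkolemPolicy = SkolemPolicy()
                           ) -> tuple[KnowledgeBase, list[DerivationTrace]]:
    kb = kb.copy()
    traces: list[DerivationTrace] = []
    _bearer_pass(kb, policy, traces)
    return kb, traces


def _bearer_pass(kb: KnowledgeBase, policy: SkolemPolicy,
                 traces: list[DerivationTrace]) -> bool:
    """Bearer principle: the bearer of a surefire disposition participates
    in every realization of that disposition — skolem or asserted.  The
    converse (process → unique disposition) is never inferred."""
    changed = False
    for ax in _surefire_axioms(kb):
        for d in sorted(kb.instances_of(ax.disposition_type)):
            for f in kb.facts_with("has_realization", subject=d):
                for b in kb.bearers_of(d):
                    atom = ("has_participant", f.object, b)
                    changed |= _add_derived(kb, atom, "BEARER10", (d, f.object, b),
                                            traces, policy.enabled)
    return changed


# ----------------------------------------------------------------- saturation


def saturate(kb: KnowledgeBase, policy: SkolemPolicy = SkolemPolicy()
             ) -> tuple[KnowledgeBase, list[DerivationTrace]]:
    """Run all rules to their least fixpoint.

    The rule chain is stratified (base/essential skolems can feed the
    realization principle, realization skolems feed the bearer principle
    and the definitional rules, and nothing feeds back), so the fixpoint
    exists and is reached after finitely many passes.  The result is
    independent of rule ordering; traces are reported in derivation order.
    """
    kb = kb.copy()
    traces: list[DerivationTrace] = []
    while True:
        changed = False
        changed |= _essential_pass(kb, policy, traces)
        changed |= _base_pass(kb, policy, traces)
        changed |= _realization_pass(kb, policy, traces)
        changed |= _bearer_pass(kb, policy, traces)
        changed |= _run_definitional(kb, traces)
        if not changed:
            break
        if not policy.enabled:
            break  # report-only generative traces are one-shot
    # dedupe report-only traces from repeated passes
    if not policy.enabled:
        seen: set = set()
        uniq = []
        for tr in traces:
            k = (tr.rule, tr.derived)
            if k not in seen:
                seen.add(k)
                uniq.append(tr)
        traces = uniq
    return kb, traces
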