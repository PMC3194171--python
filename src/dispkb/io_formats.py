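"""Load/save the native KB file format and export to Turtle/OWL.

The native format is a small JSON dialect rather than OWL, because the
generative surefire principles and the prohibition on asserting the
definitional relations are not OWL-expressible; OWL is an export target,
not the source of truth.  A document looks like::

    {
      "format_version": "1.0",
      "types":     [{"name": "Match", "kind": "material_entity", "parents": []}],
      "axioms":    [{"disposition_type": "Inflammability",
                     "realization_types": ["Inflammation"],
                     "trigger_types": ["Striking"],
                     "bearer_type": "Match", "surefire": true}],
      "instances": [{"name": "match1", "types": ["Match"]}],
      "facts":     [{"relation": "inheres_in",
                     "subject": "m_disp", "object": "match1"}]
    }

Saving is canonical (sections sorted by identifier, two-space indent,
trailing newline), so identical stores produce byte-identical files.
Derived content is saved under a separate ``derived`` section and only on
request.  Unknown top-level keys are rejected with a versioned error.

The Turtle export renders types as OWL classes under the four top-kind
classes, instances as named individuals, facts as object-property
assertions, and disposition axioms as class-level restrictions —
universal (``owl:allValuesFrom``) for the realization and trigger value
restrictions, existential (``owl:someValuesFrom``) for the all-some
bearer, essential-disposition and trigger-of-realization claims, with
multi-track alternatives as ``owl:unionOf`` class expressions.  IRIs live
in a project namespace of their own; BFO/RO IRIs are deliberately not
reused, to avoid asserting exact equivalence with external ontologies.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL
from rdflib.collection import Collection

from .core_model import (
    DispositionAxiom,
    Fact,
    InstanceDecl,
    KBError,
    KnowledgeBase,
    OntKind,
    RELATIONS,
    TypeDecl,
)
from . import multitrack

FORMAT_VERSION = "1.0"

_TOP_KEYS = {"format_version", "types", "axioms", "instances", "facts", "derived"}


class FormatError(KBError):
    """The file does not conform to the KB document schema."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise FormatError(f"KB format {FORMAT_VERSION}: {msg}")


def _check_record(rec: dict, required: set[str], optional: set[str], where: str) -> None:
    _require(isinstance(rec, dict), f"{where}: expected an object")
    keys = set(rec)
    _require(required <= keys, f"{where}: missing keys {sorted(required - keys)}")
    _require(keys <= required | optional, f"{where}: unknown keys {sorted(keys - required - optional)}")


def kb_from_document(doc: dict) -> KnowledgeBase:
    """Build a closed knowledge base from a parsed KB document."""
    _require(isinstance(doc, dict), "top level must be an object")
    unknown = set(doc) - _TOP_KEYS
    _require(not unknown, f"unknown top-level keys {sorted(unknown)}")
    version = doc.get("format_version", FORMAT_VERSION)
    _require(version == FORMAT_VERSION, f"unsupported format_version {version!r}")

    kb = KnowledgeBase()
    pending = list(doc.get("types", []))
    for rec in pending:
        _check_record(rec, {"name", "kind"}, {"parents", "comment"}, "types[]")
    # insert parents before children
    done: set[str] = set()
    while pending:
        progress = False
        for rec in list(pending):
            parents = set(rec.get("parents", []))
            if parents <= done:
                try:
                    kind = OntKind(rec["kind"])
                except ValueError:
                    raise FormatError(f"unknown kind {rec['kind']!r} for type {rec['name']!r}")
                kb.add_type(TypeDecl(rec["name"], kind, frozenset(parents)))
                done.add(rec["name"])
                pending.remove(rec)
                progress = True
        if not progress:
            names = sorted(r["name"] for r in pending)
            raise FormatError(f"unresolvable (cyclic or undeclared) parents among {names}")

    for rec in doc.get("axioms", []):
        _check_record(
            rec, {"disposition_type", "realization_types"},
            {"trigger_types", "bearer_type", "base_type", "surefire",
             "essential_of", "comment"}, "axioms[]")
        kb.add_axiom(DispositionAxiom(
            disposition_type=rec["disposition_type"],
            realization_types=tuple(rec["realization_types"]),
            trigger_types=tuple(rec.get("trigger_types", [])),
            bearer_type=rec.get("bearer_type"),
            base_type=rec.get("base_type"),
            surefire=bool(rec.get("surefire", False)),
            essential_of=rec.get("essential_of"),
            comment=rec.get("comment", ""),
        ))

    for rec in doc.get("instances", []):
        _check_record(rec, {"name", "types"}, {"comment"}, "instances[]")
        kb.add_instance(InstanceDecl(rec["name"], frozenset(rec["types"])))
        kb.kind_of_instance(rec["name"])  # abort on kind clash at load
    for rec in doc.get("facts", []):
        _check_record(rec, {"relation", "subject", "object"}, {"comment"}, "facts[]")
        kb.add_fact(Fact(rec["relation"], rec["subject"], rec["object"]))

    derived = doc.get("derived", {})
    if derived:
        _check_record(derived, set(), {"instances", "facts"}, "derived")
        for rec in derived.get("instances", []):
            kb.add_instance(InstanceDecl(rec["name"], frozenset(rec["types"]),
                                         provenance="skolem"))
        for rec in derived.get("facts", []):
            kb.add_fact(Fact(rec["relation"], rec["subject"], rec["object"],
                             provenance="derived"))
    return kb


def load_kb(path: Union[str, Path]) -> KnowledgeBase:
    """Load and close a KB file; abort-class problems (cycles, kind
    clashes, asserted definitional relations, reserved names) raise."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: not valid JSON: {e}") from e
    return kb_from_document(doc)


def kb_to_document(kb: KnowledgeBase, include_derived: bool = False) -> dict:
    def type_rec(t: TypeDecl) -> dict:
        return {"name": t.name, "kind": t.kind.value, "parents": sorted(t.parents)}

    def inst_rec(i: InstanceDecl) -> dict:
        # save the asserted-equivalent type set; closure is recomputed on load
        return {"name": i.name, "types": sorted(_minimal_types(kb, i))}

    def fact_rec(f: Fact) -> dict:
        return {"relation": f.relation, "subject": f.subject, "object": f.object}

    def axiom_rec(a: DispositionAxiom) -> dict:
        rec: dict = {
            "disposition_type": a.disposition_type,
            "realization_types": list(a.realization_types),
        }
        if a.trigger_types:
            rec["trigger_types"] = list(a.trigger_types)
        if a.bearer_type:
            rec["bearer_type"] = a.bearer_type
        if a.base_type:
            rec["base_type"] = a.base_type
        if a.surefire:
            rec["surefire"] = True
        if a.essential_of:
            rec["essential_of"] = a.essential_of
        if a.comment:
            rec["comment"] = a.comment
        return rec

    doc: dict = {
        "format_version": FORMAT_VERSION,
        "types": [type_rec(t) for _, t in sorted(kb.types.items())],
        "axioms": [axiom_rec(a) for a in sorted(kb.axioms, key=lambda a: a.key())],
        "instances": [inst_rec(i) for n, i in sorted(kb.instances.items())
                      if i.provenance == "asserted"],
        "facts": [fact_rec(f) for f in kb.facts if f.provenance == "asserted"],
    }
    if include_derived:
        doc["derived"] = {
            "instances": [inst_rec(i) for n, i in sorted(kb.instances.items())
                          if i.provenance == "skolem"],
            "facts": [fact_rec(f) for f in kb.facts if f.provenance == "derived"],
        }
    return doc


def _minimal_types(kb: KnowledgeBase, inst: InstanceDecl) -> set[str]:
    """Most-specific members of a closed type set (closure re-adds the rest)."""
    return {
        t for t in inst.types
        if not any(t != u and kb.is_subtype(u, t) for u in inst.types)
    }


def save_kb(kb: KnowledgeBase, path: Union[str, Path],
            include_derived: bool = False) -> None:
    """Write the canonical serialization (byte-stable across runs)."""
    doc = kb_to_document(kb, include_derived=include_derived)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ------------------------------------------------------------------- turtle

DISP = Namespace("https://example.org/dispkb#")

_KIND_CLASS = {
    OntKind.MATERIAL_ENTITY: DISP.MaterialEntity,
    OntKind.QUALITY: DISP.Quality,
    OntKind.DISPOSITION: DISP.Disposition,
    OntKind.PROCESS: DISP.Process,
}


def kb_to_graph(kb: KnowledgeBase) -> Graph:
    g = Graph()
    g.bind("disp", DISP)
    g.bind("owl", OWL)
    # fixed preamble: the four top classes and six object properties
    for cls in _KIND_CLASS.values():
        g.add((cls, RDF.type, OWL.Class))
    for rel in RELATIONS:
        g.add((DISP[rel], RDF.type, OWL.ObjectProperty))

    for name, t in sorted(kb.types.items()):
        iri = DISP[name]
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.subClassOf, _KIND_CLASS[t.kind]))
        for p in sorted(t.parents):
            g.add((iri, RDFS.subClassOf, DISP[p]))

    for name, inst in sorted(kb.instances.items()):
        iri = DISP[name]
        g.add((iri, RDF.type, OWL.NamedIndividual))
        for t in sorted(_minimal_types(kb, inst)):
            g.add((iri, RDF.type, DISP[t]))

    for f in kb.facts:
        g.add((DISP[f.subject], DISP[f.relation], DISP[f.object]))

    for ax in sorted(kb.axioms, key=lambda a: a.key()):
        _axiom_triples(g, kb, ax)
    return g


def _class_expr(g: Graph, kb: KnowledgeBase, t: str):
    """A named class, or an owl:unionOf expression for union scopes."""
    if t in kb.unions:
        members = kb.unions[t]
        node = BNode()
        g.add((node, RDF.type, OWL.Class))
        lst = BNode()
        Collection(g, lst, [DISP[m] for m in members])
        g.add((node, OWL.unionOf, lst))
        return node
    return DISP[t]


def _restriction(g: Graph, prop, quantifier, filler):
    node = BNode()
    g.add((node, RDF.type, OWL.Restriction))
    g.add((node, OWL.onProperty, prop))
    g.add((node, quantifier, filler))
    return node


def _axiom_triples(g: Graph, kb: KnowledgeBase, ax: DispositionAxiom) -> None:
    D = DISP[ax.disposition_type]
    r_scope = multitrack.realization_scope(kb, ax)
    t_scope = multitrack.trigger_scope(kb, ax)
    # value restriction: realizations stay within the track(s)
    g.add((D, RDFS.subClassOf, _restriction(
        g, DISP.has_realization, OWL.allValuesFrom, _class_expr(g, kb, r_scope))))
    if t_scope is not None:
        g.add((D, RDFS.subClassOf, _restriction(
            g, DISP.has_trigger_D, OWL.allValuesFrom, _class_expr(g, kb, t_scope))))
        # all-some: every realization of a declared track has a trigger
        for r_type in dict.fromkeys(ax.realization_types):
            g.add((_class_expr(g, kb, r_type), RDFS.subClassOf, _restriction(
                g, DISP.has_trigger_R, OWL.someValuesFrom, _class_expr(g, kb, t_scope))))
    if ax.bearer_type:
        g.add((D, RDFS.subClassOf, _restriction(
            g, DISP.inheres_in, OWL.someValuesFrom, DISP[ax.bearer_type])))
    if ax.base_type:
        g.add((DISP[ax.base_type], RDFS.subClassOf, _restriction(
            g, DISP.base_of, OWL.someValuesFrom, D)))
        g.add((DISP.base_of, RDF.type, OWL.ObjectProperty))
    if ax.essential_of:
        g.add((DISP[ax.essential_of], RDFS.subClassOf, _restriction(
            g, DISP.has_disposition, OWL.someValuesFrom, D)))
    if ax.surefire:
        g.add((D, DISP.surefire, Literal(True)))


def export_turtle(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    """Serialize to Turtle; the output re-parses with any standard Turtle
    parser and re-export yields an isomorphic graph."""
    g = kb_to_graph(kb)
    g.serialize(destination=str(path), format="turtle")
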