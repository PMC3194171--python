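# Methods

## The model

`dispkb` implements a formal theory of *dispositions* — causal properties
such as fragility, solubility, allergies or diseases — as an executable
knowledge base. The model is organised around a square of four top-level
categories and the binary relations connecting their instances:

* a **bearer** (material entity) carries the disposition: `inheres_in`;
* a **base** (quality of the bearer) grounds it: a quality instance in a
  bearer brings a disposition instance of the based type with it;
* a **realization** (process) is what happens when the disposition
  manifests: `has_realization`, with the bearer as `has_participant`;
* a **trigger** (process) initiates the realization: `has_trigger_R`
  (realization → trigger) is primitive, and `has_trigger_D`
  (disposition → trigger) is defined through it.

Two relations are *definitional* and may never be asserted in input:
`has_disposition(x, d)` holds exactly when a disposition instance `d`
inheres in `x`, and `has_trigger_D(d, t)` holds exactly when some
realization of `d` has trigger `t`. Allowing them in input files would
let a store contradict its own definitions silently, so the loader
aborts instead.

Type-level knowledge is captured by *disposition axioms* binding a
disposition type to bearer, base, trigger and realization types, with a
`surefire` flag. Two semantic schemes are used deliberately:

* **all-some** ("every instance of A bears some instance of D") for
  essential dispositions, inherence and the trigger-of-realization link —
  here the witness must exist, closed-world;
* **value restrictions** ("*if* an instance of D is realized, the
  realization is of type R") for the realization and disposition-trigger
  links — a disposition may never be realized, and an unrealized
  disposition must not count as a data error. All value-restriction
  checks are therefore vacuously true on unrealized data.

## Saturation

The reasoner runs five rules to a least fixpoint:

| rule | effect |
|------|--------|
| `DEF1` | derive `has_disposition` from inherence |
| `DEF5` | derive `has_trigger_D` through realizations |
| `ESS2` | skolemize the disposition an essential axiom guarantees each host instance |
| `BASE8` | skolemize the disposition a borne base-quality instance brings with it |
| `REAL9`/`REAL13` | surefire principle: borne disposition + trigger instance ⇒ skolem realization (`REAL13` for multi-track axioms) |
| `BEARER10` | the bearer participates in every realization of a surefire disposition |

Skolem names are a deterministic function of the rule id and premise
identifiers (`__sk.<rule>.<ids>`), so saturation is replay-stable and the
independent naive fixpoint can be compared atom for atom. The chain is
stratified — base/essential skolems feed the realization principle, whose
skolems feed the bearer principle and the definitional rules, and nothing
feeds back — so termination is immediate and the result is independent of
rule order.

Interpretation choices that the underlying theory leaves open, resolved
here and recorded as this package's own conventions:

* The realization guaranteed by the surefire principle and the process
  the bearer participates in are identified (one shared skolem witness).
  The principles quantify separately; identifying the witnesses is the
  natural operational reading and is visible in the derivation trace.
* The realization rule fires once per (disposition instance, trigger
  instance) pair. An *asserted* realization of that disposition with
  that trigger, typed within the axiom's track(s), suppresses the skolem
  — the existential is already witnessed.
* For `ESS2`/`BASE8`, an *asserted* disposition witness in the right
  bearer suppresses skolemization, but a skolem created for a different
  base-type axiom does not: distinct bases each ground their own
  disposition instance, and suppression keyed to asserted content keeps
  the fixpoint order-independent.
* Multi-track skolems are instantiated at the **first listed** track; the
  union class is satisfied derivationally (membership in a union is
  always derived member-wise, never asserted). The choice of track is
  conventional, not entailed, and is visible in the trace.
* The bearer principle also adds participants to *asserted* realizations
  of surefire dispositions; the converse inference (from a process to a
  disposition it realizes) is never made, since one process typically
  realizes several dispositions of several participants.
* A surefire axiom with no trigger types (spontaneous realization, e.g.
  radioactive decay) is skipped with a warning — untriggered realization
  is out of scope, as are probabilistic propensities and time indices.
* With `SkolemPolicy(enabled=False)` (CLI `--no-skolem`) the generative
  rules report the witnesses they would create instead of creating them;
  the definitional rules still run.

## Validation

Validation is closed-world and non-fatal (violations are warnings;
only cyclic `is_a`, kind clashes, duplicate ids, asserted definitional
relations and reserved skolem names abort a load). The catalogue:

* `SQ1`–`SQ5` — category-square domain/range discipline of the five
  fundamental relations (SQ5 covers base-of axioms);
* `BEAR1`/`BEAR2` — a dependent continuant (quality or disposition) with
  zero, resp. more than one, bearer. The theory does not fix bearer
  cardinality; the convention of exactly one bearer per dependent
  continuant instance is adopted here and enforced as a warning;
* `AS_ESSENTIAL`, `AS_BEARER`, `AS_TRIG` — all-some axiom checks;
* `VR_REAL`, `VR_TRIG` — value-restriction axiom checks;
* `ASSERTED_DERIVED`, `SKOLEM_NAME` — the load-abort rules, re-reported
  when a store was built in memory past the loader.

Reports are ordered by (code, entity ids) for diff-stable output.
Generative axioms (`essential_of`, `base_type`) are only satisfiable
after saturation, so the zero-violation contract for such stores is
checked on the saturated KB; stores without generative axioms validate
clean both before and after.

## The oracle

`dispkb.oracle` is an independent brute-force implementation used purely
for checking: a ground first-order evaluator with substitutional
quantification over the finite instance domain, transcriptions of the
definitional and surefire laws as formula builders, a `naive_fixpoint`
that re-derives saturation by full rescans with no indexing, and an
exhaustive `ground_validate`. The skolem naming function is shared with
the reasoner by design — it is what makes the two derivations comparable
— but the rule code is written independently against the rule
descriptions. Substitutional quantification is the right semantics here
because the validator is closed-world: "possible but absent"
realizations are deliberately outside the formal model.

## Synthetic data

`generate_random_kb` emulates desk-scale curated stores, not harvested
ontologies: a handful of bearer instances of one material type, two
disposition types (possibly one specializing the other), three process
types split into disjoint realization and trigger pools, optional base
qualities, optional asserted realization/trigger pairs, and per-axiom
trigger instances with probability `p_trigger` (default 0.5, so both
realized and dormant dispositions occur; multi-track axioms appear with
probability 0.25). Defaults keep each KB at roughly ≤ 8 instances and
≤ 7 types — large enough to exercise every rule interaction, small
enough that the exhaustive oracle is instant and the 1000-KB corpus runs
in a few seconds. Two regularities are built in so that generated KBs
validate clean before and after saturation: a specializing disposition
type inherits its parent's tracks (otherwise two value restrictions
could genuinely disagree on shared instances), and trigger pools are
disjoint from realization pools. Essential (`essential_of`) axioms are
not generated randomly — they are only satisfiable post-saturation and
are covered by the aspirin fixture and unit tests. What the generator
does *not* emulate: large taxonomies, noisy or inconsistent curation,
open-world incompleteness, probabilistic dispositions. Passing the
corpus therefore certifies the logic (rule semantics, closure, and
serialization), not robustness to messy real-world ontologies.

Fault injection (`mutate_kb`) adds exactly one fault per call. The
bearerless-disposition fault introduces a fresh axiom-free disposition
type and instance rather than deleting an existing inherence fact:
deleting the bearer of an axiom-covered disposition would trip both the
bearer-existence check and the bearer-type axiom check, and the fault
catalogue is designed so each fault maps to exactly one violation code.

## Serialization

The native format is a small JSON dialect (documented in
`dispkb.io_formats`) because the generative principles and the
derived-relation prohibition are not OWL-expressible; OWL/Turtle is an
export target. Saving is canonical (sorted sections, fixed indentation),
so equality of stores implies byte-equality of files. Instances are
saved with their most-specific types; the upward closure is recomputed
on load. The Turtle export uses a project namespace (BFO/RO IRIs are not
reused, to avoid asserting exact equivalence with external ontologies),
renders value restrictions as `owl:allValuesFrom`, all-some claims as
`owl:someValuesFrom`, and multi-track alternatives as `owl:unionOf`;
an empty store exports exactly the 10-triple preamble (4 top classes,
6 object properties).

## Known limitations

* Probabilistic propensities, background conditions as distinct from
  triggers, temporal indexing, non-monadic dispositions, and
  complementary disposition pairs are all out of scope.
* "Polycausality" (several disposition types, one realization type) and
  fully chaotic many-to-many cells have no formalization here; only
  single-track and multi-track/multi-trigger axioms are supported.
* No retraction: saturation is monotone forward chaining; removing an
  asserted fact requires rebuilding the store.
* Roles and functions (the other realizable entities) are not modelled.
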