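# dispkb

Executable knowledge bases for **dispositions** — the causal properties
biomedical ontologies lean on: fragility, solubility, allergies,
stainability, diseases-as-dispositions. A disposition links four kinds
of entity in a square of binary relations:

```
        base_of
  Quality ────────► Disposition
     │                 │   │
     │ inheres_in      │   │ has_realization (value restriction)
     ▼                 ▼   ▼
  Material ◄────── inheres_in   Process (realization)
  Entity  ◄───────────────────── has_participant
                                 │ has_trigger_R
                                 ▼
                               Process (trigger)
```

At the instance level, `has_disposition(x, d)` is *defined* as a
disposition instance `d` inhering in `x`, and `has_trigger_D(d, t)` as
`∃r: has_realization(d, r) ∧ has_trigger_R(r, t)` — so neither may be
asserted, only derived. At the type level two semantics coexist:
**all-some** (every instance of *A* bears some instance of *D*) where a
witness must exist, and **value restrictions** (*if* an instance of *D*
is realized, the realization is of type *R*) where dispositions may
stay unrealized — a feature, not a bug. For **surefire** dispositions
the realization principle is generative: disposition present, bearer
present, trigger present ⇒ the realization happens, and the bearer
participates in it. The reasoner skolemizes these existentials with
deterministic, replay-stable names. Multi-track dispositions (a fragile
glass may break, crack *or* splinter) are compiled to union classes so
the single-track machinery applies unchanged.

The package provides:

* `dispkb.core_model` — typed stores with eager `is_a` / `instance_of`
  closure over the four fixed kinds;
* `dispkb.instance_reasoner` — forward chaining to a least fixpoint with
  derivation traces and deterministic skolemization;
* `dispkb.type_semantics` — all-some and value-restriction checks with
  concrete counterexamples, plus claim induction from instance data;
* `dispkb.multitrack` — union-class compilation for multi-track /
  multi-trigger axioms;
* `dispkb.validator` — closed-world structural validation (category
  square, bearer existence, axiom conformance);
* `dispkb.oracle` — an independent ground first-order evaluator and
  naive fixpoint used to cross-check reasoner and validator;
* `dispkb.io_formats` — a canonical JSON KB format and Turtle/OWL export
  (rdflib), plus the `dispkb` CLI;
* `dispkb.fixtures` — ten worked examples and a seeded random-KB
  generator with a five-class fault injector.

## Worked example

```pycon
>>> from dispkb import build_worked_example, validate
>>> from dispkb.instance_reasoner import saturate
>>> kb = build_worked_example("salt_solubility")
>>> kb2, traces = saturate(kb)
>>> for t in traces:
...     print(t.format())
instance __sk.BASE8.NaClStructure.WaterSolubility.salt1 <- BASE8(q1, salt1)
instance __sk.REAL9.__sk.BASE8.NaClStructure.WaterSolubility.salt1.imm1.Dissolution <- REAL9(__sk.BASE8.NaClStructure.WaterSolubility.salt1, imm1)
has_realization(__sk.BASE8.NaClStructure.WaterSolubility.salt1, __sk.REAL9.__sk.BASE8.NaClStructure.WaterSolubility.salt1.imm1.Dissolution) <- REAL9(__sk.BASE8.NaClStructure.WaterSolubility.salt1, imm1)
has_trigger_R(__sk.REAL9.__sk.BASE8.NaClStructure.WaterSolubility.salt1.imm1.Dissolution, imm1) <- REAL9(__sk.BASE8.NaClStructure.WaterSolubility.salt1, imm1)
has_participant(__sk.REAL9.__sk.BASE8.NaClStructure.WaterSolubility.salt1.imm1.Dissolution, salt1) <- BEARER10(__sk.BASE8.NaClStructure.WaterSolubility.salt1, __sk.REAL9.__sk.BASE8.NaClStructure.WaterSolubility.salt1.imm1.Dissolution, salt1)
has_disposition(salt1, __sk.BASE8.NaClStructure.WaterSolubility.salt1) <- DEF1(__sk.BASE8.NaClStructure.WaterSolubility.salt1, salt1)
has_trigger_D(__sk.BASE8.NaClStructure.WaterSolubility.salt1, imm1) <- DEF5(__sk.BASE8.NaClStructure.WaterSolubility.salt1, imm1)
>>> validate(kb2).format()
'OK: 0 violations'
```

Read the trace bottom-up from the asserted data: the NaCl-structure
quality `q1` inheres in `salt1`, so the base rule creates the
water-solubility disposition; an immersion event `imm1` is present, so
the surefire realization rule creates a dissolution process triggered by
it; the bearer rule makes `salt1` a participant of that dissolution; and
the definitional rules fill in `has_disposition` and `has_trigger_D`.
Remove `imm1` and nothing is realized — the salt is still soluble.

The same pipeline is available from the shell:

```sh
dispkb demo salt_solubility          # saturate + validate a fixture
dispkb validate my_kb.json           # closed-world checks, exit 1 on violations
dispkb infer my_kb.json -o out.json  # saturate, print trace, save derived section
dispkb infer my_kb.json --no-skolem  # report witnesses without creating them
dispkb check my_kb.json              # one OK/FAIL line per type-level claim
dispkb export my_kb.json -f turtle -o my_kb.ttl
dispkb randgen --seed 7 -o random.json
```

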