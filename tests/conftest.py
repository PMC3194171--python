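import pytest

from dispkb import (
    DispositionAxiom,
    Fact,
    InstanceDecl,
    KnowledgeBase,
    OntKind,
    RandomKBParams,
    TypeDecl,
    build_worked_example,
    fixture_names,
    generate_random_kb,
)


def make_match_kb() -> KnowledgeBase:
    """Hand-built copy of the match scenario (independent of fixtures)."""
    kb = KnowledgeBase()
    kb.add_type(TypeDecl("Match", OntKind.MATERIAL_ENTITY))
    kb.add_type(TypeDecl("Inflammability", OntKind.DISPOSITION))
    kb.add_type(TypeDecl("Striking", OntKind.PROCESS))
    kb.add_type(TypeDecl("Inflammation", OntKind.PROCESS))
    kb.add_axiom(DispositionAxiom(
        disposition_type="Inflammability",
        realization_types=("Inflammation",),
        trigger_types=("Striking",),
        bearer_type="Match", surefire=True))
    kb.add_instance(InstanceDecl("match1", frozenset({"Match"})))
    kb.add_instance(InstanceDecl("m_disp", frozenset({"Inflammability"})))
    kb.add_instance(InstanceDecl("strike1", frozenset({"Striking"})))
    kb.add_fact(Fact("inheres_in", "m_disp", "match1"))
    return kb


@pytest.fixture
def match_kb() -> KnowledgeBase:
    return make_match_kb()


@pytest.fixture(params=sorted(fixture_names()))
def any_fixture(request) -> KnowledgeBase:
    return build_worked_example(request.param)


def random_corpus(n: int, **overrides):
    """Deterministic stream of small random KBs."""
    for seed in range(n):
        yield generate_random_kb(RandomKBParams(seed=seed, **overrides))
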