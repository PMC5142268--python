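import pytest

from phenoconsensus.annotations import build_corpus
from phenoconsensus.ontology import OntologyGraph
from phenoconsensus.similarity import compute_ic


CHAIN_OBO = """\
format-version: 1.2
ontology: test

[Term]
id: T:0000
name: root

[Term]
id: T:0001
name: mid
is_a: T:0000
alt_id: A:0001

[Term]
id: T:0002
name: leaf
is_a: T:0001

[Term]
id: T:0009
name: gone
is_a: T:0000
is_obsolete: true
"""


@pytest.fixture
def chain_obo_text():
    return CHAIN_OBO


@pytest.fixture
def diamond_graph():
    """Root R with child A (children B, C) and child D."""
    return OntologyGraph(
        terms={"R", "A", "B", "C", "D"},
        names={t: t.lower() for t in "RABCD"},
        parents={"R": set(), "A": {"R"}, "B": {"A"}, "C": {"A"}, "D": {"R"}},
        alt_ids={},
        root="R",
    )


@pytest.fixture
def diamond_corpus():
    """Four genes: G1 -> {B}, G2 -> {C}, G3/G4 -> {D} (|Omega| = 4)."""
    return build_corpus(
        {
            "d1": frozenset({"B"}),
            "d2": frozenset({"C"}),
            "d3": frozenset({"D"}),
            "d4": frozenset({"D"}),
        },
        {
            "G1": frozenset({"d1"}),
            "G2": frozenset({"d2"}),
            "G3": frozenset({"d3"}),
            "G4": frozenset({"d4"}),
        },
    )


@pytest.fixture
def diamond_ic(diamond_graph, diamond_corpus):
    return compute_ic(diamond_graph, diamond_corpus)
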