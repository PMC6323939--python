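import pytest

from phylogo.fixtures import make_dag, make_family
from phylogo.ontology import OntologyGraph, TermRecord


@pytest.fixture
def diamond() -> OntologyGraph:
    """D is the root; A has two paths to it (A->B->D, A->C->D)."""
    terms = [TermRecord(t, aspect="biological_process") for t in "ABCD"]
    edges = {("A", "B", "is_a"), ("A", "C", "is_a"),
             ("B", "D", "is_a"), ("C", "D", "part_of")}
    return OntologyGraph.from_parts(terms, edges)


@pytest.fixture
def chain() -> OntologyGraph:
    terms = [TermRecord(t, aspect="molecular_function") for t in "ABC"]
    edges = {("A", "B", "is_a"), ("B", "C", "is_a")}
    return OntologyGraph.from_parts(terms, edges)


@pytest.fixture(params=range(5))
def random_dag(request) -> OntologyGraph:
    return make_dag(50, seed=request.param)


@pytest.fixture(params=range(5))
def random_family(request, random_dag):
    return make_family(
        n_leaves=12, dup_prob=0.35, gain_rate=0.7, loss_rate=0.2,
        graph=random_dag, seed=request.param + 17,
    )
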