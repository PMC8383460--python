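import numpy as np
import pytest

from phenomine.fixtures import FixtureSpec, gen_corpus, gen_ontology, gen_planted_pairs
from phenomine.ontology import OntologyClass, OntologyGraph, TermLexicon


def make_graph(labels: dict[str, str], edges: list[tuple[str, str]], synonyms=None) -> OntologyGraph:
    """Build a small graph from {id: label} and (child, parent) edges."""
    synonyms = synonyms or {}
    classes = [
        OntologyClass(cid, label, frozenset(synonyms.get(cid, ())))
        for cid, label in labels.items()
    ]
    return OntologyGraph(classes, edges)


def random_dag(n_nodes: int, seed: int, edge_prob: float = 0.15) -> OntologyGraph:
    """Random labeled DAG: edges only from higher to lower index (child -> parent)."""
    rng = np.random.default_rng(seed)
    labels = {f"N{i}": f"node {i} label" for i in range(n_nodes)}
    edges = [
        (f"N{i}", f"N{j}")
        for i in range(1, n_nodes)
        for j in range(i)
        if rng.random() < edge_prob
    ]
    return make_graph(labels, edges)


def brute_force_descendants(g: OntologyGraph, root: str, include_self: bool) -> set[str]:
    """Naive fixed-point expansion over direct children."""
    out = {root}
    changed = True
    while changed:
        changed = False
        for cid in list(out):
            for child in g.children(cid):
                if child not in out:
                    out.add(child)
                    changed = True
    return out if include_self else out - {root}


@pytest.fixture(scope="session")
def chain_graph():
    """A ⊑ B ⊑ C."""
    return make_graph({"A": "class a", "B": "class b", "C": "class c"}, [("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def g30_graph():
    """ICD-style fixture: G30 with its four dotted subcodes."""
    return make_graph(
        {
            "G30": "alzheimer's disease",
            "G30.0": "alzheimer's disease with early onset",
            "G30.1": "alzheimer's disease with late onset",
            "G30.8": "other alzheimer's disease",
            "G30.9": "alzheimer's disease unspecified",
        },
        [("G30.0", "G30"), ("G30.1", "G30"), ("G30.8", "G30"), ("G30.9", "G30")],
    )


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(n_docs=200, seed=7)


@pytest.fixture(scope="session")
def fixture_world(small_spec):
    """One generated world shared by mining/scoring tests: ontologies,
    lexicons, planted pairs, 200-doc corpus."""
    g_d, lex_d = gen_ontology(small_spec, "disease")
    g_p, lex_p = gen_ontology(small_spec, "phenotype")
    planted = gen_planted_pairs(small_spec, g_d, g_p)
    docs, truth = gen_corpus(small_spec, g_d, g_p, planted)
    return {
        "spec": small_spec,
        "g_d": g_d,
        "g_p": g_p,
        "lex_d": lex_d,
        "lex_p": lex_p,
        "planted": planted,
        "docs": docs,
        "truth": truth,
    }
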