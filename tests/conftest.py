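import io

import numpy as np
import pytest

from gorelax.goldstd import AnnotationSet
from gorelax.network import AssociationNetwork
from gorelax.ontology import EdgeWeights, OntologyDAG, parse_obo

TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: A
is_a: GO:0000001

[Term]
id: GO:0000003
name: B
is_a: GO:0000001
"""


@pytest.fixture
def toy_dag():
    """Root R with two sibling children A, B (all is_a)."""
    return parse_obo(io.StringIO(TOY_OBO))


@pytest.fixture
def chain_dag():
    """A is_a B is_a R."""
    return OntologyDAG(
        {"R": "root", "B": "mid", "A": "leaf"},
        [("A", "B", "is_a"), ("B", "R", "is_a")],
    )


@pytest.fixture
def diamond_dag():
    """A reaches R through is_a B and part_of C."""
    return OntologyDAG(
        {"R": "root", "B": "b", "C": "c", "A": "a"},
        [
            ("A", "B", "is_a"),
            ("A", "C", "part_of"),
            ("B", "R", "is_a"),
            ("C", "R", "is_a"),
        ],
    )


@pytest.fixture
def default_weights():
    return EdgeWeights({"is_a": 0.8, "part_of": 0.6})


@pytest.fixture
def toy_network():
    """Triangle a-b (0.9), a-c (0.75), b-c (0.6) after no filtering."""
    net = AssociationNetwork()
    net.add_edge("a", "b", 0.9)
    net.add_edge("a", "c", 0.75)
    net.add_edge("b", "c", 0.6)
    return net


@pytest.fixture
def toy_network_tsv():
    return io.StringIO("a\tb\t0.9\na\tc\t0.75\nb\tc\t0.6\n")


def random_dag_edges(rng, n_terms, relations=("is_a", "part_of")):
    """A random layered DAG for oracle tests; returns (terms, edges)."""
    terms = {f"T{i}": f"term {i}" for i in range(n_terms)}
    ids = list(terms)
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + (rng.random() < 0.4)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for j in np.atleast_1d(parents):
            edges.append((ids[i], ids[int(j)], relations[int(rng.integers(len(relations)))]))
    return terms, edges


def brute_force_svalues(dag, focus, weights):
    """Oracle: max product of edge factors over every path focus -> ancestor."""
    best = {focus: 1.0}
    stack = [(focus, 1.0)]
    while stack:
        term, value = stack.pop()
        for parent, rel in dag.parents[term]:
            v = value * weights[rel]
            if v > best.get(parent, 0.0):
                best[parent] = v
                stack.append((parent, v))
    return best


def brute_force_auc(scores, labels):
    """Oracle: all-pairs concordance with 0.5 credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def make_annotations(labels: dict[str, set[str]], terms=None) -> AnnotationSet:
    """AnnotationSet from bare protein -> label-set maps (IPI evidence)."""
    if terms is None:
        terms = sorted({t for ls in labels.values() for t in ls})
    records = {p: {(t, "IPI") for t in ls} for p, ls in labels.items()}
    return AnnotationSet(records, list(terms))
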