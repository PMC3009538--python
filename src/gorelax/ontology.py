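"""Ontology handling and Wang semantic similarity.

Parses an OBO 1.2 ontology into a light-weight DAG and implements the
graph-structural semantic similarity of Wang et al. (2007): every ancestor
``q`` of a term ``A`` receives an S-value

    S_A(A) = 1
    S_A(q) = max over children q' of q (within A's ancestor closure)
             of  r_e(q -> q') * S_A(q')

where ``r_e`` is a per-relation contribution factor in (0, 1).  The
similarity between two terms is the normalised overlap of their S-values:

    Sim(A, B) = sum_{q in T_A ∩ T_B} (S_A(q) + S_B(q)) / (SV(A) + SV(B))

with SV(X) = sum of S-values over X's ancestor closure.  Pairwise
similarities over a label set form the term-term compatibility matrix used
by the relaxation labelling predictor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

#: Relation kinds the similarity measure assigns a contribution factor to.
SUPPORTED_RELATIONS = ("is_a", "part_of")

#: Default per-relation edge contribution factors (Wang et al. defaults).
DEFAULT_EDGE_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, dangling ids)."""


@dataclass(frozen=True)
class EdgeWeights:
    """Per-relation contribution factors r_e, each strictly inside (0, 1)."""

    factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for rel, r in self.factors.items():
            if not 0.0 < r < 1.0:
                raise ValueError(f"edge factor for {rel!r} must be in (0,1), got {r}")

    def __getitem__(self, relation: str) -> float:
        return self.factors[relation]


class OntologyDAG:
    """A directed acyclic graph of ontology terms.

    Edges point child -> parent and carry a relation kind (``is_a`` or
    ``part_of``).  Obsolete terms are excluded at parse time.
    """

    def __init__(
        self,
        terms: Mapping[str, str],
        edges: Iterable[tuple[str, str, str]],
    ) -> None:
        self.names = dict(terms)
        self.parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.names}
        self.children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.names}
        seen: set[tuple[str, str, str]] = set()
        for child, parent, relation in edges:
            for endpoint in (child, parent):
                if endpoint not in self.names:
                    raise OntologyError(
                        f"edge references unknown term {endpoint!r}"
                    )
            key = (child, parent, relation)
            if key in seen:
                continue
            seen.add(key)
            self.parents[child].append((parent, relation))
            self.children[parent].append((child, relation))
        self._check_acyclic()

    # -- construction -----------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for child, plist in self.parents.items():
            for parent, _ in plist:
                g.add_edge(child, parent)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")

    # -- queries -----------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.names)

    @property
    def roots(self) -> set[str]:
        return {t for t, p in self.parents.items() if not p}

    def __contains__(self, term: str) -> bool:
        return term in self.names

    def __len__(self) -> int:
        return len(self.names)

    def n_edges(self) -> int:
        return sum(len(p) for p in self.parents.values())

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` by parent edges (term excluded)."""
        if term not in self.names:
            raise KeyError(f"unknown term {term!r}")
        out: set[str] = set()
        stack = [p for p, _ in self.parents[term]]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(p for p, _ in self.parents[t])
        return out


def parse_obo(source: IO[str] | str) -> OntologyDAG:
    """Parse OBO 1.2 text into an :class:`OntologyDAG`.

    ``is_a`` and ``relationship: part_of`` lines become typed parent edges;
    other relationship kinds are dropped with a warning.  Terms flagged
    ``is_obsolete: true`` are excluded (obonet's default).  A dangling
    parent reference or a cycle is a hard error.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # obonet warns on unknown ontology version
        graph = obonet.read_obo(source, ignore_obsolete=True)
    terms: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data and not data:
            # networkx auto-created the node from a reference in some stanza
            raise OntologyError(f"dangling reference to undefined term {node!r}")
        terms[node] = data.get("name", node)
    edges: list[tuple[str, str, str]] = []
    skipped: set[str] = set()
    for child, parent, relation in graph.edges(keys=True):
        if relation in SUPPORTED_RELATIONS:
            if parent not in terms:
                raise OntologyError(f"dangling reference to undefined term {parent!r}")
            edges.append((child, parent, relation))
        else:
            skipped.add(relation)
    for relation in sorted(skipped):
        logger.warning("ignoring unsupported relation kind %r", relation)
    return OntologyDAG(terms, edges)


def write_obo(dag: OntologyDAG, stream: IO[str]) -> None:
    """Write the DAG as minimal OBO 1.2 (round-trips through parse_obo)."""
    stream.write("format-version: 1.2\n")
    for term in sorted(dag.names):
        stream.write(f"\n[Term]\nid: {term}\nname: {dag.names[term]}\n")
        for parent, relation in sorted(dag.parents[term]):
            if relation == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {relation} {parent}\n")


@dataclass
class TermAncestorGraph:
    """Ancestor closure of one focus term with its S-values.

    ``svalues`` maps every member (the focus plus all ancestors) to its
    semantic contribution S_focus(q) in (0, 1]; ``sv_total`` is their sum.
    """

    focus: str
    svalues: dict[str, float]
    sv_total: float

    @property
    def members(self) -> set[str]:
        return set(self.svalues)


def ancestor_graph(
    dag: OntologyDAG, focus: str, weights: EdgeWeights | None = None
) -> TermAncestorGraph:
    """Build the ancestor closure of ``focus`` and compute its S-values.

    S-values follow the max-recurrence over the closure: each ancestor's
    value is the best product of edge factors along any downward path to
    the focus, computed by a memoised sweep in topological order.
    """
    if weights is None:
        weights = EdgeWeights()
    if focus not in dag:
        raise KeyError(f"unknown term {focus!r}")
    members = dag.ancestors(focus) | {focus}
    # order members children-before-parents so each S-value is final when read
    sub = nx.DiGraph()
    sub.add_nodes_from(members)
    for t in members:
        for parent, rel in dag.parents[t]:
            if parent in members:
                sub.add_edge(t, parent, relation=rel)
    svalues: dict[str, float] = {focus: 1.0}
    for term in nx.topological_sort(sub):
        if term == focus:
            continue
        best = 0.0
        for child, rel in dag.children[term]:
            if child in members:
                cand = weights[rel] * svalues[child]
                if cand > best:
                    best = cand
        svalues[term] = best
    return TermAncestorGraph(focus, svalues, float(sum(svalues.values())))


def wang_similarity(ga: TermAncestorGraph, gb: TermAncestorGraph) -> float:
    """Wang semantic similarity between two terms given their ancestor graphs.

    Symmetric, in [0, 1]; equals 1 when both foci are the same term and 0
    when the terms share no ancestor (e.g. different GO namespaces).
    """
    shared = ga.members & gb.members
    if not shared:
        return 0.0
    num = sum(ga.svalues[q] + gb.svalues[q] for q in shared)
    return num / (ga.sv_total + gb.sv_total)


@dataclass
class CompatibilityMatrix:
    """Symmetric m x m matrix of term-term compatibilities in [0, 1].

    Row/column order follows ``terms``, the ordered label set of the
    predictor.  The diagonal is 1.
    """

    terms: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.terms)
        if self.values.shape != (m, m):
            raise ValueError("matrix shape does not match the term list")

    def index(self, term: str) -> int:
        return self.terms.index(term)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.index(a), self.index(b)])

    def to_tsv(self, stream: IO[str]) -> None:
        """Write the matrix as TSV with term-id header row and column."""
        stream.write("term\t" + "\t".join(self.terms) + "\n")
        for i, t in enumerate(self.terms):
            row = "\t".join(f"{v:.6f}" for v in self.values[i])
            stream.write(f"{t}\t{row}\n")


def compatibility_matrix(
    dag: OntologyDAG,
    terms: Iterable[str],
    weights: EdgeWeights | None = None,
) -> CompatibilityMatrix:
    """Pairwise Wang similarity over an ordered label set.

    Terms in disconnected ontology components (e.g. distinct GO namespaces)
    get zero off-diagonal compatibility because their ancestor closures are
    disjoint.
    """
    terms = list(terms)
    missing = [t for t in terms if t not in dag]
    if missing:
        raise KeyError(f"terms absent from ontology: {', '.join(missing)}")
    graphs = [ancestor_graph(dag, t, weights) for t in terms]
    m = len(terms)
    values = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = wang_similarity(graphs[i], graphs[j])
    return CompatibilityMatrix(terms, values)
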