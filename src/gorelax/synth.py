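"""Synthetic ontologies, networks and annotations with planted structure.

The generator emulates the statistical regime the predictor assumes:
proteins cluster into functional modules that are more densely connected
internally than externally, each module is labelled with a primary GO-like
term, and functional labels co-occur in a way that mirrors their semantic
similarity — a protein carrying a module's primary term also carries that
term's ontology sibling with probability ``rho``.  Association scores are
drawn from the post-filter high-confidence regime (uniform on
[0.75, 1.0] by default).  Annotation noise independently flips
(protein, term) indicators at a fixed rate.

Everything is driven by one seed; identical specs give identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .goldstd import AnnotationSet
from .network import AssociationNetwork
from .ontology import OntologyDAG


@dataclass
class ScenarioSpec:
    """Parameters of a planted-module benchmark scenario."""

    n_proteins: int = 300
    n_terms: int = 8
    n_modules: int = 6
    dag_depth: int = 3
    dag_branching: int = 4
    part_of_fraction: float = 0.2
    within_p: float = 0.05
    between_p: float = 0.005
    score_low: float = 0.75
    score_high: float = 1.0
    rho: float = 0.8
    noise: float = 0.1
    seed: int = 0
    module_sizes: list[int] | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("part_of_fraction", "within_p", "between_p", "rho", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_proteins < 1 or self.n_terms < 2 or self.n_modules < 1:
            raise ValueError("sizes must be positive (and n_terms >= 2)")
        if self.module_sizes is not None and sum(self.module_sizes) != self.n_proteins:
            raise ValueError("module sizes must sum to n_proteins")

    def sizes(self) -> list[int]:
        if self.module_sizes is not None:
            return list(self.module_sizes)
        base, extra = divmod(self.n_proteins, self.n_modules)
        return [base + (1 if i < extra else 0) for i in range(self.n_modules)]


def random_dag(
    depth: int = 3,
    branching: int = 4,
    part_of_fraction: float = 0.2,
    seed: int = 0,
) -> OntologyDAG:
    """A single-rooted layered DAG of GO-like terms.

    Level 0 is the root; every term at level d has ``branching`` children
    at level d+1, and each non-root term additionally gains a second
    parent from the previous level with 50% probability (making it a true
    DAG, not a tree).  Each parent edge is ``part_of`` with the given
    fraction, ``is_a`` otherwise.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    terms: dict[str, str] = {"T:0000000": "root"}
    edges: list[tuple[str, str, str]] = []
    levels: list[list[str]] = [["T:0000000"]]
    counter = 1
    for d in range(1, depth):
        level: list[str] = []
        for parent in levels[d - 1]:
            for _ in range(branching):
                tid = f"T:{counter:07d}"
                counter += 1
                terms[tid] = f"term level {d} #{counter}"
                rel = "part_of" if rng.random() < part_of_fraction else "is_a"
                edges.append((tid, parent, rel))
                if len(levels[d - 1]) > 1 and rng.random() < 0.5:
                    second = levels[d - 1][rng.integers(len(levels[d - 1]))]
                    if second != parent:
                        rel2 = "part_of" if rng.random() < part_of_fraction else "is_a"
                        edges.append((tid, second, rel2))
                level.append(tid)
        levels.append(level)
    return OntologyDAG(terms, edges)


def _label_terms(dag: OntologyDAG, n_terms: int, rng: np.random.Generator) -> list[str]:
    """Pick n_terms leaf-level terms as sibling pairs sharing a parent.

    Consecutive pairs in the returned list share a parent, so each term's
    designated "sibling" (its pair partner) is semantically close.
    """
    # group leaves by one of their parents
    leaves = sorted(t for t in dag.terms if not dag.children[t])
    by_parent: dict[str, list[str]] = {}
    for t in leaves:
        for parent, _ in dag.parents[t]:
            by_parent.setdefault(parent, []).append(t)
    pairs: list[tuple[str, str]] = []
    used: set[str] = set()
    for parent in sorted(by_parent):
        sibs = [t for t in by_parent[parent] if t not in used]
        while len(sibs) >= 2:
            a, b = sibs.pop(0), sibs.pop(0)
            pairs.append((a, b))
            used.update((a, b))
    if 2 * len(pairs) < n_terms:
        raise ValueError(
            f"ontology too small: need {n_terms} label terms, found {2 * len(pairs)}"
        )
    chosen = rng.permutation(len(pairs))[: (n_terms + 1) // 2]
    out: list[str] = []
    for idx in chosen:
        out.extend(pairs[idx])
    return out[:n_terms]


def planted_scenario(
    spec: ScenarioSpec,
) -> tuple[AssociationNetwork, AnnotationSet, OntologyDAG]:
    """Generate a module network with semantically correlated labels.

    Proteins are partitioned into modules.  Edges appear with probability
    ``within_p`` inside a module and ``between_p`` across modules, scored
    uniformly on [score_low, score_high].  Module i's proteins carry label
    term ``L[i mod n_terms]``; with probability ``rho`` a protein also
    carries that term's ontology sibling.  Each (protein, term) indicator
    is then flipped independently with probability ``noise``.  All
    annotations carry IPI evidence.
    """
    rng = np.random.default_rng(spec.seed)
    dag = random_dag(
        spec.dag_depth, spec.dag_branching, spec.part_of_fraction, spec.seed
    )
    terms = _label_terms(dag, spec.n_terms, rng)
    sibling = {}
    for i in range(0, len(terms) - 1, 2):
        sibling[terms[i]] = terms[i + 1]
        sibling[terms[i + 1]] = terms[i]
    if len(terms) % 2:
        sibling[terms[-1]] = terms[0]

    sizes = spec.sizes()
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    module_of: dict[str, int] = {}
    start = 0
    for mi, size in enumerate(sizes):
        for p in proteins[start : start + size]:
            module_of[p] = mi
        start += size

    net = AssociationNetwork()
    for p in proteins:
        net.add_protein(p)
    n = len(proteins)
    for i in range(n):
        for j in range(i + 1, n):
            same = module_of[proteins[i]] == module_of[proteins[j]]
            p_edge = spec.within_p if same else spec.between_p
            if rng.random() < p_edge:
                score = float(rng.uniform(spec.score_low, spec.score_high))
                score = min(max(score, 1e-9), 1.0)
                net.add_edge(proteins[i], proteins[j], score)

    # modules take pair-first terms before pair-second ones, so that sibling
    # terms without a module of their own still gain carriers through rho
    primary_order = terms[0::2] + terms[1::2]
    label_rows: dict[str, set[str]] = {}
    for p in proteins:
        primary = primary_order[module_of[p] % spec.n_terms]
        labels = {primary}
        if rng.random() < spec.rho:
            labels.add(sibling[primary])
        label_rows[p] = labels
    if spec.noise > 0:
        for p in proteins:
            for t in terms:
                if rng.random() < spec.noise:
                    label_rows[p] ^= {t}

    records = {
        p: {(t, "IPI") for t in labels} for p, labels in label_rows.items() if labels
    }
    annotations = AnnotationSet(records, sorted(terms))
    return net, annotations, dag
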