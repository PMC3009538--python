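"""Weighted protein functional-association networks.

A thin wrapper over an undirected :class:`networkx.Graph` whose edges carry
an association score a_ij in (0, 1] — the confidence that two proteins
share function.  Reading applies the high-confidence filter (score >= a
minimum, 0.75 by default, matching the probability cut-off used to build
integrated association networks).
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 0.75


class NetworkFormatError(ValueError):
    """Raised for malformed edge-list rows or out-of-range scores."""


class AssociationNetwork:
    """Undirected weighted graph over proteins.

    No self-edges, at most one edge per pair, scores in (0, 1].  Proteins
    may be isolated (e.g. annotated proteins absent from the edge list are
    added as isolated nodes so they can fall back to label priors).
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- building ----------------------------------------------------------

    def add_protein(self, protein: str) -> None:
        self._g.add_node(protein)

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            logger.warning("dropping self-edge on %r", a)
            return
        if not 0.0 < score <= 1.0:
            raise NetworkFormatError(f"score {score} for ({a},{b}) not in (0,1]")
        if self._g.has_edge(a, b):
            old = self._g[a][b]["score"]
            if score != old:
                logger.warning(
                    "duplicate edge (%s,%s): keeping max of %g and %g", a, b, old, score
                )
            score = max(score, old)
        self._g.add_edge(a, b, score=score)

    # -- queries -----------------------------------------------------------

    @property
    def proteins(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_proteins(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for a, b, data in self._g.edges(data=True):
            lo, hi = (a, b) if a <= b else (b, a)
            yield lo, hi, data["score"]

    def score(self, a: str, b: str) -> float:
        return self._g[a][b]["score"]

    def neighbors(self, protein: str) -> dict[str, float]:
        """Map of neighbour id -> association score; empty if isolated."""
        if protein not in self._g:
            raise KeyError(f"unknown protein {protein!r}")
        return {nbr: data["score"] for nbr, data in self._g[protein].items()}

    def degree(self, protein: str) -> int:
        return self._g.degree(protein)


def read_network(
    stream: IO[str], min_score: float = DEFAULT_MIN_SCORE
) -> AssociationNetwork:
    """Read a TSV edge list ``protein_a<TAB>protein_b<TAB>score``.

    Keeps only edges with score >= ``min_score`` (inclusive).  Lines
    starting with '#' and an optional non-numeric header row are skipped.
    Self-edges are dropped with a warning; duplicate pairs keep the maximum
    score.  Scores outside [0, 1] or malformed rows are hard errors naming
    the line number.
    """
    net = AssociationNetwork()
    seen_data = False
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise NetworkFormatError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        a, b, raw = fields[0].strip(), fields[1].strip(), fields[2].strip()
        try:
            score = float(raw)
        except ValueError:
            if not seen_data:  # tolerate one header row before any data
                seen_data = True
                continue
            raise NetworkFormatError(f"line {lineno}: unparseable score {raw!r}") from None
        seen_data = True
        if not 0.0 <= score <= 1.0:
            raise NetworkFormatError(f"line {lineno}: score {score} outside [0,1]")
        if a == b:
            logger.warning("line %d: dropping self-edge on %r", lineno, a)
            continue
        if score >= min_score and score > 0.0:
            net.add_edge(a, b, score)
    return net


def write_network(net: AssociationNetwork, stream: IO[str]) -> None:
    """Write the edge list; round-trips exactly through :func:`read_network`.

    Scores are printed with :func:`repr` so re-reading reproduces the exact
    float values (filter outcomes are bit-identical on re-read).
    """
    stream.write("protein_a\tprotein_b\tscore\n")
    for a, b, score in sorted(net.edges()):
        stream.write(f"{a}\t{b}\t{score!r}\n")


def ensure_proteins(net: AssociationNetwork, proteins: Iterable[str]) -> None:
    """Add any missing proteins as isolated nodes (annotation-only proteins)."""
    for p in proteins:
        net.add_protein(p)
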