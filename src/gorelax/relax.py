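"""Weighted-voting initialisation and relaxation labelling.

The predictor has two stages.

**Weighted voting** scores protein ``o_i``'s affinity for label ``l_k`` as
the score-weighted fraction of its labelled neighbours that carry the
label:

    P_i(l_k)^(0) = sum_{j in N_i} a_ij * theta(o_j, l_k)
                   / sum_{j in N_i} a_ij

where N_i ranges over the labelled (training) neighbours and theta is the
0/1 annotation indicator.  When no neighbour carries ``l_k`` (in particular
for isolated or neighbourless-of-labels proteins) the label's prior
frequency in the training gold standard is used instead.

**Relaxation labelling** then iteratively re-estimates each protein's label
probabilities from its neighbours' probabilities, weighted by a label-label
compatibility matrix C (here: GO semantic similarity).  The support a
neighbourhood lends to label ``l_k`` at generation T is

    Delta_i(l_k) = sum_{j in N_i} w_ij * sum_l C(l_k, l_l) * P_j(l_l)

with neighbour weights w_ij = a_ij / sum_j' a_ij' (so sum_j w_ij = 1), and
the probabilities are re-estimated multiplicatively and renormalised
(Rosenfeld-Hummel-Zucker form):

    P_i(l_k)^(T+1) = P_i(l_k) * (1 + Delta_i(l_k))
                     / sum_l P_i(l_l) * (1 + Delta_i(l_l))

Training proteins may be clamped to their 0/1 indicator rows.  Iteration is
synchronous and stops when the largest absolute probability change falls
below a tolerance, or at a maximum generation count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .goldstd import AnnotationSet
from .network import AssociationNetwork
from .ontology import CompatibilityMatrix

logger = logging.getLogger(__name__)


@dataclass
class LabelProbabilityMatrix:
    """n x m matrix of per-protein, per-term label probabilities."""

    proteins: list[str]
    terms: list[str]
    values: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.proteins), len(self.terms)):
            raise ValueError("matrix shape does not match protein/term lists")
        self._prow = {p: i for i, p in enumerate(self.proteins)}

    def row(self, protein: str) -> np.ndarray:
        return self.values[self._prow[protein]]

    def probability(self, protein: str, term: str) -> float:
        return float(self.values[self._prow[protein], self.terms.index(term)])

    def copy(self) -> "LabelProbabilityMatrix":
        return LabelProbabilityMatrix(
            list(self.proteins), list(self.terms), self.values.copy(), self.generation
        )


@dataclass
class RelaxationOptions:
    """Convergence controls for the relaxation iteration."""

    tolerance: float = 1e-4
    max_iterations: int = 100
    clamp_training: bool = True
    record_history: bool = False

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RelaxationResult:
    probabilities: LabelProbabilityMatrix
    iterations: int
    converged: bool
    max_changes: list[float] = field(default_factory=list)


# -- initialisation ----------------------------------------------------------


def init_probabilities(
    net: AssociationNetwork,
    annotations: AnnotationSet,
    hidden: frozenset[str] | set[str] = frozenset(),
) -> LabelProbabilityMatrix:
    """Weighted-voting initial probabilities (the local-classifier baseline).

    ``hidden`` proteins (a held-out cross-validation fold) contribute no
    annotation information: they neither vote nor enter the priors.  Rows
    are the raw voting ratios with the per-label prior fallback; they are
    NOT normalised here (the relaxation stage rescales its own copy).
    """
    hidden = set(hidden)
    training = annotations.labelled_proteins - hidden
    proteins = sorted(net.proteins)
    terms = list(annotations.terms)
    tindex = {t: i for i, t in enumerate(terms)}
    n, m = len(proteins), len(terms)

    if training:
        counts = np.zeros(m)
        for p in training:
            for t in annotations.labels(p):
                counts[tindex[t]] += 1
        priors = counts / len(training)
    else:
        logger.warning("no training proteins: falling back to uniform priors")
        priors = np.full(m, 1.0 / m)

    values = np.empty((n, m))
    for i, protein in enumerate(proteins):
        nbrs = {
            j: a for j, a in net.neighbors(protein).items() if j in training
        }
        if not nbrs:
            values[i] = priors
            continue
        denom = sum(nbrs.values())
        votes = np.zeros(m)
        for j, a in nbrs.items():
            for t in annotations.labels(j):
                votes[tindex[t]] += a
        row = votes / denom
        # prior fallback exactly where no neighbour carries the label
        zero = row == 0.0
        row[zero] = priors[zero]
        values[i] = row
    return LabelProbabilityMatrix(proteins, terms, values)


def neighbor_weights(net: AssociationNetwork, protein: str) -> dict[str, float]:
    """Score-proportional neighbour weights w_ij summing to 1.

    Empty for isolated proteins (their rows are never moved by the update).
    """
    nbrs = net.neighbors(protein)
    total = sum(nbrs.values())
    if total == 0.0:
        return {}
    return {j: a / total for j, a in nbrs.items()}


def _weight_matrix(net: AssociationNetwork, proteins: list[str]) -> np.ndarray:
    """Row-stochastic n x n matrix of neighbour weights (zero rows if isolated)."""
    n = len(proteins)
    index = {p: i for i, p in enumerate(proteins)}
    w = np.zeros((n, n))
    for i, p in enumerate(proteins):
        for j, a in net.neighbors(p).items():
            w[i, index[j]] = a
    totals = w.sum(axis=1, keepdims=True)
    np.divide(w, totals, out=w, where=totals > 0)
    return w


# -- iteration ----------------------------------------------------------------


def delta(
    P: LabelProbabilityMatrix,
    C: CompatibilityMatrix,
    weights: dict[str, float],
    term: str,
) -> float:
    """Support for one (protein, term) pair from its weighted neighbourhood."""
    if C.terms != P.terms:
        raise ValueError("compatibility and probability term orders differ")
    k = P.terms.index(term)
    total = 0.0
    for j, w in weights.items():
        total += w * float(C.values[k] @ P.row(j))
    return total


def _delta_matrix(values: np.ndarray, C: np.ndarray, W: np.ndarray) -> np.ndarray:
    # Delta[i,k] = sum_j W[i,j] * sum_l C[k,l] * P[j,l];  C is symmetric
    return W @ values @ C


def update_step(
    P: LabelProbabilityMatrix,
    C: CompatibilityMatrix,
    W: np.ndarray,
    clamped: frozenset[str] | set[str] = frozenset(),
) -> LabelProbabilityMatrix:
    """One synchronous multiplicative update of every unclamped row.

    Clamped rows (0/1 training indicators) pass through unchanged.  A row
    that is all zero before the update is left unchanged with a warning
    (its normaliser would vanish).
    """
    if C.terms != P.terms:
        raise ValueError("compatibility and probability term orders differ")
    values = P.values
    d = _delta_matrix(values, C.values, W)
    new = values * (1.0 + d)
    denom = new.sum(axis=1, keepdims=True)
    out = values.copy()
    movable = denom[:, 0] > 0.0
    if not movable.all():
        logger.warning(
            "%d all-zero rows left unchanged", int((~movable).sum())
        )
    np.divide(new, denom, out=out, where=movable[:, None])
    if clamped:
        idx = [P._prow[p] for p in clamped]
        out[idx] = values[idx]
    return LabelProbabilityMatrix(P.proteins, P.terms, out, P.generation + 1)


def relax(
    net: AssociationNetwork,
    P0: LabelProbabilityMatrix,
    C: CompatibilityMatrix,
    opts: RelaxationOptions | None = None,
    clamped: frozenset[str] | set[str] = frozenset(),
) -> RelaxationResult:
    """Iterate the relaxation update to convergence.

    Unclamped rows of ``P0`` are rescaled to sum to 1 before iterating
    (the voting output is multi-label and need not lie on the simplex);
    clamped rows are kept verbatim.  Stops when the maximum absolute
    change falls below ``opts.tolerance`` or after ``opts.max_iterations``
    generations.
    """
    if opts is None:
        opts = RelaxationOptions()
    P = P0.copy()
    clamped = set(clamped) & set(P.proteins) if opts.clamp_training else set()
    clamp_idx = [P._prow[p] for p in clamped]
    free = np.ones(len(P.proteins), dtype=bool)
    free[clamp_idx] = False
    sums = P.values.sum(axis=1)
    norm = free & (sums > 0)
    P.values[norm] /= sums[norm, None]

    W = _weight_matrix(net, P.proteins)
    max_changes: list[float] = []
    converged = False
    iterations = 0
    for _ in range(opts.max_iterations):
        nxt = update_step(P, C, W, clamped)
        change = float(np.max(np.abs(nxt.values - P.values)))
        max_changes.append(change)
        P = nxt
        iterations += 1
        logger.debug("generation %d: max change %.3e", iterations, change)
        if change < opts.tolerance:
            converged = True
            break
    return RelaxationResult(
        P, iterations, converged, max_changes if opts.record_history else []
    )


def predict(
    net: AssociationNetwork,
    annotations: AnnotationSet,
    C: CompatibilityMatrix,
    hidden: frozenset[str] | set[str] = frozenset(),
    opts: RelaxationOptions | None = None,
) -> tuple[LabelProbabilityMatrix, RelaxationResult]:
    """Full pipeline: voting baseline plus relaxed probabilities.

    Returns the raw weighted-voting matrix (the baseline classifier) and
    the relaxation result.  Training proteins (labelled, not hidden) are
    clamped to their 0/1 indicator rows when ``opts.clamp_training``.
    """
    if opts is None:
        opts = RelaxationOptions()
    if C.terms != list(annotations.terms):
        raise ValueError("compatibility terms differ from the label set")
    baseline = init_probabilities(net, annotations, hidden)
    P0 = baseline.copy()
    training = annotations.labelled_proteins - set(hidden)
    clamped = training & set(P0.proteins) if opts.clamp_training else set()
    tindex = {t: k for k, t in enumerate(P0.terms)}
    for p in clamped:
        row = np.zeros(len(P0.terms))
        for t in annotations.labels(p):
            row[tindex[t]] = 1.0
        P0.values[P0._prow[p]] = row
    result = relax(net, P0, C, opts, clamped)
    return baseline, result
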