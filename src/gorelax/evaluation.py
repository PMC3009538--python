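"""Cross-validated evaluation: per-term ROC AUC and precision/recall.

Labelled proteins are split into k folds by greedy multi-label
stratification so that every fold holds an approximately equal share of
each label.  For each fold, the fold's annotations are hidden, the
weighted-voting and relaxation classifiers are run, and the held-out
predictions are pooled.  Performance is reported as

* per-term AUC (Mann-Whitney rank statistic with 0.5 tie credit) over the
  pooled held-out scores, for both classifiers — plus fold-averaged AUCs;
* micro-averaged precision and recall over a threshold grid: a label is
  predicted when its probability strictly exceeds the threshold, and

      precision = sum_i k_i / sum_i m_i      recall = sum_i k_i / sum_i n_i

  where m_i / n_i / k_i count predicted / known / correctly predicted
  annotations of protein i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .goldstd import AnnotationSet
from .network import AssociationNetwork
from .ontology import CompatibilityMatrix
from .relax import LabelProbabilityMatrix, RelaxationOptions, predict

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.0, 1.0, 101), 2))


@dataclass
class FoldAssignment:
    """Partition of the labelled proteins into k disjoint folds."""

    folds: dict[str, int]
    k: int
    seed: int

    def members(self, fold: int) -> set[str]:
        return {p for p, f in self.folds.items() if f == fold}


def stratified_folds(
    annotations: AnnotationSet, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Greedy multi-label stratification (iterative-stratification style).

    Proteins are processed rarest-label-first; each goes to the fold with
    the largest remaining desire for that label, ties broken by smallest
    fold, then at random (seeded).  Deterministic for a given seed.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    proteins = sorted(annotations.labelled_proteins)
    if len(proteins) < k:
        raise ValueError(f"only {len(proteins)} labelled proteins for {k} folds")
    rng = np.random.default_rng(seed)
    counts = {t: annotations.term_count(t) for t in annotations.terms}
    # desire[f][t]: how many more proteins with label t fold f still wants
    desire = [{t: counts[t] / k for t in counts} for _ in range(k)]
    size_desire = [len(proteins) / k] * k
    remaining = set(proteins)
    assignment: dict[str, int] = {}
    while remaining:
        # rarest label still represented among the unassigned proteins
        label_pool: dict[str, list[str]] = {}
        for p in remaining:
            for t in annotations.labels(p):
                label_pool.setdefault(t, []).append(p)
        if label_pool:
            rare = min(label_pool, key=lambda t: (len(label_pool[t]), t))
            pool = sorted(label_pool[rare])
        else:  # unreachable for labelled proteins, kept for safety
            rare = None
            pool = sorted(remaining)
        order = rng.permutation(len(pool))
        for idx in order:
            p = pool[idx]
            labels = annotations.labels(p)
            scores = []
            for f in range(k):
                want = sum(desire[f][t] for t in labels)
                scores.append((want, size_desire[f], rng.random()))
            best = max(range(k), key=lambda f: scores[f])
            assignment[p] = best
            remaining.discard(p)
            size_desire[best] -= 1
            for t in labels:
                desire[best][t] -= 1
    return FoldAssignment(assignment, k, seed)


def auc(scores, labels) -> float:
    """ROC AUC = P(score of a positive > score of a negative) + 0.5 * ties.

    Raises ``ValueError`` when only one class is present (the statistic is
    undefined; callers report such term/fold combinations as missing).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


@dataclass
class PRPoint:
    threshold: float
    m_total: int  # predicted annotations
    n_total: int  # known annotations
    k_total: int  # correct predictions
    precision: float
    recall: float


def precision_recall(
    P: LabelProbabilityMatrix,
    truth: AnnotationSet,
    thresholds=DEFAULT_THRESHOLDS,
    macro: bool = False,
) -> list[PRPoint]:
    """Micro-averaged precision/recall over a threshold grid.

    A label is assigned when its probability strictly exceeds the
    threshold.  Points with no predictions (m_total = 0) are dropped.
    With ``macro=True``, precision and recall are instead averaged over
    proteins with at least one prediction / known annotation.
    """
    thresholds = sorted(thresholds)
    truth_rows = np.array(
        [[truth.theta(p, t) for t in P.terms] for p in P.proteins], dtype=bool
    )
    points: list[PRPoint] = []
    for thr in thresholds:
        pred = P.values > thr
        correct = pred & truth_rows
        m_tot, n_tot, k_tot = int(pred.sum()), int(truth_rows.sum()), int(correct.sum())
        if m_tot == 0:
            continue
        if macro:
            m_i, n_i, k_i = pred.sum(1), truth_rows.sum(1), correct.sum(1)
            has_pred, has_known = m_i > 0, n_i > 0
            prec = float(np.mean(k_i[has_pred] / m_i[has_pred]))
            rec = float(np.mean(k_i[has_known] / n_i[has_known])) if has_known.any() else 0.0
        else:
            prec = k_tot / m_tot
            rec = k_tot / n_tot if n_tot else 0.0
        points.append(PRPoint(float(thr), m_tot, n_tot, k_tot, prec, rec))
    return points


@dataclass
class EvaluationResult:
    """Pooled cross-validation outputs for the two classifiers."""

    terms: list[str]
    auc_voting: dict[str, float | None]
    auc_relax: dict[str, float | None]
    fold_auc_voting: dict[str, list[float]]
    fold_auc_relax: dict[str, list[float]]
    pr_voting: list[PRPoint]
    pr_relax: list[PRPoint]
    folds: FoldAssignment
    pooled_voting: LabelProbabilityMatrix | None = None
    pooled_relax: LabelProbabilityMatrix | None = None
    n_pos: dict[str, int] = field(default_factory=dict)

    def mean_auc(self, method: str = "relax") -> float:
        d = self.auc_relax if method == "relax" else self.auc_voting
        vals = [v for v in d.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")


def _pooled_auc(
    values: np.ndarray, truth: np.ndarray, terms: list[str]
) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for k, t in enumerate(terms):
        try:
            out[t] = auc(values[:, k], truth[:, k])
        except ValueError:
            logger.warning("term %s has a single class in pooled predictions", t)
            out[t] = None
    return out


def cross_validate(
    net: AssociationNetwork,
    annotations: AnnotationSet,
    C: CompatibilityMatrix,
    k: int = 5,
    seed: int = 0,
    opts: RelaxationOptions | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> EvaluationResult:
    """k-fold cross-validated comparison of voting vs relaxation labelling.

    For each fold the held-out proteins' annotations are hidden from
    initialisation, priors and clamping; their predictions from both
    classifiers are pooled across folds (each labelled protein is held out
    exactly once) before computing per-term AUC and PR curves.  Per-fold
    AUCs are also recorded where both classes are present.
    """
    if C.terms != list(annotations.terms):
        raise ValueError("compatibility terms differ from the label set")
    folds = stratified_folds(annotations, k, seed)
    terms = list(annotations.terms)
    rows_v: dict[str, np.ndarray] = {}
    rows_r: dict[str, np.ndarray] = {}
    fold_auc_v: dict[str, list[float]] = {t: [] for t in terms}
    fold_auc_r: dict[str, list[float]] = {t: [] for t in terms}
    for f in range(k):
        hidden = folds.members(f) & net.proteins
        baseline, result = predict(net, annotations, C, hidden=hidden, opts=opts)
        relaxed = result.probabilities
        truth_f = np.array(
            [[annotations.theta(p, t) for t in terms] for p in sorted(hidden)]
        )
        vals_v = np.array([baseline.row(p) for p in sorted(hidden)])
        vals_r = np.array([relaxed.row(p) for p in sorted(hidden)])
        for p in hidden:
            rows_v[p] = baseline.row(p).copy()
            rows_r[p] = relaxed.row(p).copy()
        for kk, t in enumerate(terms):
            col = truth_f[:, kk]
            if 0 < col.sum() < len(col):
                fold_auc_v[t].append(auc(vals_v[:, kk], col))
                fold_auc_r[t].append(auc(vals_r[:, kk], col))
            else:
                logger.warning("fold %d: term %s single-class, AUC skipped", f, t)

    proteins = sorted(rows_v)
    pooled_v = LabelProbabilityMatrix(
        proteins, terms, np.array([rows_v[p] for p in proteins])
    )
    pooled_r = LabelProbabilityMatrix(
        proteins, terms, np.array([rows_r[p] for p in proteins])
    )
    truth = np.array([[annotations.theta(p, t) for t in terms] for p in proteins])
    held_truth = annotations.restricted_to(proteins)
    return EvaluationResult(
        terms=terms,
        auc_voting=_pooled_auc(pooled_v.values, truth, terms),
        auc_relax=_pooled_auc(pooled_r.values, truth, terms),
        fold_auc_voting=fold_auc_v,
        fold_auc_relax=fold_auc_r,
        pr_voting=precision_recall(pooled_v, held_truth, thresholds),
        pr_relax=precision_recall(pooled_r, held_truth, thresholds),
        folds=folds,
        pooled_voting=pooled_v,
        pooled_relax=pooled_r,
        n_pos={t: int(truth[:, terms.index(t)].sum()) for t in terms},
    )


def auc_table(result: EvaluationResult) -> list[tuple[str, int, float | None, float | None]]:
    """Rows (term, n_pos, auc_voting, auc_relax) for the per-term report."""
    return [
        (t, result.n_pos.get(t, 0), result.auc_voting[t], result.auc_relax[t])
        for t in result.terms
    ]
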