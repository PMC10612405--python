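"""Protein-centric evaluation and hierarchy-consistent post-processing.

Fmax is the CAFA protein-centric metric: for thresholds τ in
{0.01, …, 1.00}, precision is averaged over proteins with at least one
predicted term at τ, recall over proteins with at least one true term, and
Fmax is the maximum harmonic mean over the sweep.  AUC and AUPR are
micro-averaged over all (protein, term) pairs.  Before scoring, predicted
score matrices are made DAG-consistent by propagating each term's maximum
descendant score upward, so parent ≥ child holds on every is_a edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology import GoDag, LabelSpace

THRESHOLDS = np.round(np.arange(0.01, 1.001, 0.01), 2)


@dataclass
class ScoreMatrix:
    """Predicted per-term probabilities for an ordered set of proteins."""

    proteins: list[str]
    space: LabelSpace
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.proteins), len(self.space)):
            raise ValueError("score matrix shape does not match proteins × terms")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")


@dataclass
class EvalReport:
    branch: str
    fmax: float
    fmax_threshold: float
    auc: float
    aupr: float
    per_term_aupr: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "branch": self.branch,
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "auc": self.auc,
            "aupr": self.aupr,
            "per_term_aupr": self.per_term_aupr,
        }, indent=2))


def hierarchical_postprocess(matrix: ScoreMatrix, dag: GoDag) -> ScoreMatrix:
    """Set each term's score to the max over itself and its descendants.

    This never lowers a score, is idempotent, and guarantees
    parent ≥ child on every is_a edge restricted to the label space.
    """
    space = matrix.space
    for t in space.terms:
        if t not in dag.terms:
            raise ValueError(f"term {t} not in DAG")

    depth_cache: dict[str, int] = {}

    def depth(t: str) -> int:
        if t not in depth_cache:
            ps = dag.parents[t]
            depth_cache[t] = 0 if not ps else 1 + max(depth(p) for p in ps)
        return depth_cache[t]

    # running max over the WHOLE DAG (children before parents), so scores
    # flow through intermediate terms that are not part of the label space
    n = len(matrix.proteins)
    work = {
        t: (matrix.scores[:, space.index[t]].copy() if t in space.index
            else np.full(n, -np.inf))
        for t in dag.terms
    }
    for term in sorted(dag.terms, key=lambda t: -depth(t)):
        for parent in dag.parents[term]:
            np.maximum(work[parent], work[term], out=work[parent])
    out = np.stack([work[t] for t in space.terms], axis=1)
    return ScoreMatrix(matrix.proteins, space, out)


def fmax(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """CAFA protein-centric Fmax and the (smallest) threshold achieving it."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same shape")
    has_truth = truth.sum(axis=1) > 0
    if not has_truth.any():
        raise ValueError("no protein has a true term")
    n_with_truth = int(has_truth.sum())
    best_f, best_tau = 0.0, float(THRESHOLDS[0])
    for tau in THRESHOLDS:
        pred = scores >= tau
        n_pred = pred.sum(axis=1)
        covered = n_pred > 0
        if covered.any():
            tp = (pred & (truth > 0)).sum(axis=1)
            precision = float(np.mean(tp[covered] / n_pred[covered]))
        else:
            precision = 0.0
        recall_num = (pred & (truth > 0)).sum(axis=1)[has_truth]
        recall = float(np.mean(recall_num / truth[has_truth].sum(axis=1)))
        if precision + recall > 0:
            f = 2 * precision * recall / (precision + recall)
            if f > best_f + 1e-12:
                best_f, best_tau = f, float(tau)
    return best_f, best_tau


def auc_aupr(scores: np.ndarray, truth: np.ndarray,
             averaging: str = "micro") -> tuple[float, float]:
    """Micro-averaged ROC AUC and area under precision-recall."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    if averaging != "micro":
        raise ValueError("only micro averaging is implemented")
    y = np.asarray(truth).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("truth must contain both classes")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def evaluate(matrix: ScoreMatrix, truth: np.ndarray, dag: GoDag) -> EvalReport:
    """Hierarchy post-processing followed by Fmax / AUC / AUPR.

    Includes a per-term AUPR table (terms with a single class get NaN).
    """
    from sklearn.metrics import average_precision_score

    post = hierarchical_postprocess(matrix, dag)
    f, tau = fmax(post.scores, truth)
    auc, aupr = auc_aupr(post.scores, truth)
    per_term = {}
    for term, j in post.space.index.items():
        col = np.asarray(truth)[:, j]
        if col.min() == col.max():
            per_term[term] = float("nan")
        else:
            per_term[term] = float(average_precision_score(col, post.scores[:, j]))
    return EvalReport(post.space.branch, f, tau, auc, aupr, per_term)


def naive_frequency_baseline(train_truth: np.ndarray, n_proteins: int) -> np.ndarray:
    """Score every term by its training-set frequency for every protein."""
    freq = np.asarray(train_truth, dtype=float).mean(axis=0)
    return np.tile(freq, (n_proteins, 1))


def write_predictions_tsv(matrix: ScoreMatrix, path: str | Path) -> None:
    """CAFA-style predictions: protein_id, term_id, score (3 decimals)."""
    with open(path, "w") as fh:
        for i, pid in enumerate(matrix.proteins):
            for term in matrix.space.terms:
                fh.write(f"{pid}\t{term}\t{matrix.scores[i, matrix.space.index[term]]:.3f}\n")


def read_predictions_tsv(path: str | Path, space: LabelSpace) -> ScoreMatrix:
    rows: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            pid, term, score = line.split()
            rows.setdefault(pid, {})[term] = float(score)
    proteins = sorted(rows)
    mat = np.zeros((len(proteins), len(space)))
    for i, pid in enumerate(proteins):
        for term, sc in rows[pid].items():
            if term in space.index:
                mat[i, space.index[term]] = sc
    return ScoreMatrix(proteins, space, mat)
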