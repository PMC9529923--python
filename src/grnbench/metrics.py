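"""Accuracy protocol for directed network predictions.

Predictions are compared to the gold-standard network on *ordered* gene
pairs: direction counts, sign does not (scores are thresholded on absolute
value).  The selfloop policy makes the comparison fair across method
families: design-based methods estimate selfloops, so they are evaluated on
all N^2 ordered pairs with the diagonal kept in the gold standard;
expression-only methods cannot see selfloops, so the diagonal is removed
from both sides (N^2 - N pairs) rather than charging them false negatives.
An optional ``strip_all`` mode removes the diagonal everywhere (the
sensitivity analysis for the selfloop contribution).

A prediction is swept across sparsity levels — every unique absolute score
is a cutoff for dense outputs, or the 30 penalty networks for sweep outputs
— and each level contributes one (recall, precision, FPR, F1, MCC) point.
AUPR and AUROC are trapezoidal areas over the achieved points: the PR curve
is anchored at recall 0 by extending the sparsest point's precision
horizontally, and the ROC curve is anchored at (0,0) and (1,1).  The
maximum-F1 network (ties broken toward the sparser level) supplies the edge
sets compared across methods via the Jaccard index and the true fraction of
their overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .networks import Network
from .pbased import ScoredGRN

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "apply_selfloop_policy",
    "threshold_sweep",
    "confusion",
    "precision",
    "recall",
    "tpr",
    "fpr",
    "f1",
    "mcc",
    "aupr",
    "auroc",
    "evaluate",
    "jaccard",
    "true_fraction",
    "group_significance",
]

logger = logging.getLogger(__name__)

Edge = tuple[int, int]  # (target, regulator)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def recall(c: ConfusionCounts) -> float:
    """TPR = TP / (TP + FN); 0 when there are no gold edges."""
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0


tpr = recall


def fpr(c: ConfusionCounts) -> float:
    """FP / (FP + TN); 0 when there are no gold non-edges."""
    return c.fp / (c.fp + c.tn) if (c.fp + c.tn) else 0.0


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); an empty prediction makes no false claims -> 1."""
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 1.0


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 by convention when any marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom))


def confusion(
    gold_edges: frozenset[Edge] | set[Edge],
    predicted_edges: frozenset[Edge] | set[Edge],
    evaluated_pair_count: int,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN for edge sets over a fixed universe of ordered pairs."""
    gold = set(gold_edges)
    pred = set(predicted_edges)
    tp = len(pred & gold)
    fp = len(pred - gold)
    fn = len(gold - pred)
    tn = evaluated_pair_count - tp - fp - fn
    if tn < 0:
        raise ValueError("edge sets exceed the evaluated pair universe")
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def apply_selfloop_policy(
    gold: Network, predicted: ScoredGRN, mode: str = "policy"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Gold edge indicator, evaluated-pair mask, and pair count for a prediction.

    ``mode='policy'``: design-based predictions keep the diagonal (N^2
    pairs), expression-only ones drop it from both gold and prediction
    (N^2 - N pairs).  ``mode='strip_all'``: diagonal dropped everywhere.
    """
    n = gold.n_genes
    if predicted.n_genes != n:
        raise ValueError("gold network and prediction have different gene sets")
    if mode not in ("policy", "strip_all"):
        raise ValueError("selfloop mode must be 'policy' or 'strip_all'")
    include_diag = mode == "policy" and predicted.category == "p_based"
    mask = np.ones((n, n), dtype=bool)
    if not include_diag:
        mask &= ~np.eye(n, dtype=bool)
    gold_bool = (gold.weights != 0) & mask
    return gold_bool, mask, int(mask.sum())


def threshold_sweep(
    predicted: ScoredGRN, mask: np.ndarray | None = None
) -> list[np.ndarray]:
    """Binary networks at every unique absolute score, sparsest to densest.

    An edge enters a level iff ``|score| >= cutoff``; tied scores enter
    together.  Sweep-typed predictions pass their penalty networks through
    (reordered sparsest-first).  Intended for inspection and small cases —
    :func:`evaluate` computes the same curve without materializing the
    networks.
    """
    n = predicted.n_genes
    if mask is None:
        mask = np.ones((n, n), dtype=bool)
    if predicted.sweep is not None:
        return [net & mask for net in reversed(predicted.sweep)]
    scores = np.abs(predicted.dense_weights)
    values = np.unique(scores[mask])[::-1]
    if values.size == 0 or (values[0] == 0 and values.size == 1):
        logger.warning("all-zero prediction; sweep is a single empty network")
        return [np.zeros((n, n), dtype=bool)]
    return [(scores >= v) & mask for v in values]


def _curve_counts(
    gold_bool: np.ndarray, mask: np.ndarray, predicted: ScoredGRN
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Per-level (tp, fp) arrays sparsest->densest, plus dense cutoffs if any."""
    if predicted.sweep is not None:
        tp, fp = [], []
        for net in reversed(predicted.sweep):
            sel = net & mask
            tp.append(int((sel & gold_bool).sum()))
            fp.append(int((sel & ~gold_bool).sum()))
        return np.asarray(tp), np.asarray(fp), None
    scores = np.abs(predicted.dense_weights[mask])
    gold_flat = gold_bool[mask]
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    cum_tp = np.cumsum(gold_flat[order])
    # last index of each tied block of scores, descending
    boundaries = np.nonzero(np.diff(sorted_scores))[0]
    last = np.append(boundaries, scores.size - 1)
    tp = cum_tp[last]
    fp = (last + 1) - tp
    return tp, fp, sorted_scores[last]


def _vector_mcc(tp, fp, tn, fn):
    tp, fp, tn, fn = (x.astype(float) for x in (tp, fp, tn, fn))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (tp * tn - fp * fn) / denom
    return np.where(denom > 0, out, 0.0)


def aupr(recall_pts: np.ndarray, precision_pts: np.ndarray) -> float:
    """Trapezoidal PR area over achieved points (sparsest first).

    The curve is anchored at recall 0 by extending the sparsest achieved
    precision horizontally; no unachieved endpoint is fabricated on the
    dense side.
    """
    r = np.concatenate([[0.0], recall_pts])
    p = np.concatenate([[precision_pts[0]], precision_pts])
    order = np.argsort(r, kind="stable")
    return float(np.trapezoid(p[order], r[order]))


def auroc(fpr_pts: np.ndarray, tpr_pts: np.ndarray) -> float:
    """Trapezoidal ROC area with (0,0) and (1,1) anchors."""
    x = np.concatenate([[0.0], fpr_pts, [1.0]])
    y = np.concatenate([[0.0], tpr_pts, [1.0]])
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


@dataclass
class EvaluationResult:
    """Sparsity-sweep accuracy summary for one prediction vs one gold network.

    Point arrays run sparsest to densest.  ``max_f1_edges`` is the directed
    edge set (target, regulator pairs) of the F1-maximizing level.
    """

    method_name: str
    n_evaluated: int
    n_gold: int
    recall: np.ndarray
    precision: np.ndarray
    fpr: np.ndarray
    f1: np.ndarray
    mcc: np.ndarray
    aupr: float
    auroc: float
    max_f1: float
    max_mcc: float
    max_f1_edges: frozenset[Edge]
    cutoffs: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def prevalence(self) -> float:
        return self.n_gold / self.n_evaluated if self.n_evaluated else 0.0

    def summary(self) -> dict:
        return {
            "method": self.method_name,
            "aupr": self.aupr,
            "auroc": self.auroc,
            "max_f1": self.max_f1,
            "max_mcc": self.max_mcc,
            "n_evaluated": self.n_evaluated,
            "n_gold": self.n_gold,
            "n_sweep_points": int(self.recall.size),
            "n_max_f1_edges": len(self.max_f1_edges),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "recall": self.recall,
                "precision": self.precision,
                "fpr": self.fpr,
                "f1": self.f1,
                "mcc": self.mcc,
            }
        )


def evaluate(
    gold: Network, predicted: ScoredGRN, selfloop_mode: str = "policy"
) -> EvaluationResult:
    """Full sparsity-sweep evaluation of a prediction against a gold network."""
    gold_bool, mask, n_pairs = apply_selfloop_policy(gold, predicted, selfloop_mode)
    n_gold = int(gold_bool.sum())
    n_neg = n_pairs - n_gold
    tp, fp, cutoffs = _curve_counts(gold_bool, mask, predicted)
    fn = n_gold - tp
    tn = n_neg - fp

    rec = tp / n_gold if n_gold else np.zeros_like(tp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    fprs = fp / n_neg if n_neg else np.zeros_like(fp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1s = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
    mccs = _vector_mcc(tp, fp, tn, fn)

    # ties in F1 resolved toward the sparser level (first index at the max)
    first_best = int(np.flatnonzero(f1s == f1s.max())[0])
    if predicted.sweep is not None:
        nets = list(reversed(predicted.sweep))
        best_edges_mask = nets[first_best] & mask
    else:
        best_edges_mask = (np.abs(predicted.dense_weights) >= cutoffs[first_best]) & mask
    rows, cols = np.nonzero(best_edges_mask)
    max_f1_edges = frozenset(zip(rows.tolist(), cols.tolist()))

    return EvaluationResult(
        method_name=predicted.method_name,
        n_evaluated=n_pairs,
        n_gold=n_gold,
        recall=rec.astype(float),
        precision=prec.astype(float),
        fpr=fprs.astype(float),
        f1=f1s.astype(float),
        mcc=mccs.astype(float),
        aupr=aupr(rec, prec),
        auroc=auroc(fprs, rec),
        max_f1=float(f1s[first_best]),
        max_mcc=float(mccs.max()) if mccs.size else 0.0,
        max_f1_edges=max_f1_edges,
        cutoffs=cutoffs,
        extra={"category": predicted.category},
    )


def jaccard(edges_a: frozenset[Edge], edges_b: frozenset[Edge]) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets count as identical (1, logged)."""
    a, b = set(edges_a), set(edges_b)
    union = a | b
    if not union:
        logger.info("Jaccard of two empty edge sets taken as 1 by convention")
        return 1.0
    return len(a & b) / len(union)


def true_fraction(
    edges_a: frozenset[Edge], edges_b: frozenset[Edge], gold_edges: frozenset[Edge]
) -> float | None:
    """Portion of the A∩B overlap present in the gold network; None if no overlap."""
    overlap = set(edges_a) & set(edges_b)
    if not overlap:
        return None
    return len(overlap & set(gold_edges)) / len(overlap)


def group_significance(values_a, values_b) -> float:
    """Two-sided Mann–Whitney U p-value comparing two accuracy samples."""
    return float(stats.mannwhitneyu(values_a, values_b, alternative="two-sided").pvalue)
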