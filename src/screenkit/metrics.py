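"""Residue-level prediction metrics and the spatial-cohesion analysis.

AUC uses the Mann–Whitney pairwise formulation with tie correction; AUPR
uses step-interpolated precision-recall integration (precision envelope,
equivalent to average precision). Confusion-based metrics pool residues
across enzymes (micro aggregation) by default; macro (per-enzyme mean)
variants are available and every report labels which was used.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .types import PredictionSet

__all__ = ["threshold_metrics", "best_f1", "rank_metrics",
           "distance_to_nearest_catalytic", "summarize_distances",
           "evaluate_predictions"]


def _confusion(scores, labels, t):
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, fn


def _prf(tp, fp, fn):
    flags = {}
    if tp + fp == 0:
        precision, flags["precision_undefined"] = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, flags["recall_undefined"] = 0.0, True
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else \
        2 * precision * recall / (precision + recall)
    return precision, recall, f1, flags


def threshold_metrics(preds: PredictionSet, t: float) -> dict:
    """Precision/recall/F1 at a fixed threshold, micro-pooled over enzymes.

    Undefined ratios (empty denominator) are reported as 0 with a flag.
    """
    if not 0 <= t <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    scores, labels = preds.pooled()
    p, r, f1, flags = _prf(*_confusion(scores, labels, t))
    return {"threshold": t, "precision": p, "recall": r, "f1": f1,
            "aggregation": "micro", **flags}


def best_f1(preds: PredictionSet):
    """Maximum F1 over all thresholds in the observed score set (plus
    endpoints 0 and 1); ties broken toward the lower threshold.

    Returns (best_f1, threshold).
    """
    scores, labels = preds.pooled()
    if labels.min() == labels.max():
        raise ValueError("best_f1 needs both classes present")
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    best, best_t = -1.0, 0.0
    for t in candidates:  # ascending, so '>' keeps the lowest tied threshold
        _, _, f1, _ = _prf(*_confusion(scores, labels, t))
        if f1 > best:
            best, best_t = f1, float(t)
    return best, best_t


def rank_metrics(preds: PredictionSet) -> dict:
    """Threshold-free metrics: AUC (Mann–Whitney with tie correction) and
    AUPR (step-wise average precision)."""
    scores, labels = preds.pooled()
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rank metrics need both classes present")

    ranks = rankdata(scores)  # midranks handle ties -> 0.5 credit per tie
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # Step-interpolated precision-recall integral: sum over positives, in
    # descending-score order, of precision at each recall increment.
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # Ties share one threshold: keep only the last index of each tied block.
    last_of_block = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    precision = precision[last_of_block]
    recall = recall[last_of_block]
    recall_prev = np.r_[0.0, recall[:-1]]
    aupr = float(np.sum((recall - recall_prev) * precision))
    return {"auc": float(auc), "aupr": aupr, "n_pos": n_pos, "n_neg": n_neg}


def distance_to_nearest_catalytic(coords: np.ndarray, mask, subset=None
                                  ) -> np.ndarray:
    """Distance from each subset residue to the nearest catalytic residue.

    Catalytic residues measure the distance to the nearest *other*
    catalytic residue (self excluded) so the cohesion of the site itself
    is measurable. Residues with no eligible target (the sole catalytic
    residue) are omitted from the output.
    """
    coords = np.asarray(coords, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("no catalytic residues in mask")
    if subset is None:
        subset = np.ones(len(mask), dtype=bool)
    subset = np.asarray(subset, dtype=bool)
    cat_idx = np.nonzero(mask)[0]
    d = cdist(coords[subset], coords[cat_idx])
    # Exclude self-distance for subset residues that are catalytic.
    sub_idx = np.nonzero(subset)[0]
    for row, i in enumerate(sub_idx):
        self_col = np.nonzero(cat_idx == i)[0]
        if self_col.size:
            d[row, self_col[0]] = np.inf
    out = d.min(axis=1)
    return out[np.isfinite(out)]


def summarize_distances(distances_per_enzyme) -> dict:
    """Pooled median and quartiles (linear interpolation) across enzymes."""
    pooled = np.concatenate([np.asarray(d, dtype=float)
                             for d in distances_per_enzyme if len(d)])
    if pooled.size == 0:
        raise ValueError("no distances to summarize")
    q1, med, q3 = np.percentile(pooled, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "n": int(pooled.size)}


def evaluate_predictions(preds: PredictionSet, threshold: float = 0.5) -> dict:
    """Full metrics report: fixed-threshold P/R/F1, Best-F1, AUC, AUPR."""
    report = threshold_metrics(preds, threshold)
    bf1, bt = best_f1(preds)
    report.update(rank_metrics(preds))
    report["best_f1"] = bf1
    report["best_f1_threshold"] = bt
    return report
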