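"""Mutation-tolerance triage from deep mutational scanning (MAVE) data.

Variant functional scores are binarized into wild-type-like (WTL) and
functional-loss (FL) calls at the intersection of the first and last
components of a 3-Gaussian mixture fitted to the score distribution. A
shallow decision tree over two structure-derived features — distance to
the nearest predicted catalytic residue and relative solvent
accessibility — then predicts each residue's class.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.metrics import make_scorer, precision_score
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold, cross_validate
from sklearn.tree import DecisionTreeClassifier

from .metrics import distance_to_nearest_catalytic
from .types import EnzymeRecord, VariantTable

__all__ = ["gaussian_cutoff", "classify_variants", "triage_features",
           "fit_triage_tree", "read_variant_table"]

WTL, FL = "WTL", "FL"


def gaussian_cutoff(scores, n_restarts: int = 10, tol: float = 1e-6,
                    seed: int = 0) -> float:
    """Classification cutoff from a 3-component Gaussian mixture.

    Fits k=3 univariate Gaussians by EM (seeded restarts), orders the
    components by mean, and returns the point between the first and last
    components' means where their weighted densities are equal.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size < 50:
        raise ValueError("gaussian_cutoff needs >= 50 scores")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate score distribution (all identical)")
    gm = GaussianMixture(n_components=3, n_init=n_restarts, tol=tol,
                         random_state=seed, max_iter=500)
    gm.fit(scores[:, None])
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge after {n_restarts} restarts "
            f"(lower bound {gm.lower_bound_:.4g})")
    order = np.argsort(gm.means_.ravel())
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.ravel()[order])
    w = gm.weights_.ravel()[order]

    def density_gap(x):
        return (w[0] * norm.pdf(x, mu[0], sd[0])
                - w[2] * norm.pdf(x, mu[2], sd[2]))

    lo, hi = mu[0], mu[2]
    if density_gap(lo) * density_gap(hi) > 0:
        raise RuntimeError(
            f"no density intersection between component means "
            f"({lo:.3g}, {hi:.3g}); mixture may be degenerate")
    return float(brentq(density_gap, lo, hi))


def classify_variants(table: VariantTable, cutoff: float):
    """Per-variant and per-residue WTL/FL calls.

    A variant is WTL iff its (orientation-normalized) score is >= cutoff.
    A residue's class is the majority vote over its variants; ties break
    to FL (conservative toward flagging functional loss).

    Returns (per_variant_calls, per_residue_calls) where the latter maps
    residue number -> "WTL"/"FL".
    """
    if table.higher_is_active is None:
        raise ValueError(
            "score orientation unknown: set higher_is_active on the table")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = table.scores if table.higher_is_active else -table.scores
    cut = cutoff if table.higher_is_active else -cutoff
    variant_calls = [WTL if s >= cut else FL for s in scores]

    residue_calls = {}
    for rn in dict.fromkeys(table.residue_numbers):  # preserve order
        calls = [c for r, c in zip(table.residue_numbers, variant_calls)
                 if r == rn]
        n_wtl = sum(c == WTL for c in calls)
        residue_calls[rn] = WTL if n_wtl > len(calls) - n_wtl else FL
    return variant_calls, residue_calls


def triage_features(record: EnzymeRecord, predicted_catalytic,
                    sasa_relative) -> np.ndarray:
    """Per-residue feature pairs (distance to nearest predicted catalytic
    residue in Å, relative solvent accessibility), shape n x 2.

    Predicted catalytic residues themselves get distance 0.
    """
    mask = np.asarray(predicted_catalytic, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("prediction mask has no catalytic residues")
    sasa_relative = np.asarray(sasa_relative, dtype=float)
    n = record.n_residues
    if mask.shape != (n,) or sasa_relative.shape != (n,):
        raise ValueError("mask/sasa lengths must match the record")
    dist = np.zeros(n)
    non_pred = ~mask
    if non_pred.any():
        dist[non_pred] = distance_to_nearest_catalytic(
            record.ca_coords, mask, subset=non_pred)
    return np.column_stack([dist, sasa_relative])


def fit_triage_tree(features, residue_classes, max_depth: int = 3,
                    n_folds: int = 5, seed: int = 0):
    """Depth-limited decision tree over the 2 triage features with
    stratified seeded cross-validation.

    ``residue_classes`` is a sequence of "WTL"/"FL" strings (or 0/1 with
    1 = FL). Returns (fitted tree, report dict) with mean CV accuracy and
    precision (FL treated as the positive class) plus full-training-set
    accuracy.
    """
    X = np.asarray(features, dtype=float)
    y = np.array([1 if c in (FL, 1) else 0 for c in residue_classes])
    if len(np.unique(y)) < 2:
        raise ValueError("triage tree needs both WTL and FL residues")
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_validate(
        tree, X, y, cv=cv,
        scoring={"accuracy": "accuracy",
                 "precision": make_scorer(precision_score, zero_division=0)})
    tree.fit(X, y)
    report = {
        "cv_accuracy": float(scores["test_accuracy"].mean()),
        "cv_accuracy_sd": float(scores["test_accuracy"].std()),
        "cv_precision": float(scores["test_precision"].mean()),
        "train_accuracy": float(tree.score(X, y)),
        "n_folds": n_folds,
        "max_depth": max_depth,
        "positive_class": FL,
    }
    return tree, report


def read_variant_table(tsv_path, orientation: bool = None,
                       provenance: str = "") -> VariantTable:
    """Read a variant TSV (residue_number, wildtype, substitution, score).

    ``orientation`` (higher score = more active) usually comes from the
    YAML sidecar written next to the table.
    """
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t", dtype={"residue_number": str})
    required = {"residue_number", "wildtype", "substitution", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{tsv_path}: missing columns {sorted(missing)}")
    return VariantTable(
        residue_numbers=df["residue_number"].tolist(),
        wildtype=df["wildtype"].tolist(),
        substitution=df["substitution"].tolist(),
        scores=df["score"].to_numpy(dtype=float),
        higher_is_active=orientation,
        provenance=provenance,
    )
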