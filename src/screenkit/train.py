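"""Contrastive-then-supervised training.

Early epochs pull pooled enzyme representations toward their enzyme-class
(EC first level) cluster center and away from a randomly drawn other-class
center via the hinged Triplet Margin Loss (margin alpha = 1). The mixing
weight lambda decays linearly from 1 to 0 over the first configured
fraction of epochs (default 30%), after which training is pure
class-weighted cross-entropy on the per-residue catalytic labels.

Cluster centers are recomputed every epoch from cached pooled
representations and treated as constants in the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .model import ModelConfig, ScreenModel, pool_sequence
from .types import ResidueGraph

__all__ = ["TrainConfig", "TrainState", "triplet_margin_loss",
           "update_cluster_centers", "sample_triplet", "lambda_schedule",
           "train"]


def triplet_margin_loss(za, zp, zn, alpha: float = 1.0,
                        hinge: bool = True) -> float:
    """max(0, ||za - zp||_2 - ||za - zn||_2 + alpha) on plain vectors."""
    za = np.asarray(za, dtype=float).ravel()
    zp = np.asarray(zp, dtype=float).ravel()
    zn = np.asarray(zn, dtype=float).ravel()
    if not (za.shape == zp.shape == zn.shape):
        raise ValueError("triplet vectors must share one dimension")
    if alpha < 0:
        raise ValueError("margin must be >= 0")
    raw = np.linalg.norm(za - zp) - np.linalg.norm(za - zn) + alpha
    return float(max(0.0, raw)) if hinge else float(raw)


def update_cluster_centers(embeddings: dict, classes: dict) -> dict:
    """Per-class arithmetic mean of member pooled representations.

    ``embeddings`` maps enzyme id -> (d,) or (1, d) vector; ``classes``
    maps enzyme id -> EC class.
    """
    if not embeddings:
        raise ValueError("no embeddings to cluster")
    groups: dict[int, list] = {}
    for eid, vec in embeddings.items():
        groups.setdefault(classes[eid], []).append(np.asarray(vec).ravel())
    return {c: np.mean(vs, axis=0) for c, vs in groups.items()}


def sample_triplet(anchor_class: int, centers: dict, rng) -> tuple:
    """Positive = anchor's class center; negative drawn uniformly among
    the other classes' centers."""
    if anchor_class not in centers:
        raise ValueError(f"no center for class {anchor_class}")
    others = sorted(c for c in centers if c != anchor_class)
    if not others:
        raise ValueError(
            "contrastive sampling needs >= 2 enzyme classes; disable the "
            "contrastive phase for single-class datasets")
    zn_class = others[rng.integers(len(others))]
    return centers[anchor_class], centers[zn_class]


def lambda_schedule(epoch: int, epochs: int, fraction: float) -> float:
    """Linear decay from 1 at epoch 0 to 0 at epoch ceil(fraction*epochs)."""
    if fraction <= 0:
        return 0.0
    boundary = fraction * epochs
    return float(max(0.0, 1.0 - epoch / boundary))


@dataclass
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2              # decoupled (AdamW), weights only
    contrastive_fraction: float = 0.3     # share of epochs spent mixing in L_TM
    validation_fraction: float = 0.0      # enzymes held out for model selection
    margin: float = 1.0                   # triplet margin alpha
    hinge: bool = True
    pos_weight: float = None              # None -> inverse catalytic prevalence
    seed: int = 0
    use_contrastive: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class TrainState:
    epoch: int = 0
    phase_weight: float = 1.0
    cluster_centers: dict = field(default_factory=dict)
    history: list = field(default_factory=list)


class Adam:
    """Adam with decoupled weight decay (AdamW); decay skips biases."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k.endswith(".w"):
                p.data -= self.lr * self.weight_decay * p.data


def _class_weights(dataset, pos_weight):
    if pos_weight is None:
        pos = sum(int(g.labels.sum()) for g in dataset)
        total = sum(g.n_residues for g in dataset)
        neg = total - pos
        pos_weight = neg / max(pos, 1)
    return np.array([1.0, float(pos_weight)])


def train(dataset: list, config: TrainConfig = None,
          model: ScreenModel = None, callback=None):
    """Train on a list of labeled ResidueGraphs.

    Returns (model, TrainState); the state's ``history`` holds one dict
    per epoch with the lambda value and the mean contrastive and
    supervised loss components. ``callback(model, state)``, if given, is
    invoked after every epoch.

    With ``config.validation_fraction > 0`` a deterministic slice of the
    training enzymes is held out; after the contrastive phase the model
    with the best validation AUPR is kept (early stopping by model
    selection), and each history row records the validation AUPR.
    """
    config = config or TrainConfig()
    if not dataset:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model_cfg = config.model
        model_cfg.seed = config.seed
        model = ScreenModel(model_cfg)

    contrastive_on = config.use_contrastive
    classes = {g.id: g.ec_class for g in dataset}
    if contrastive_on:
        present = {c for c in classes.values() if c is not None}
        if len(present) < 2:
            raise ValueError(
                "contrastive phase needs >= 2 enzyme classes; set "
                "use_contrastive=False for single-class datasets")

    # optional deterministic validation split for early stopping
    val_set = []
    if config.validation_fraction > 0:
        split_rng = np.random.default_rng(config.seed)
        n_val = max(1, int(round(config.validation_fraction * len(dataset))))
        val_idx = set(split_rng.choice(len(dataset), n_val, replace=False))
        val_set = [g for i, g in enumerate(dataset) if i in val_idx]
        dataset = [g for i, g in enumerate(dataset) if i not in val_idx]
        if not dataset:
            raise ValueError("validation split left no training enzymes")

    weights = _class_weights(dataset, config.pos_weight)
    opt = Adam(model.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    state = TrainState()
    best_val, best_params = -np.inf, None

    # Initial pooled representations for the first epoch's cluster centers.
    z_cache = {}
    if contrastive_on:
        for g in dataset:
            z_cache[g.id] = model.sequence_embedding(g).ravel()

    order = np.arange(len(dataset))
    for epoch in range(config.epochs):
        lam = lambda_schedule(epoch, config.epochs,
                              config.contrastive_fraction)
        if not contrastive_on:
            lam = 0.0
        state.epoch, state.phase_weight = epoch, lam
        if contrastive_on and lam > 0:
            state.cluster_centers = update_cluster_centers(z_cache, classes)

        rng.shuffle(order)
        sup_losses, con_losses = [], []
        for idx in order:
            g = dataset[idx]
            model.zero_grad()
            logits, xe = model.forward(g)
            l_sup = ag.softmax_cross_entropy(logits, g.labels, weights)
            terms = [(1.0 - lam, l_sup)]
            if lam > 0:
                za = ag.mean_rows(xe)
                zp, zn = sample_triplet(g.ec_class, state.cluster_centers, rng)
                l_con = ag.triplet_margin(za, zp, zn, alpha=config.margin,
                                          hinge=config.hinge)
                terms.append((lam, l_con))
                con_losses.append(float(l_con.data))
                z_cache[g.id] = za.data.ravel().copy()
            elif contrastive_on:
                z_cache[g.id] = pool_sequence(xe.data).ravel()
            total = ag.weighted_sum(terms)
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, enzyme {g.id}; "
                    f"state: lambda={lam}, history={state.history[-3:]}")
            total.backward()
            opt.step()
            sup_losses.append(float(l_sup.data))

        row = {
            "epoch": epoch,
            "lambda": lam,
            "loss_supervised": float(np.mean(sup_losses)),
            "loss_contrastive":
                float(np.mean(con_losses)) if con_losses else 0.0,
        }
        if val_set and lam == 0.0:
            from .metrics import rank_metrics
            from .types import PredictionSet
            val_preds = PredictionSet(
                [model.predict_propensities(g) for g in val_set],
                [g.labels for g in val_set])
            row["val_aupr"] = rank_metrics(val_preds)["aupr"]
            if row["val_aupr"] > best_val:
                best_val = row["val_aupr"]
                best_params = {k: t.data.copy()
                               for k, t in model.params.items()}
        state.history.append(row)
        if callback is not None:
            callback(model, state)

    if best_params is not None:
        for k, t in model.params.items():
            t.data = best_params[k]
    return model, state
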