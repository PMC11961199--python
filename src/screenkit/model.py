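"""The catalytic-residue network: a three-layer graph convolution over the
residue contact graph, concatenation of the per-layer representations,
MLP fusion with the language-model embedding branch, and a fully-connected
head producing a two-channel residue output.

Message passing uses the symmetric renormalized propagation operator
S = D̃^{-1/2} (A + I) D̃^{-1/2} with self-loops; the GCN consumes the
evolutionary + atomic block [X_L, X_A] (width 64), and the embedding block
X_G joins only at the fusion stage:

    H(0) = [X_L, X_A]
    H(i) = ReLU(S H(i-1) W(i)),  i = 1..3
    XE   = ReLU(W_f [ ReLU(W_g [H1,H2,H3] + b_g), ReLU(W_e X_G + b_e) ] + b_f)
    Y    = W_2 ReLU(W_1 XE + b_1) + b_2          (n x 2 logits)

Softmax over the two channels turns the logits into catalytic propensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .types import ResidueGraph, GCN_INPUT_WIDTH, EMBED_WIDTH

__all__ = ["ModelConfig", "ScreenModel", "normalized_adjacency",
           "pool_sequence"]


def normalized_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric renormalized propagation matrix S = D̃^{-1/2}(A+I)D̃^{-1/2}.

    ``a`` must be a symmetric binary matrix with zero diagonal. The
    self-loop guarantees every degree is >= 1, so S is well defined.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def pool_sequence(xe: np.ndarray) -> np.ndarray:
    """Average-pool residue representations into one sequence vector (1 x d)."""
    xe = np.asarray(xe, dtype=float)
    if xe.ndim != 2 or xe.shape[0] < 1:
        raise ValueError("pooling requires a nonempty n x d matrix")
    return xe.mean(axis=0, keepdims=True)


@dataclass
class ModelConfig:
    theta: int = GCN_INPUT_WIDTH            # GCN input width (50 + 14)
    gcn_dims: tuple = (256, 256, 256)       # d1, d2, d3
    fusion_dim: int = 512                   # d, width of XE
    embed_dim: int = EMBED_WIDTH            # h1
    head_hidden: int = 128
    seed: int = 0

    def to_dict(self):
        d = asdict(self)
        d["gcn_dims"] = list(self.gcn_dims)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["gcn_dims"] = tuple(d["gcn_dims"])
        return cls(**d)


def _init_linear(rng, fan_in, fan_out):
    """Uniform fan-based initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=fan_out)
    return w, b


class ScreenModel:
    """GCN + fusion-MLP catalytic residue predictor.

    Parameters live in ``self.params`` (name -> Tensor with gradients).
    ``init="uniform"`` draws fan-scaled uniform weights from the config
    seed; ``init="zeros"`` gives the all-zero model whose propensities are
    exactly 0.5 everywhere (useful as a null reference).
    """

    def __init__(self, config: ModelConfig = None, init: str = "uniform"):
        self.config = config or ModelConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        shapes = {}
        prev = c.theta
        for i, d in enumerate(c.gcn_dims, start=1):
            shapes[f"gcn{i}"] = (prev, d)
            prev = d
        concat_width = sum(c.gcn_dims)
        shapes["graph_mlp"] = (concat_width, c.fusion_dim)
        shapes["embed_mlp"] = (c.embed_dim, c.fusion_dim)
        shapes["fuse"] = (2 * c.fusion_dim, c.fusion_dim)
        shapes["head1"] = (c.fusion_dim, c.head_hidden)
        shapes["head2"] = (c.head_hidden, 2)

        self.params: dict[str, Tensor] = {}
        for name, (fi, fo) in shapes.items():
            if init == "zeros":
                w, b = np.zeros((fi, fo)), np.zeros(fo)
            else:
                w, b = _init_linear(rng, fi, fo)
            self.params[f"{name}.w"] = Tensor(w, requires_grad=True)
            self.params[f"{name}.b"] = Tensor(b, requires_grad=True)

    # -- forward pieces -------------------------------------------------

    def _linear(self, name, x: Tensor) -> Tensor:
        return ag.add_bias(ag.matmul(x, self.params[f"{name}.w"]),
                           self.params[f"{name}.b"])

    def gcn_forward(self, graph: ResidueGraph):
        """Three propagation layers; returns (H1, H2, H3) as Tensors."""
        h0 = graph.gcn_input
        if h0.shape[1] != self.config.theta:
            raise ValueError(
                f"feature width {h0.shape[1]} does not match the model's "
                f"GCN input width {self.config.theta}")
        s = Tensor(normalized_adjacency(graph.adjacency))
        h = Tensor(h0)
        outs = []
        for i in range(1, len(self.config.gcn_dims) + 1):
            h = ag.relu(self._linear(f"gcn{i}", ag.matmul(s, h)))
            outs.append(h)
        return tuple(outs)

    def fuse_and_score(self, h1: Tensor, h2: Tensor, h3: Tensor,
                       x_g: np.ndarray):
        """Fuse graph layers with the embedding branch; return (logits, XE)."""
        ns = {t.shape[0] for t in (h1, h2, h3)} | {np.asarray(x_g).shape[0]}
        if len(ns) != 1:
            raise ValueError("row counts of graph layers and embedding disagree")
        graph_branch = ag.relu(self._linear("graph_mlp", ag.concat([h1, h2, h3])))
        embed_branch = ag.relu(self._linear("embed_mlp", Tensor(x_g)))
        xe = ag.relu(self._linear("fuse", ag.concat([graph_branch, embed_branch])))
        hidden = ag.relu(self._linear("head1", xe))
        logits = self._linear("head2", hidden)
        return logits, xe

    def forward(self, graph: ResidueGraph):
        """Full forward pass; returns (logits Tensor n x 2, XE Tensor n x d)."""
        h1, h2, h3 = self.gcn_forward(graph)
        return self.fuse_and_score(h1, h2, h3, graph.x_g)

    # -- inference ------------------------------------------------------

    def predict_propensities(self, graph: ResidueGraph) -> np.ndarray:
        """Per-residue catalytic propensity in [0, 1] (softmax channel 1)."""
        logits, _ = self.forward(graph)
        z = logits.data
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        return p[:, 1]

    def sequence_embedding(self, graph: ResidueGraph) -> np.ndarray:
        """Pooled sequence representation z (1 x d)."""
        _, xe = self.forward(graph)
        return pool_sequence(xe.data)

    # -- parameter plumbing ---------------------------------------------

    def zero_grad(self):
        for t in self.params.values():
            t.zero_grad()

    def save(self, path) -> None:
        """Write weights (npz) plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **{k: v.data for k, v in self.params.items()})
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.config.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ScreenModel":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        config = ModelConfig.from_dict(json.loads(sidecar.read_text()))
        model = cls(config, init="zeros")
        with np.load(path, allow_pickle=False) as z:
            for k in model.params:
                if k not in z.files:
                    raise ValueError(f"checkpoint missing parameter {k}; "
                                     f"see sidecar {sidecar}")
                model.params[k].data = z[k].astype(float)
        return model
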