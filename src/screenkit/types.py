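"""Core domain containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np


class Atom(NamedTuple):
    element: str          # heavy-atom element symbol, upper case
    name: str             # PDB atom name (e.g. "CA", "OD1")
    coords: tuple         # (x, y, z) in Å
    b_factor: float
    is_sidechain: bool


@dataclass
class EnzymeRecord:
    """One enzyme chain at residue resolution.

    ``residue_numbers`` keeps author numbering (with insertion codes) as
    strings; they are the join key against label and variant tables.
    Internal indexing is 0-based positional.
    """

    id: str
    sequence: str
    residue_numbers: list[str]
    ca_coords: np.ndarray                 # (n, 3) float
    atoms: list[list[Atom]]               # per-residue heavy atoms
    catalytic_mask: np.ndarray = None     # (n,) uint8
    ec_class: Optional[int] = None

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        n = len(self.sequence)
        if self.catalytic_mask is None:
            self.catalytic_mask = np.zeros(n, dtype=np.uint8)
        self.catalytic_mask = np.asarray(self.catalytic_mask, dtype=np.uint8)
        self.validate()

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        if not (len(self.residue_numbers) == n == self.ca_coords.shape[0]
                == len(self.catalytic_mask) == len(self.atoms)):
            raise ValueError(
                f"{self.id}: inconsistent lengths (sequence {n}, "
                f"residue_numbers {len(self.residue_numbers)}, "
                f"ca_coords {self.ca_coords.shape[0]}, "
                f"mask {len(self.catalytic_mask)}, atoms {len(self.atoms)})")
        if self.ca_coords.shape != (n, 3):
            raise ValueError(f"{self.id}: ca_coords must be (n, 3)")
        if any(len(a) == 0 for a in self.atoms):
            raise ValueError(f"{self.id}: every residue needs >= 1 atom")
        if self.ec_class is not None and self.ec_class not in range(1, 8):
            raise ValueError(f"{self.id}: ec_class must be in 1..7")


@dataclass
class ProfileSet:
    """Normalized evolutionary profiles for one enzyme.

    ``pssm`` is the sigmoid-normalized n x 20 log-odds block (entries
    strictly in (0, 1)); ``hmm`` is the n x 30 profile-HMM block in [0, 1].
    """

    pssm: np.ndarray
    hmm: np.ndarray
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.hmm = np.asarray(self.hmm, dtype=float)
        if self.pssm.ndim != 2 or self.pssm.shape[1] != 20:
            raise ValueError(f"pssm must be n x 20, got {self.pssm.shape}")
        if self.hmm.ndim != 2 or self.hmm.shape[1] != 30:
            raise ValueError(f"hmm must be n x 30, got {self.hmm.shape}")
        if self.pssm.shape[0] != self.hmm.shape[0]:
            raise ValueError("pssm and hmm row counts disagree")
        if not (np.isfinite(self.pssm).all() and np.isfinite(self.hmm).all()):
            raise ValueError("profiles must be finite")
        if not ((self.pssm > 0).all() and (self.pssm < 1).all()):
            raise ValueError("pssm entries must lie strictly in (0, 1)")
        if not ((self.hmm >= 0).all() and (self.hmm <= 1).all()):
            raise ValueError("hmm entries must lie in [0, 1]")

    @property
    def n_residues(self) -> int:
        return self.pssm.shape[0]


#: GCN input feature width: 50 evolutionary + 14 atomic channels.
GCN_INPUT_WIDTH = 64
EMBED_WIDTH = 1024
ATOMIC_WIDTH = 14


@dataclass
class ResidueGraph:
    """Attributed residue graph G = (V, A, X) for one enzyme.

    ``x_l`` (n x 50) is PSSM ‖ HMM, ``x_g`` (n x 1024) the language-model
    embedding block, ``x_a`` (n x 14) the atomic descriptor. The GCN
    consumes [x_l, x_a] (width 64); x_g enters only at the fusion stage.
    """

    adjacency: np.ndarray
    x_l: np.ndarray
    x_g: np.ndarray
    x_a: np.ndarray
    labels: np.ndarray = None
    ec_class: Optional[int] = None
    id: str = ""
    embedding_missing: bool = False

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.x_l = np.asarray(self.x_l, dtype=float)
        self.x_g = np.asarray(self.x_g, dtype=float)
        self.x_a = np.asarray(self.x_a, dtype=float)
        n = self.adjacency.shape[0]
        if self.labels is None:
            self.labels = np.zeros(n, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.validate()

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]

    def validate(self) -> None:
        a = self.adjacency
        n = a.shape[0]
        if a.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.trace(a) != 0:
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be binary")
        if self.x_l.shape != (n, 50):
            raise ValueError(f"x_l must be {n} x 50, got {self.x_l.shape}")
        if self.x_g.shape != (n, EMBED_WIDTH):
            raise ValueError(f"x_g must be {n} x {EMBED_WIDTH}")
        if self.x_a.shape != (n, ATOMIC_WIDTH):
            raise ValueError(f"x_a must be {n} x {ATOMIC_WIDTH}")
        if not ((self.x_l >= 0).all() and (self.x_l <= 1).all()):
            raise ValueError("x_l entries must lie in [0, 1]")
        if len(self.labels) != n:
            raise ValueError("labels length mismatch")

    @property
    def gcn_input(self) -> np.ndarray:
        """H(0) = [X_L, X_A], width 64."""
        return np.concatenate([self.x_l, self.x_a], axis=1)

    def save(self, path) -> None:
        np.savez(
            path,
            adjacency=self.adjacency, x_l=self.x_l, x_g=self.x_g,
            x_a=self.x_a, labels=self.labels,
            ec_class=np.array(-1 if self.ec_class is None else self.ec_class),
            id=np.array(self.id),
            embedding_missing=np.array(self.embedding_missing),
        )

    @classmethod
    def load(cls, path) -> "ResidueGraph":
        with np.load(path, allow_pickle=False) as z:
            ec = int(z["ec_class"])
            return cls(
                adjacency=z["adjacency"], x_l=z["x_l"], x_g=z["x_g"],
                x_a=z["x_a"], labels=z["labels"],
                ec_class=None if ec < 0 else ec, id=str(z["id"]),
                embedding_missing=bool(z["embedding_missing"]),
            )


@dataclass
class PredictionSet:
    """Per-enzyme propensities with matching labels and Cα coordinates."""

    propensities: list          # list of (n,) float arrays in [0, 1]
    labels: list                # list of (n,) binary arrays
    ca_coords: list = None      # list of (n, 3) arrays, optional

    def __post_init__(self):
        self.propensities = [np.asarray(p, dtype=float) for p in self.propensities]
        self.labels = [np.asarray(l, dtype=int) for l in self.labels]
        if len(self.propensities) != len(self.labels):
            raise ValueError("propensities and labels count mismatch")
        for p, l in zip(self.propensities, self.labels):
            if p.shape != l.shape:
                raise ValueError("per-enzyme length mismatch")
            if ((p < 0) | (p > 1)).any():
                raise ValueError("propensities must lie in [0, 1]")
        if self.ca_coords is not None:
            self.ca_coords = [np.asarray(c, dtype=float) for c in self.ca_coords]

    def pooled(self):
        """Concatenate scores and labels across enzymes (micro pooling)."""
        return (np.concatenate(self.propensities),
                np.concatenate(self.labels))


@dataclass
class VariantTable:
    """MAVE variant scores for one enzyme.

    ``higher_is_active`` declares score orientation; it must be set
    explicitly before classification.
    """

    residue_numbers: list        # author residue numbers, str
    wildtype: list               # 1-letter codes
    substitution: list
    scores: np.ndarray
    higher_is_active: Optional[bool] = None
    provenance: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        k = len(self.scores)
        if not (len(self.residue_numbers) == len(self.wildtype)
                == len(self.substitution) == k):
            raise ValueError("variant table column lengths disagree")
        if not np.isfinite(self.scores).all():
            raise ValueError("variant scores must be finite")

    def __len__(self) -> int:
        return len(self.scores)
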