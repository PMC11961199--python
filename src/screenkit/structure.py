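"""Structure parsing and residue-graph construction.

An enzyme chain is reduced to residue-level records (Cα coordinates plus
per-residue heavy atoms), from which a binary Cα–Cα contact graph and a
14-channel atomic descriptor are built. Hydrogens, waters and hetero
compounds are excluded on read; residues lacking a Cα are dropped with a
warning and all downstream blocks are aligned to the surviving residues.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_structure

from . import chemdata as chem
from .types import Atom, EnzymeRecord, ProfileSet, ResidueGraph, EMBED_WIDTH

logger = logging.getLogger(__name__)

__all__ = ["read_structure", "contact_map", "atomic_descriptor",
           "build_graph", "residue_sasa", "read_catalytic_labels",
           "apply_catalytic_labels", "write_contact_map_dense",
           "write_contact_map_edges"]

DEFAULT_CONTACT_CUTOFF = 10.0   # Å, Cα–Cα

#: Fixed channel order of the atomic descriptor (14 columns).
ATOMIC_CHANNELS = (
    "frac_C", "frac_N", "frac_O", "frac_S", "frac_other",
    "mean_mass", "mean_b_factor", "frac_sidechain",
    "mean_bonded_hydrogens", "frac_ring", "mean_vdw_radius",
    "relative_sasa", "absolute_sasa", "reserved",
)

# Divisors applied per channel when assembling X_A for the network, so all
# channels are O(1); raw physical values stay available from
# atomic_descriptor itself.
ATOMIC_SCALES = np.array([1, 1, 1, 1, 1, 32.06, 100.0, 1, 4.0, 1, 2.0,
                          1, 200.0, 1])


def _load_atom_array(path):
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        cif = CIFFile.read(str(path))
        return _cif_structure(cif, model=1, extra_fields=["b_factor"])
    pdb = PDBFile.read(str(path))
    return pdb.get_structure(model=1, extra_fields=["b_factor"])


def read_structure(path, chain: str) -> EnzymeRecord:
    """Parse one chain of a PDB/mmCIF file into an EnzymeRecord.

    Hydrogens (H/D), waters and hetero compounds are removed. Residues
    are ordered by author numbering; residues without a Cα atom are
    dropped (a warning is logged).
    """
    arr = _load_atom_array(path)
    chains = sorted(set(arr.chain_id))
    if chain not in chains:
        raise ValueError(
            f"{path}: chain {chain!r} not present; available chains: "
            f"{', '.join(chains)}")
    keep = (
        (arr.chain_id == chain)
        & struc.filter_amino_acids(arr)
        & ~arr.hetero
        & ~np.isin(arr.element, ("H", "D"))
        & (arr.res_name != "HOH")
    )
    arr = arr[keep]
    if arr.array_length() == 0:
        raise ValueError(f"{path}: chain {chain} has no standard residues")

    # Group atoms by author residue id (number + insertion code).
    order = np.argsort(arr.res_id, kind="stable")
    arr = arr[order]
    residues: dict[str, list[int]] = {}
    for i in range(arr.array_length()):
        ins = arr.ins_code[i].strip() if hasattr(arr, "ins_code") else ""
        key = f"{arr.res_id[i]}{ins}"
        residues.setdefault(key, []).append(i)

    sequence, numbers, ca_coords, atoms = [], [], [], []
    for resnum, idxs in residues.items():
        names = [arr.atom_name[i] for i in idxs]
        if "CA" not in names:
            msg = (f"{path}: residue {resnum} ({arr.res_name[idxs[0]]}) "
                   f"lacks a CA atom; dropped")
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        res3 = arr.res_name[idxs[0]]
        sequence.append(chem.AA3_TO_1.get(res3, "X"))
        numbers.append(resnum)
        ca_coords.append(arr.coord[idxs[names.index("CA")]])
        res_atoms = [
            Atom(element=str(arr.element[i]).upper(),
                 name=str(arr.atom_name[i]),
                 coords=tuple(float(c) for c in arr.coord[i]),
                 b_factor=float(arr.b_factor[i]),
                 is_sidechain=str(arr.atom_name[i]) not in chem.BACKBONE_ATOMS)
            for i in idxs
        ]
        atoms.append(res_atoms)
    if not sequence:
        raise ValueError(f"{path}: chain {chain} has no residues with CA")

    structure_id = path if isinstance(path, str) else str(path)
    structure_id = Path(structure_id).stem
    return EnzymeRecord(
        id=f"{structure_id}_{chain}",
        sequence="".join(sequence),
        residue_numbers=numbers,
        ca_coords=np.array(ca_coords, dtype=float),
        atoms=atoms,
    )


def contact_map(record: EnzymeRecord, cutoff: float = DEFAULT_CONTACT_CUTOFF
                ) -> np.ndarray:
    """Binary Cα–Cα contact matrix: (i, j) = 1 iff i != j and the Cα
    distance is <= cutoff Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = record.ca_coords
    if not np.isfinite(coords).all():
        raise ValueError(f"{record.id}: non-finite CA coordinates")
    d = cdist(coords, coords)
    a = (d <= cutoff).astype(float)
    np.fill_diagonal(a, 0.0)
    return a


def _record_to_atom_array(record: EnzymeRecord):
    flat = [(ri, a) for ri, res in enumerate(record.atoms) for a in res]
    n = len(flat)
    arr = struc.AtomArray(n)
    arr.coord = np.array([a.coords for _, a in flat], dtype=np.float32)
    arr.element = np.array([a.element for _, a in flat])
    arr.atom_name = np.array([a.name for _, a in flat])
    arr.res_id = np.array([ri + 1 for ri, _ in flat])
    arr.res_name = np.array(
        [chem.AA1_TO_3.get(record.sequence[ri], "ALA") for ri, _ in flat])
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    return arr, np.array([ri for ri, _ in flat])


def residue_sasa(record: EnzymeRecord, probe_radius: float = 1.4,
                 point_number: int = 200) -> np.ndarray:
    """Per-residue absolute solvent-accessible surface area (Å^2) by the
    Shrake–Rupley rolling-probe method on heavy atoms."""
    arr, res_index = _record_to_atom_array(record)
    atom_sasa = struc.sasa(arr, probe_radius=probe_radius,
                           point_number=point_number, vdw_radii="Single")
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    out = np.zeros(record.n_residues)
    np.add.at(out, res_index, atom_sasa)
    return out


def atomic_descriptor(record: EnzymeRecord, sasa: np.ndarray) -> np.ndarray:
    """n x 14 atomic descriptor; per residue the mean over heavy atoms of
    the atom channels, plus broadcast residue-level SASA channels.

    Column order is :data:`ATOMIC_CHANNELS`; values are raw physical
    units (mass in u, SASA in Å^2).
    """
    sasa = np.asarray(sasa, dtype=float)
    n = record.n_residues
    if sasa.shape != (n,):
        raise ValueError(f"sasa must have length {n}, got {sasa.shape}")
    out = np.zeros((n, 14))
    for i, res_atoms in enumerate(record.atoms):
        res3 = chem.AA1_TO_3.get(record.sequence[i], "ALA")
        k = len(res_atoms)
        for a in res_atoms:
            cls = chem.element_class(a.element)
            out[i, chem.ELEMENT_CLASSES.index(cls)] += 1.0
            out[i, 5] += chem.ATOMIC_MASS.get(a.element, chem.DEFAULT_MASS)
            out[i, 6] += a.b_factor
            out[i, 7] += float(a.is_sidechain)
            out[i, 8] += chem.hydrogen_count(res3, a.name)
            out[i, 9] += float(chem.in_ring(res3, a.name))
            out[i, 10] += chem.VDW_RADIUS.get(a.element, chem.DEFAULT_VDW)
        out[i, :11] /= k
        max_sasa = chem.MAX_SASA.get(res3, chem.DEFAULT_MAX_SASA)
        out[i, 11] = min(1.0, sasa[i] / max_sasa)
        out[i, 12] = sasa[i]
        out[i, 13] = 0.0
    return out


def build_graph(record: EnzymeRecord, profiles: ProfileSet,
                embedding: np.ndarray = None,
                cutoff: float = DEFAULT_CONTACT_CUTOFF,
                sasa: np.ndarray = None,
                scale_atomic: bool = True) -> ResidueGraph:
    """Assemble adjacency and feature blocks into a ResidueGraph.

    ``embedding=None`` fills the 1024-wide block with zeros and raises the
    ``embedding_missing`` flag (the forward pass stays defined). With
    ``scale_atomic`` the atomic block is divided by fixed per-channel
    scales so every channel is O(1) for the network.
    """
    n = record.n_residues
    if profiles.n_residues != n:
        raise ValueError(
            f"{record.id}: structure has {n} residues but profiles have "
            f"{profiles.n_residues} rows (PSSM/HMM must be re-aligned)")
    missing = embedding is None
    if missing:
        embedding = np.zeros((n, EMBED_WIDTH))
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape != (n, EMBED_WIDTH):
        raise ValueError(
            f"{record.id}: embedding rows ({embedding.shape[0]}) do not "
            f"match structure residues ({n})")
    if sasa is None:
        sasa = residue_sasa(record)
    x_a = atomic_descriptor(record, sasa)
    if scale_atomic:
        x_a = x_a / ATOMIC_SCALES
    return ResidueGraph(
        adjacency=contact_map(record, cutoff),
        x_l=np.concatenate([profiles.pssm, profiles.hmm], axis=1),
        x_g=embedding,
        x_a=x_a,
        labels=record.catalytic_mask,
        ec_class=record.ec_class,
        id=record.id,
        embedding_missing=missing,
    )


# -- label tables and contact-map serialization -------------------------

def read_catalytic_labels(path) -> dict:
    """Read a TSV of (structure_id, chain, residue_number) into a map
    (structure_id, chain) -> set of residue-number strings."""
    out: dict[tuple, set] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "structure_id":
            continue
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        out.setdefault((fields[0], fields[1]), set()).add(fields[2])
    return out


def apply_catalytic_labels(record: EnzymeRecord, residue_numbers) -> EnzymeRecord:
    """Set the catalytic mask from author residue numbers (join key)."""
    wanted = set(str(r) for r in residue_numbers)
    mask = np.array([1 if rn in wanted else 0 for rn in record.residue_numbers],
                    dtype=np.uint8)
    unmatched = wanted - set(record.residue_numbers)
    if unmatched:
        logger.warning("%s: %d catalytic labels matched no residue: %s",
                       record.id, len(unmatched), sorted(unmatched))
    record.catalytic_mask = mask
    return record


def write_contact_map_dense(a: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(a, dtype=int), fmt="%d")


def write_contact_map_edges(a: np.ndarray, path) -> None:
    """Sparse upper-triangle edge list as TSV (i, j) with 0-based indices."""
    a = np.asarray(a)
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for i, j in zip(*np.nonzero(np.triu(a))):
            fh.write(f"{i}\t{j}\n")
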