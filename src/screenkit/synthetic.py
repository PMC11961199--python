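"""Synthetic protein-like fixtures with planted, spatially clustered
catalytic residues and correlated feature signals.

The generator emulates the hallmarks of real catalytic sites that the
predictor exploits — spatial cohesion of the catalytic residues, elevated
evolutionary conservation, depressed B-factors, burial (limited solvent
accessibility), and enrichment of charged amino acids — without any
physical folding model. Chains are self-avoiding random walks with a
3.8 Å Cα step; per-residue pseudo-atoms (backbone + residue-type side
chain) are placed around each Cα so the atomic descriptor and the
rolling-probe SASA are well defined. Every draw comes from one seeded
generator, so a config + seed reproduces a dataset bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from scipy.stats import norm

from . import chemdata as chem
from .structure import build_graph, residue_sasa
from .types import Atom, EnzymeRecord, ProfileSet, VariantTable, EMBED_WIDTH

__all__ = ["GeneratorConfig", "generate_backbone", "plant_catalytic",
           "synthesize_features", "generate_enzyme", "generate_dataset",
           "generate_variant_scores", "generate_variant_table",
           "analytic_cutoff", "emit_fixture_set"]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give 200 enzymes of 100 residues with 5 planted catalytic
    residues (5% prevalence) in 3 enzyme classes — the benchmark scale —
    with conservation, rigidity, burial and charge signals at strengths a
    real catalytic site plausibly shows.
    """

    n_enzymes: int = 200
    residues_per_enzyme: int = 100
    catalytic_per_enzyme: int = 5
    n_classes: int = 3
    # signal strengths
    conservation_lift: float = 2.0       # PSSM log-odds shift at catalytic rows
    bfactor_depression: float = 20.0     # B-factor units subtracted
    burial_bias: float = 3.0             # softmax weight toward buried seeds
    charged_enrichment: float = 0.7      # P(charged aa) at catalytic positions
    # geometry
    backbone_step: float = 3.8           # Å, consecutive Cα spacing
    step_jitter: float = 0.05
    min_separation: float = 4.0          # Å, non-consecutive Cα floor
    cluster_radius: float = 8.0          # Å, catalytic cohesion radius
    compactness: float = 0.25            # pull toward the centroid per step
    # embedding signal: class direction + shared low-rank basis + residual
    embed_class_scale: float = 1.0
    embed_rank: int = 16                 # rank of the shared noise basis
    embed_noise: float = 1.0             # std of basis coefficients
    embed_residual: float = 0.05         # std of isotropic residual
    # variant-score mixture (active / intermediate / loss components)
    variant_means: tuple = (-2.0, 0.0, 2.0)
    variant_sds: tuple = (0.3, 0.3, 0.3)
    variant_weights: tuple = (0.4, 0.2, 0.4)
    variants_per_residue: int = 5
    seed: int = 0

    def to_dict(self):
        d = asdict(self)
        for k in ("variant_means", "variant_sds", "variant_weights"):
            d[k] = list(d[k])
        return d

    def __post_init__(self):
        if self.catalytic_per_enzyme >= self.residues_per_enzyme:
            raise ValueError("catalytic_per_enzyme must be < residues_per_enzyme")


def generate_backbone(m: int, rng, step: float = 3.8, jitter: float = 0.05,
                      min_separation: float = 4.0, compactness: float = 0.25,
                      max_retries: int = 200) -> np.ndarray:
    """Self-avoiding random-walk Cα trace: consecutive spacing step±jitter,
    non-consecutive pairs kept >= min_separation apart, with a mild pull
    toward the running centroid so chains stay globular."""
    if m < 2:
        raise ValueError("need at least 2 residues")
    for _ in range(20):  # global restarts
        coords = np.zeros((m, 3))
        coords[1] = [step, 0.0, 0.0]
        ok = True
        for i in range(2, m):
            centroid = coords[:i].mean(axis=0)
            placed = False
            for _ in range(max_retries):
                direction = rng.normal(size=3)
                pull = centroid - coords[i - 1]
                pull_norm = np.linalg.norm(pull)
                if pull_norm > 0:
                    direction = direction / np.linalg.norm(direction) \
                        + compactness * pull / pull_norm
                direction /= np.linalg.norm(direction)
                length = step + rng.uniform(-jitter, jitter)
                cand = coords[i - 1] + length * direction
                d = np.linalg.norm(coords[:i - 1] - cand, axis=1)
                if (d >= min_separation).all():
                    coords[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise RuntimeError(f"backbone placement failed for m={m} after retries")


def plant_catalytic(coords: np.ndarray, k: int, radius: float, rng,
                    burial_bias: float = 3.0) -> np.ndarray:
    """Plant a spatial cluster of k catalytic residues.

    The seed residue is drawn with probability increasing toward the
    chain centroid (burial); each subsequent residue is drawn uniformly
    among the residues within ``radius`` of the current cluster, so every
    planted residue lies within radius of another planted residue.
    """
    coords = np.asarray(coords, dtype=float)
    m = len(coords)
    if k < 2:
        raise ValueError("plant at least 2 catalytic residues")
    centroid = coords.mean(axis=0)
    depth = np.linalg.norm(coords - centroid, axis=1)
    w = np.exp(-burial_bias * depth / max(depth.max(), 1e-9))
    w /= w.sum()
    d = cdist(coords, coords)
    for _ in range(50):
        seed_idx = rng.choice(m, p=w)
        planted = [seed_idx]
        feasible = True
        for _ in range(k - 1):
            near = np.unique(np.nonzero(d[planted] <= radius)[1])
            candidates = np.setdiff1d(near, planted)
            if candidates.size == 0:
                feasible = False
                break
            planted.append(int(rng.choice(candidates)))
        if feasible:
            mask = np.zeros(m, dtype=np.uint8)
            mask[planted] = 1
            return mask
    raise RuntimeError(
        f"could not plant {k} catalytic residues within {radius} Å")


def _sample_sequence(mask, rng, charged_enrichment: float) -> str:
    seq = []
    for is_cat in mask:
        if is_cat and rng.random() < charged_enrichment:
            seq.append(chem.CHARGED_AA[rng.integers(len(chem.CHARGED_AA))])
        else:
            seq.append(AA_ALPHABET[rng.integers(len(AA_ALPHABET))])
    return "".join(seq)


def _embedding_basis(config: GeneratorConfig) -> np.ndarray:
    """Shared low-rank basis for residue-level embedding variation.

    Deterministic in the config seed and shared across a dataset, so the
    embedding block is genuinely low-rank (class directions + rank-r
    basis + small residual), like the principal-subspace structure of
    real language-model embeddings.
    """
    basis_rng = np.random.default_rng((config.seed * 2654435761 + 97) % 2**31)
    return basis_rng.normal(size=(config.embed_rank, EMBED_WIDTH)) \
        / np.sqrt(EMBED_WIDTH)


def synthesize_features(mask, config: GeneratorConfig, rng,
                        class_vector: np.ndarray = None,
                        embed_basis: np.ndarray = None):
    """Profile + embedding blocks with signal planted at catalytic rows.

    PSSM log-odds are integers ~ round(N(-1, 2)) with the mean lifted by
    ``conservation_lift`` at catalytic positions; the HMM match-emission
    block is correlated with the PSSM lift; the embedding is the
    enzyme-class direction plus rank-``embed_rank`` structured variation
    plus a small isotropic residual.

    Returns (pssm_int n x 20, hmm n x 30 in [0,1], embedding n x 1024).
    """
    mask = np.asarray(mask, dtype=bool)
    n = len(mask)
    lift = config.conservation_lift * mask[:, None]
    pssm_int = np.round(rng.normal(-1.0, 2.0, size=(n, 20)) + lift).astype(int)

    hmm = rng.uniform(0.0, 1.0, size=(n, 30))
    hmm[:, :20] = np.clip(
        hmm[:, :20] + 0.1 * config.conservation_lift * mask[:, None], 0.0, 1.0)

    if class_vector is None:
        class_vector = np.zeros(EMBED_WIDTH)
    if embed_basis is None:
        embed_basis = _embedding_basis(config)
    coeffs = config.embed_noise * rng.normal(size=(n, config.embed_rank))
    embedding = (config.embed_class_scale * class_vector[None, :]
                 + coeffs @ embed_basis
                 + config.embed_residual * rng.normal(size=(n, EMBED_WIDTH)))
    return pssm_int, hmm, embedding


def _build_atoms(coords, sequence, b_factors, rng):
    atoms = []
    for i, ca in enumerate(coords):
        res3 = chem.AA1_TO_3[sequence[i]]
        res_atoms = []
        for name in chem.BACKBONE_ATOMS:
            if name == "CA":
                pos = ca
            else:
                offset = rng.normal(size=3)
                offset *= rng.uniform(1.2, 1.6) / np.linalg.norm(offset)
                pos = ca + offset
            res_atoms.append(Atom(
                element=name[0], name=name,
                coords=tuple(np.round(pos, 3)),
                b_factor=float(np.round(b_factors[i] + rng.normal(0, 2), 2)),
                is_sidechain=False))
        for name in chem.SIDECHAIN_ATOMS[res3]:
            offset = rng.normal(size=3)
            offset *= rng.uniform(1.5, 3.0) / np.linalg.norm(offset)
            pos = ca + offset
            res_atoms.append(Atom(
                element=name[0], name=name,
                coords=tuple(np.round(pos, 3)),
                b_factor=float(np.round(b_factors[i] + rng.normal(0, 2), 2)),
                is_sidechain=True))
        atoms.append(res_atoms)
    return atoms


def generate_enzyme(config: GeneratorConfig, rng, enzyme_id: str,
                    ec_class: int, class_vector=None):
    """One synthetic enzyme: (EnzymeRecord, ProfileSet, embedding)."""
    from .profiles import sigmoid_normalize

    m = config.residues_per_enzyme
    coords = generate_backbone(
        m, rng, step=config.backbone_step, jitter=config.step_jitter,
        min_separation=config.min_separation, compactness=config.compactness)
    mask = plant_catalytic(coords, config.catalytic_per_enzyme,
                           config.cluster_radius, rng,
                           burial_bias=config.burial_bias)
    sequence = _sample_sequence(mask, rng, config.charged_enrichment)
    b_base = rng.normal(50.0, 10.0, size=m)
    b_base = np.clip(b_base - config.bfactor_depression * mask, 2.0, None)
    atoms = _build_atoms(coords, sequence, b_base, rng)
    record = EnzymeRecord(
        id=enzyme_id, sequence=sequence,
        residue_numbers=[str(i + 1) for i in range(m)],
        ca_coords=coords, atoms=atoms, catalytic_mask=mask,
        ec_class=ec_class)
    pssm_int, hmm, embedding = synthesize_features(
        mask, config, rng, class_vector)
    profiles = ProfileSet(pssm=sigmoid_normalize(pssm_int), hmm=hmm,
                          source_meta={"generator": "screenkit.synthetic",
                                       "raw_pssm": pssm_int})
    return record, profiles, embedding


def generate_dataset(config: GeneratorConfig = None, cutoff: float = 10.0,
                     as_graphs: bool = True):
    """Generate the full synthetic dataset under ``config``.

    Returns (records, graphs) — graphs is None with ``as_graphs=False``.
    EC classes cycle 1..n_classes so every class is populated.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    class_vectors = {
        c: rng.normal(size=EMBED_WIDTH) / np.sqrt(EMBED_WIDTH) * 10.0
        for c in range(1, config.n_classes + 1)}
    records, graphs = [], [] if as_graphs else None
    for i in range(config.n_enzymes):
        ec = 1 + i % config.n_classes
        record, profiles, embedding = generate_enzyme(
            config, rng, enzyme_id=f"SYN{i:04d}_A", ec_class=ec,
            class_vector=class_vectors[ec])
        records.append(record)
        if as_graphs:
            graphs.append(build_graph(record, profiles, embedding,
                                      cutoff=cutoff))
    return records, graphs


# -- variant-score generation ------------------------------------------

def generate_variant_scores(n: int, config: GeneratorConfig, rng,
                            component=None) -> np.ndarray:
    """Draw scores from the planted 3-Gaussian mixture; ``component``
    forces all draws from one component (0 = loss end, 2 = active end)."""
    mu = np.asarray(config.variant_means)
    sd = np.asarray(config.variant_sds)
    w = np.asarray(config.variant_weights, dtype=float)
    w = w / w.sum()
    comp = (np.full(n, component) if component is not None
            else rng.choice(3, size=n, p=w))
    return rng.normal(mu[comp], sd[comp])


def analytic_cutoff(config: GeneratorConfig) -> float:
    """Equal-weighted-density point between the first and last planted
    mixture components — the ground-truth classification cutoff."""
    mu = np.asarray(config.variant_means)
    sd = np.asarray(config.variant_sds)
    w = np.asarray(config.variant_weights, dtype=float)
    w = w / w.sum()

    def gap(x):
        return w[0] * norm.pdf(x, mu[0], sd[0]) - w[2] * norm.pdf(x, mu[2], sd[2])

    return float(brentq(gap, mu[0], mu[2]))


def generate_variant_table(record: EnzymeRecord, config: GeneratorConfig,
                           rng, distance_threshold: float = 8.0
                           ) -> VariantTable:
    """MAVE-style table tied to the structure: residues near the planted
    catalytic site draw scores from the loss component, distant residues
    from the active component (higher score = more active)."""
    from .metrics import distance_to_nearest_catalytic

    n = record.n_residues
    dist = np.zeros(n)
    non_cat = record.catalytic_mask == 0
    if non_cat.any():
        dist[non_cat] = distance_to_nearest_catalytic(
            record.ca_coords, record.catalytic_mask, subset=non_cat)
    rows_rn, rows_wt, rows_sub, rows_score = [], [], [], []
    for i in range(n):
        near = dist[i] < distance_threshold
        for _ in range(config.variants_per_residue):
            # near-site residues mostly lose function (component 0 is the
            # low-score end; orientation is higher = active)
            if rng.random() < 0.1:
                comp = 1
            else:
                comp = 0 if near else 2
            score = generate_variant_scores(1, config, rng, component=comp)[0]
            wt = record.sequence[i]
            sub = wt
            while sub == wt:
                sub = AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
            rows_rn.append(record.residue_numbers[i])
            rows_wt.append(wt)
            rows_sub.append(sub)
            rows_score.append(score)
    return VariantTable(
        residue_numbers=rows_rn, wildtype=rows_wt, substitution=rows_sub,
        scores=np.array(rows_score), higher_is_active=True,
        provenance="screenkit.synthetic")


# -- on-disk fixture emission ------------------------------------------

def _write_pdb(record: EnzymeRecord, path) -> None:
    lines = [f"HEADER    SYNTHETIC ENZYME {record.id}"]
    serial = 1
    chain = "A"
    for i, res_atoms in enumerate(record.atoms):
        res3 = chem.AA1_TO_3[record.sequence[i]]
        resnum = int(record.residue_numbers[i])
        for a in res_atoms:
            name_field = f" {a.name:<3s}" if len(a.name) < 4 else a.name
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name_field}{'':1s}{res3:3s} {chain}"
                f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
                f"{a.b_factor:6.2f}          {a.element:>2s}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_pssm(pssm_int: np.ndarray, sequence: str, path) -> None:
    aa = chem.PSSM_ALPHABET
    header = ("\nLast position-specific scoring matrix computed, weighted, "
              "observed percentages rounded down\n"
              "            " + "  ".join(aa) + "   " + "  ".join(aa) + "\n")
    lines = [header.rstrip("\n")]
    for i, row in enumerate(pssm_int, start=1):
        scores = " ".join(f"{v:3d}" for v in row)
        pct = " ".join(f"{0:3d}" for _ in row)
        lines.append(f"{i:5d} {sequence[i - 1]}  {scores}  {pct}  0.00 0.00")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def _prob_to_score(p: float) -> str:
    if p <= 0.0:
        return "*"
    return str(int(round(-1000.0 * np.log2(min(p, 1.0)))))


def _write_hmm(hmm: np.ndarray, sequence: str, path) -> None:
    n = hmm.shape[0]
    lines = [
        "HMMER3/f [screenkit synthetic profile]",
        f"LENG  {n}",
        "ALPH  amino",
        "HMM          " + "        ".join("ACDEFGHIKLMNPQRSTVWY"),
    ]
    for i in range(n):
        match = "  ".join(_prob_to_score(p) for p in hmm[i, :20])
        trans = "  ".join(_prob_to_score(p) for p in hmm[i, 20:30])
        lines.append(f"{i + 1:7d}   {match}")
        lines.append(f"          {trans}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def emit_fixture_set(config: GeneratorConfig, out_dir) -> Path:
    """Write a complete on-disk dataset in the formats the pipeline reads.

    Layout: per-enzyme PDB / PSSM / HMM / embedding files, a dataset-level
    catalytic-label TSV, an EC-class manifest TSV, per-enzyme MAVE-style
    variant TSVs with YAML orientation sidecars, and a MANIFEST.json
    recording config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    class_vectors = {
        c: rng.normal(size=EMBED_WIDTH) / np.sqrt(EMBED_WIDTH) * 10.0
        for c in range(1, config.n_classes + 1)}

    label_rows = ["structure_id\tchain\tresidue_number"]
    manifest_rows = ["enzyme_id\tpdb\tpssm\thmm\tembedding\tec_class"]
    for i in range(config.n_enzymes):
        ec = 1 + i % config.n_classes
        eid = f"SYN{i:04d}"
        record, profiles, embedding = generate_enzyme(
            config, rng, enzyme_id=f"{eid}_A", ec_class=ec,
            class_vector=class_vectors[ec])
        _write_pdb(record, out / f"{eid}.pdb")
        _write_pssm(profiles.source_meta["raw_pssm"], record.sequence,
                    out / f"{eid}.pssm")
        _write_hmm(profiles.hmm, record.sequence, out / f"{eid}.hmm")
        np.savez(out / f"{eid}.embedding.npz", embedding=embedding)
        for idx in np.nonzero(record.catalytic_mask)[0]:
            label_rows.append(f"{eid}\tA\t{record.residue_numbers[idx]}")
        manifest_rows.append(
            f"{eid}_A\t{eid}.pdb\t{eid}.pssm\t{eid}.hmm\t"
            f"{eid}.embedding.npz\t{ec}")
        if i < 4:  # a handful of MAVE-style tables is enough
            table = generate_variant_table(record, config, rng)
            tsv = out / f"{eid}.variants.tsv"
            with open(tsv, "w") as fh:
                fh.write("residue_number\twildtype\tsubstitution\tscore\n")
                for rn, wt, sub, sc in zip(
                        table.residue_numbers, table.wildtype,
                        table.substitution, table.scores):
                    fh.write(f"{rn}\t{wt}\t{sub}\t{sc:.6f}\n")
            (out / f"{eid}.variants.yaml").write_text(
                "higher_is_active: true\n")

    (out / "catalytic_labels.tsv").write_text("\n".join(label_rows) + "\n")
    (out / "manifest.tsv").write_text("\n".join(manifest_rows) + "\n")
    (out / "MANIFEST.json").write_text(json.dumps(
        {"config": config.to_dict(), "seed": config.seed}, indent=2))
    return out
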