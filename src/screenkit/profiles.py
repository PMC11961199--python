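"""Evolutionary profile features: PSI-BLAST PSSMs, profile-HMM matrices,
and pre-computed per-residue language-model embeddings.

The PSSM block is the 20 log-odds columns of the PSI-BLAST ASCII matrix,
squashed elementwise through the logistic sigmoid into (0, 1). The HMM
block has 30 per-position columns — 20 match-emission scores, 7 state
transitions and 3 local-diversity fields — stored as integer negative-log
scores and converted to probabilities by 2^(-score/1000), with '*'
denoting an impossible event (probability 0). The 1024-wide embedding
block is consumed as-is from a named-array file.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path

import numpy as np

from .chemdata import PSSM_ALPHABET
from .types import ProfileSet, EMBED_WIDTH

__all__ = ["parse_pssm", "sigmoid_normalize", "parse_hmm", "load_embedding",
           "load_profile_set", "run_psiblast", "run_hmmer"]

HMM_WIDTH = 30


class ProfileParseError(ValueError):
    pass


def sigmoid_normalize(m: np.ndarray) -> np.ndarray:
    """Elementwise logistic squashing x -> 1 / (1 + e^(-x))."""
    m = np.asarray(m, dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("input to sigmoid_normalize must be finite")
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-m[pos]))
    e = np.exp(m[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def parse_pssm(path) -> np.ndarray:
    """Read a PSI-BLAST ``-out_ascii_pssm`` file into an n x 20 integer
    matrix in the fixed column order ``ARNDCQEGHILKMFPSTWYV``.

    Only the 20 log-odds columns are kept; the trailing weighted-percentage
    columns and information-content fields are ignored.
    """
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        fields = line.split()
        if len(fields) >= 20 and all(f in PSSM_ALPHABET and len(f) == 1
                                     for f in fields[:20]):
            header_idx = i
            col_order = fields[:20]
            break
    if header_idx is None:
        raise ProfileParseError(f"{path}: no PSSM header row found")
    perm = [col_order.index(a) for a in PSSM_ALPHABET]

    rows = []
    for lineno, line in enumerate(lines[header_idx + 1:], header_idx + 2):
        stripped = line.strip()
        if not stripped:
            break  # blank line terminates the matrix body
        fields = stripped.split()
        if len(fields) < 22:
            raise ProfileParseError(
                f"{path}:{lineno}: expected residue row with >= 22 fields, "
                f"got {len(fields)}")
        if not fields[0].isdigit():
            raise ProfileParseError(
                f"{path}:{lineno}: residue index expected, got {fields[0]!r}")
        try:
            scores = [int(f) for f in fields[2:22]]
        except ValueError as err:
            raise ProfileParseError(f"{path}:{lineno}: {err}") from None
        rows.append([scores[j] for j in perm])
    if not rows:
        raise ProfileParseError(f"{path}: PSSM has no residue rows")
    return np.array(rows, dtype=int)


def _score_to_prob(token: str, path, lineno: int) -> float:
    if token == "*":
        return 0.0
    try:
        return min(1.0, max(0.0, 2.0 ** (-float(token) / 1000.0)))
    except ValueError:
        raise ProfileParseError(
            f"{path}:{lineno}: bad profile score {token!r}") from None


def parse_hmm(path) -> np.ndarray:
    """Read a profile-HMM text file into an n x 30 matrix in [0, 1].

    Layout: after a header whose first line contains ``HMMER3``, the body
    between the ``HMM`` marker line and ``//`` holds two lines per match
    state: (1) the position index followed by 20 match-emission scores,
    (2) 7 transition scores followed by 3 local-diversity values. Scores
    are integer negative-log values mapped through 2^(-x/1000); ``*``
    maps to 0.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or "HMMER3" not in lines[0]:
        raise ProfileParseError(
            f"{path}: not a HMMER3-style profile (bad header)")
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.split() and l.split()[0] == "HMM")
    except StopIteration:
        raise ProfileParseError(f"{path}: no HMM body marker") from None

    rows = []
    i = start + 1
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped == "//":
            break
        if not stripped:
            i += 1
            continue
        match_fields = stripped.split()
        if len(match_fields) < 21 or not match_fields[0].isdigit():
            raise ProfileParseError(
                f"{path}:{i + 1}: expected match-state line "
                f"(index + 20 scores)")
        if i + 1 >= len(lines):
            raise ProfileParseError(f"{path}:{i + 2}: truncated node")
        trans_fields = lines[i + 1].split()
        if len(trans_fields) < 10:
            raise ProfileParseError(
                f"{path}:{i + 2}: expected 7 transitions + 3 diversity "
                f"fields, got {len(trans_fields)}")
        row = [_score_to_prob(t, path, i + 1) for t in match_fields[1:21]]
        row += [_score_to_prob(t, path, i + 2) for t in trans_fields[:10]]
        rows.append(row)
        i += 2
    if not rows:
        raise ProfileParseError(f"{path}: profile has no match states")
    return np.array(rows, dtype=float)


def load_embedding(path, n: int, allow_missing: bool = False):
    """Load an n x 1024 per-residue embedding from a named-array file.

    Returns (matrix, missing_flag). With ``allow_missing`` a nonexistent
    file yields a zero matrix and a raised flag, so the forward pass stays
    defined without the language-model branch.
    """
    path = Path(path)
    if not path.exists():
        if allow_missing:
            return np.zeros((n, EMBED_WIDTH)), True
        raise FileNotFoundError(f"embedding file {path} not found")
    with np.load(path, allow_pickle=False) as z:
        key = "embedding" if "embedding" in z.files else z.files[0]
        x = np.asarray(z[key], dtype=float)
    if x.shape != (n, EMBED_WIDTH):
        raise ValueError(
            f"{path}: expected embedding of shape ({n}, {EMBED_WIDTH}), "
            f"found {x.shape}")
    return x, False


def load_profile_set(pssm_path, hmm_path, meta=None) -> ProfileSet:
    """Parse and normalize a PSSM/HMM pair into a ProfileSet."""
    pssm = sigmoid_normalize(parse_pssm(pssm_path))
    hmm = parse_hmm(hmm_path)
    if pssm.shape[0] != hmm.shape[0]:
        raise ValueError(
            f"PSSM has {pssm.shape[0]} rows but HMM has {hmm.shape[0]}")
    return ProfileSet(pssm=pssm, hmm=hmm, source_meta=meta or {})


# -- optional external-tool wrappers (never exercised by the test suite) --

def run_psiblast(fasta_path, db, out_pssm, iterations: int = 3,
                 evalue: float = 1e-3):
    """Thin wrapper over ``psiblast`` producing an ASCII PSSM (3 iterations,
    E-value < 1e-3 by default). Requires psiblast on PATH and a database."""
    if shutil.which("psiblast") is None:
        raise RuntimeError("psiblast not found on PATH")
    cmd = ["psiblast", "-query", str(fasta_path), "-db", str(db),
           "-num_iterations", str(iterations), "-evalue", str(evalue),
           "-out_ascii_pssm", str(out_pssm)]
    subprocess.run(cmd, check=True, capture_output=True)
    return Path(out_pssm)


def run_hmmer(fasta_path, db, out_hmm):
    """Thin wrapper over jackhmmer/hmmbuild with default parameters."""
    if shutil.which("jackhmmer") is None:
        raise RuntimeError("jackhmmer not found on PATH")
    cmd = ["jackhmmer", "--chkhmm", str(out_hmm), str(fasta_path), str(db)]
    subprocess.run(cmd, check=True, capture_output=True)
    return Path(out_hmm)
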