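"""Per-residue node features.

Each residue is described by the concatenation of a 1280-dimensional
language-model embedding row and its 20-dimensional BLOSUM62 substitution
score row, giving F = 1300 features per node.  Embeddings are consumed from
files (one per protein) produced by an external embedder, or generated by a
deterministic stub provider so the pipeline runs offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

EMBED_DIM = 1280
BLOSUM_DIM = 20
FEATURE_DIM = EMBED_DIM + BLOSUM_DIM

#: Fixed column order of the substitution encoding (alphabetical one-letter).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

_blosum = substitution_matrices.load("BLOSUM62")
#: 20x20 BLOSUM62 block in AA_ORDER, float64.
BLOSUM62_TABLE = np.array(
    [[float(_blosum[a, b]) for b in AA_ORDER] for a in AA_ORDER], dtype=np.float64
)
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass
class Blosum62Matrix:
    protein_id: str
    B: np.ndarray  # L x 20


@dataclass
class EmbeddingMatrix:
    protein_id: str
    E: np.ndarray  # L x 1280

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=np.float64)
        if self.E.ndim != 2 or self.E.shape[1] != EMBED_DIM:
            raise ValueError(
                f"embedding matrix must have {EMBED_DIM} columns, "
                f"got shape {self.E.shape}"
            )
        if not np.all(np.isfinite(self.E)):
            raise ValueError("embedding matrix contains non-finite values")


@dataclass
class NodeFeatureMatrix:
    """L x F node features; embedding columns first, substitution columns last."""

    protein_id: str
    H: np.ndarray
    feature_mode: str = "esm+blosum"

    @property
    def F(self) -> int:
        return self.H.shape[1]


def encode_blosum62(sequence: str, protein_id: str = "protein",
                    strict: bool = False) -> Blosum62Matrix:
    """Encode a sequence as its L x 20 BLOSUM62 score rows.

    ``X`` (unknown residue) maps to an all-zero row unless ``strict`` is set.
    Any other non-standard letter raises, naming the 1-based position.
    """
    if not sequence:
        raise ValueError("sequence is empty")
    B = np.zeros((len(sequence), BLOSUM_DIM), dtype=np.float64)
    for pos, aa in enumerate(sequence):
        if aa in _AA_INDEX:
            B[pos] = BLOSUM62_TABLE[_AA_INDEX[aa]]
        elif aa == "X" and not strict:
            continue  # zero row
        else:
            raise ValueError(
                f"illegal residue {aa!r} at position {pos + 1} of {protein_id}"
            )
    return Blosum62Matrix(protein_id=protein_id, B=B)


def stub_embeddings(sequence: str, seed: int,
                    protein_id: str = "protein") -> EmbeddingMatrix:
    """Deterministic pseudo-random embeddings standing in for a pretrained
    protein language model.

    Each row is a residue-type basis vector (drawn once from the seed) plus a
    sinusoidal positional component, so rows depend on residue type, position
    and seed, and identical sequences give bit-identical matrices.
    """
    rng = np.random.default_rng(seed)
    # one basis row per standard residue type + one for 'X'
    basis = rng.normal(0.0, 0.5, size=(len(AA_ORDER) + 1, EMBED_DIM))
    idx = np.array([_AA_INDEX.get(aa, len(AA_ORDER)) for aa in sequence])
    L = len(sequence)
    pos = np.arange(L, dtype=np.float64)[:, None]
    dim = np.arange(EMBED_DIM, dtype=np.float64)[None, :]
    wavelength = np.power(10000.0, dim / EMBED_DIM)
    positional = 0.2 * np.sin(pos / wavelength)
    return EmbeddingMatrix(protein_id=protein_id, E=basis[idx] + positional)


# ---------------------------------------------------------------------------
# embedding file container
# ---------------------------------------------------------------------------

def write_embeddings(path, emb: EmbeddingMatrix) -> None:
    """Write one protein's embeddings.

    ``.npz`` suffix selects the binary variant (bit-exact); anything else is
    the text variant: a ``#protein_id=<id> L=<n> width=<w>`` header followed
    by one whitespace-separated row per residue (hex floats, bit-exact).
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, protein_id=np.array(emb.protein_id), E=emb.E)
    else:
        with open(path, "w") as fh:
            fh.write(f"#protein_id={emb.protein_id} L={emb.E.shape[0]} "
                     f"width={emb.E.shape[1]}\n")
            for row in emb.E:
                fh.write(" ".join(v.hex() for v in row.tolist()) + "\n")


def load_embeddings(path, sequence: str,
                    protein_id: str | None = None) -> EmbeddingMatrix:
    """Load and validate one protein's L x 1280 embedding matrix.

    The row count must equal ``len(sequence)``; width must be 1280; all
    entries must be finite.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding file not found: {path}")
    if path.suffix == ".npz":
        with np.load(path) as data:
            pid = str(data["protein_id"])
            E = np.asarray(data["E"], dtype=np.float64)
    else:
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing embedding header line")
            fields = dict(item.split("=") for item in header[1:].split())
            pid = fields["protein_id"]
            E = np.array(
                [[float.fromhex(tok) for tok in line.split()]
                 for line in fh if line.strip()],
                dtype=np.float64,
            )
        declared = int(fields["L"])
        if E.shape[0] != declared:
            raise ValueError(
                f"{path}: header declares L={declared} but file has "
                f"{E.shape[0]} rows"
            )
    if E.ndim != 2 or E.shape[1] != EMBED_DIM:
        raise ValueError(
            f"{path}: expected {EMBED_DIM} embedding columns, got shape {E.shape}"
        )
    if E.shape[0] != len(sequence):
        raise ValueError(
            f"{path}: embedding has {E.shape[0]} rows but sequence has "
            f"{len(sequence)} residues"
        )
    if not np.all(np.isfinite(E)):
        raise ValueError(f"{path}: embedding contains non-finite values")
    return EmbeddingMatrix(protein_id=protein_id or pid, E=E)


class EmbeddingProvider:
    """Uniform access to per-protein embeddings (file-backed or stub)."""

    def __init__(self, kind: str = "stub", directory=None, seed: int = 0):
        if kind not in ("file", "stub"):
            raise ValueError(f"unknown provider kind {kind!r}")
        if kind == "file" and directory is None:
            raise ValueError("file provider requires a directory")
        self.kind = kind
        self.directory = Path(directory) if directory else None
        self.seed = seed

    def get(self, protein_id: str, sequence: str) -> EmbeddingMatrix:
        if self.kind == "stub":
            return stub_embeddings(sequence, self.seed, protein_id=protein_id)
        for suffix in (".emb", ".npz"):
            candidate = self.directory / f"{protein_id}{suffix}"
            if candidate.exists():
                return load_embeddings(candidate, sequence, protein_id=protein_id)
        raise FileNotFoundError(
            f"no embedding file for {protein_id!r} in {self.directory}"
        )


def concat_features(emb: EmbeddingMatrix, blosum: Blosum62Matrix) -> NodeFeatureMatrix:
    """Concatenate embedding (columns 0..1279) and BLOSUM62 (1280..1299) rows."""
    if emb.E.shape[0] != blosum.B.shape[0]:
        raise ValueError(
            f"row count mismatch: embeddings {emb.E.shape[0]} vs "
            f"substitution encoding {blosum.B.shape[0]}"
        )
    if emb.protein_id != blosum.protein_id:
        raise ValueError(
            f"protein_id mismatch: {emb.protein_id!r} vs {blosum.protein_id!r}"
        )
    H = np.hstack([emb.E, blosum.B])
    return NodeFeatureMatrix(protein_id=emb.protein_id, H=H,
                             feature_mode="esm+blosum")


def featurize_sequence(sequence: str, protein_id: str = "protein",
                       mode: str = "esm+blosum",
                       provider: EmbeddingProvider | None = None) -> NodeFeatureMatrix:
    """Build node features in one of three ablation modes.

    ``esm+blosum`` (F=1300, default), ``esm`` (F=1280), ``blosum`` (F=20).
    """
    if mode not in ("esm+blosum", "esm", "blosum"):
        raise ValueError(f"unknown feature mode {mode!r}")
    if mode == "blosum":
        B = encode_blosum62(sequence, protein_id=protein_id).B
        return NodeFeatureMatrix(protein_id=protein_id, H=B, feature_mode=mode)
    provider = provider or EmbeddingProvider("stub", seed=0)
    E = provider.get(protein_id, sequence).E
    if mode == "esm":
        return NodeFeatureMatrix(protein_id=protein_id, H=E, feature_mode=mode)
    return concat_features(
        EmbeddingMatrix(protein_id=protein_id, E=E),
        encode_blosum62(sequence, protein_id=protein_id),
    )


def feature_width(mode: str) -> int:
    return {"esm+blosum": FEATURE_DIM, "esm": EMBED_DIM, "blosum": BLOSUM_DIM}[mode]
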