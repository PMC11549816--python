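"""Synthetic structures, embeddings and labeled datasets with known signal.

Proteins are generated as ideal alpha-helical Calpha traces (rise 1.5 A per
residue, radius 2.3 A, 100 degree turn) with optional coordinate jitter, so
consecutive residues sit ~3.8 A apart and the thresholded contact graph has
realistic local band structure.  Labels are a squashed linear combination of
mean node degree, the mean of a designated embedding column, and inverse
length, plus Gaussian noise, clipped to [0, 1] — a solubility-like continuous
target whose generating weights are returned so tests know the signal.  The
squash gain spreads clean labels across most of [0, 1] (cell-free expression
labels are broadly dispersed toward both extremes), and the small coordinate
jitter keeps the geometric part of the signal dominated by its
length-correlated component, which pooled attention features can recover.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from Bio.SeqUtils import seq3

from .features import AA_ORDER, encode_blosum62, stub_embeddings, \
    write_embeddings, featurize_sequence, EmbeddingProvider
from .graphs import CalphaTrace, compute_distance_map, threshold_adjacency, \
    DEFAULT_CUTOFF
from .train import SolubilityRecord

HELIX_RISE = 1.5      # A per residue
HELIX_RADIUS = 2.3    # A
HELIX_TURN_DEG = 100.0


@dataclass
class FixtureSpec:
    """Conditions of one synthetic dataset."""

    n_proteins: int = 32
    length_range: tuple = (20, 60)
    seed: int = 0
    label_rule: str = "degree+feature+length"
    noise_sd: float = 0.05
    cutoff: float = DEFAULT_CUTOFF
    jitter: float = 0.15
    feature_mode: str = "esm+blosum"
    feature_column: int = 0
    # generating weights of the standardized signals
    w_degree: float = 0.25
    w_feature: float = 0.55
    w_length: float = 0.20
    squash_gain: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 3:
            raise ValueError("minimum length must be >= 3")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        if not (0.0 <= self.noise_sd < 0.5):
            raise ValueError("noise_sd must be in [0, 0.5)")


def make_helix_trace(L: int, seed: int, jitter: float = 0.0,
                     protein_id: str | None = None) -> CalphaTrace:
    """Ideal alpha-helix Calpha trace with a random sequence.

    Deterministic given (L, seed, jitter); ``jitter`` is the per-coordinate
    Gaussian displacement in angstroms.
    """
    if L < 3:
        raise ValueError(f"helix needs L >= 3, got {L}")
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(HELIX_TURN_DEG) * np.arange(L)
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * np.arange(L),
    ])
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, size=coords.shape)
    sequence = "".join(rng.choice(list(AA_ORDER), size=L))
    residues = [(i + 1, aa) for i, aa in enumerate(sequence)]
    return CalphaTrace(protein_id=protein_id or f"helix{L}_{seed}",
                       residues=residues, coords=coords)


def write_min_pdb(trace: CalphaTrace) -> str:
    """Render a trace as minimal CA-only ATOM records (chain A) plus END.

    Coordinates are written at the PDB's fixed 3-decimal precision, so a
    parse round-trip reproduces them to 1e-3 A.
    """
    lines = []
    for serial, ((resseq, aa), xyz) in enumerate(
            zip(trace.residues, trace.coords), start=1):
        res3 = seq3(aa).upper()
        x, y, z = xyz
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3:<3s} A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def make_labeled_dataset(spec: FixtureSpec):
    """Generate ``(records, truth)`` for a fixture dataset.

    Each record carries its contact graph (at ``spec.cutoff``) and node
    features.  The clean label is
    ``sigmoid(gain * (w1*degree_z + w2*feature_z + w3*invlen_z))`` where the
    three signals are standardized across the dataset; Gaussian noise of sd
    ``noise_sd`` is added and the result clipped to [0, 1].  ``truth``
    returns the weights, the per-protein signals and the noise-free labels.
    """
    rng = np.random.default_rng(spec.seed)
    traces, records = [], []
    degrees, feat_means, inv_lengths = [], [], []
    for i in range(spec.n_proteins):
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        trace = make_helix_trace(L, seed=int(rng.integers(2 ** 31)),
                                 jitter=spec.jitter, protein_id=f"fx{i:04d}")
        graph = threshold_adjacency(compute_distance_map(trace), spec.cutoff)
        features = featurize_sequence(
            trace.sequence, protein_id=trace.protein_id,
            mode=spec.feature_mode,
            provider=EmbeddingProvider("stub", seed=spec.seed))
        traces.append(trace)
        records.append(SolubilityRecord(
            id=trace.protein_id, sequence=trace.sequence, graph=graph,
            features=features.H, solubility=0.0))
        A = graph.A.astype(np.float64)
        degrees.append(A.sum() / L - 1.0)          # mean degree, self excluded
        feat_means.append(float(features.H[:, spec.feature_column].mean()))
        inv_lengths.append(1.0 / L)

    zg = _standardize(np.array(degrees))
    zf = _standardize(np.array(feat_means))
    zl = _standardize(np.array(inv_lengths))
    combined = (spec.w_degree * zg + spec.w_feature * zf + spec.w_length * zl)
    clean = _sigmoid(spec.squash_gain * combined)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_proteins) \
        if spec.noise_sd > 0 else np.zeros(spec.n_proteins)
    labels = np.clip(clean + noise, 0.0, 1.0)
    for record, label in zip(records, labels):
        record.solubility = float(label)

    truth = {
        "spec": asdict(spec),
        "weights": {"degree": spec.w_degree, "feature": spec.w_feature,
                    "inv_length": spec.w_length},
        "signals": {"mean_degree": degrees, "feature_mean": feat_means,
                    "inv_length": inv_lengths},
        "clean_labels": clean.tolist(),
        "labels": labels.tolist(),
    }
    return records, traces, truth


def write_fixture_files(spec: FixtureSpec, out_dir) -> Path:
    """Materialize a fixture dataset on disk.

    Emits one PDB and one embedding file per protein, a FASTA of all
    sequences, the dataset CSV (id, sequence, solubility, pdb_path,
    embedding_path) and a ground-truth JSON.  Returns the CSV path.
    """
    out_dir = Path(out_dir)
    (out_dir / "pdb").mkdir(parents=True, exist_ok=True)
    (out_dir / "embeddings").mkdir(parents=True, exist_ok=True)
    records, traces, truth = make_labeled_dataset(spec)

    fasta_path = out_dir / "sequences.fasta"
    with open(fasta_path, "w") as fasta:
        for record, trace in zip(records, traces):
            pdb_path = out_dir / "pdb" / f"{record.id}.pdb"
            pdb_path.write_text(write_min_pdb(trace))
            emb_path = out_dir / "embeddings" / f"{record.id}.emb"
            emb = stub_embeddings(record.sequence, spec.seed,
                                  protein_id=record.id)
            write_embeddings(emb_path, emb)
            fasta.write(f">{record.id}\n{record.sequence}\n")

    csv_path = out_dir / "dataset.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sequence", "solubility", "pdb_path",
                         "embedding_path"])
        # paths are stored relative to the CSV so the dataset is relocatable
        for record in records:
            writer.writerow([
                record.id, record.sequence, f"{record.solubility:.6f}",
                f"pdb/{record.id}.pdb",
                f"embeddings/{record.id}.emb",
            ])
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return csv_path
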