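"""Dataset assembly and the end-to-end pipeline.

Stages: build contact graphs from PDB files -> featurize sequences ->
train -> evaluate.  Every artifact is stamped with the package version, the
configuration hash and the seed; a rerun with the same configuration on one
thread is bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .features import EmbeddingProvider, feature_width, featurize_sequence
from .gat import GATModelConfig, save_checkpoint
from .graphs import build_graph
from .train import (SolubilityRecord, TrainConfig, evaluate, predict,
                    rmse_loss, train, cross_validate)

logger = logging.getLogger(__name__)

DATASET_COLUMNS = ["id", "sequence", "solubility", "pdb_path", "embedding_path"]


class StageError(RuntimeError):
    """Pipeline failure carrying the stage name and the offending record."""

    def __init__(self, stage: str, record_id: str, message: str):
        super().__init__(f"stage {stage!r} failed on record {record_id!r}: "
                         f"{message}")
        self.stage = stage
        self.record_id = record_id


def load_dataset(csv_path) -> pd.DataFrame:
    """Read the dataset table (id, sequence, solubility, pdb_path,
    embedding_path); the last two columns are optional."""
    df = pd.read_csv(csv_path, dtype={"id": str, "sequence": str})
    missing = [c for c in ("id", "sequence", "solubility")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing dataset columns {missing}")
    if df["id"].duplicated().any():
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"{csv_path}: duplicate ids {dupes}")
    return df


def assemble_records(df: pd.DataFrame, config: RunConfig) -> list[SolubilityRecord]:
    """Build graphs and node features for every dataset row."""
    if config.embeddings_dir:
        provider = EmbeddingProvider("file", directory=config.embeddings_dir)
    else:
        provider = EmbeddingProvider("stub", seed=config.stub_seed)
    base = Path(config.dataset).parent
    records = []
    for row in df.itertuples(index=False):
        rid = str(row.id)
        pdb_path = getattr(row, "pdb_path", None)
        if pdb_path is None or (isinstance(pdb_path, float) and np.isnan(pdb_path)):
            raise StageError("build-graph", rid, "no pdb_path in dataset")
        pdb_file = Path(pdb_path)
        if not pdb_file.is_absolute():
            pdb_file = base / pdb_file
        if not pdb_file.exists():
            raise StageError("build-graph", rid, f"missing PDB {pdb_file}")
        try:
            trace, graph = build_graph(pdb_file.read_text(),
                                       cutoff=config.cutoff, protein_id=rid)
        except ValueError as exc:
            raise StageError("build-graph", rid, str(exc)) from exc
        sequence = str(row.sequence)
        if len(trace) != len(sequence):
            logger.warning("%s: trace length %d != sequence length %d; "
                           "using trace sequence", rid, len(trace),
                           len(sequence))
            sequence = trace.sequence
        emb_path = getattr(row, "embedding_path", None)
        row_provider = provider
        if config.embeddings_dir is None and emb_path and \
                not (isinstance(emb_path, float) and np.isnan(emb_path)):
            emb_file = Path(emb_path)
            if not emb_file.is_absolute():
                emb_file = base / emb_path
            row_provider = EmbeddingProvider("file", directory=emb_file.parent)
        try:
            features = featurize_sequence(sequence, protein_id=rid,
                                          mode=config.feature_mode,
                                          provider=row_provider)
        except (ValueError, FileNotFoundError) as exc:
            raise StageError("featurize", rid, str(exc)) from exc
        records.append(SolubilityRecord(id=rid, sequence=sequence,
                                        graph=graph, features=features.H,
                                        solubility=float(row.solubility)))
    return records


def _metadata(config: RunConfig) -> dict:
    return {"tool_version": __version__, "config_hash": config.hash(),
            "seed": config.train.seed}


def holdout_split(records, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_test = max(1, int(round(test_fraction * len(records))))
    test_idx = set(order[:n_test].tolist())
    train_set = [r for i, r in enumerate(records) if i not in test_idx]
    test_set = [r for i, r in enumerate(records) if i in test_idx]
    return train_set, test_set


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts under ``config.out_dir``.

    Returns the evaluation report dictionary (also written as JSON).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_config = config.model
    expected = feature_width(config.feature_mode)
    if model_config.in_features != expected:
        model_config = GATModelConfig(**{**model_config.__dict__,
                                         "in_features": expected})

    logger.info("stage build-graph/featurize: loading %s", config.dataset)
    df = load_dataset(config.dataset)
    records = assemble_records(df, config)

    train_set, test_set = holdout_split(records, config.test_fraction,
                                        config.split_seed)
    logger.info("stage train: %d train / %d test records",
                len(train_set), len(test_set))
    params, history = train(train_set, model_config, config.train,
                            val_records=test_set)
    save_checkpoint(out_dir / "model.npz", params, model_config,
                    feature_mode=config.feature_mode, extra=_metadata(config))

    logger.info("stage evaluate")
    pred = predict(test_set, params, model_config)
    truth = np.array([r.solubility for r in test_set])
    report = evaluate(pred, truth, threshold=config.threshold).as_dict()
    report["train_rmse"] = history["train_rmse"][-1] if history["train_rmse"] else None
    report["test_rmse"] = rmse_loss(pred, truth)
    report["metadata"] = _metadata(config)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out_dir / "history.json", "w") as fh:
        json.dump({"metadata": _metadata(config), **history}, fh, indent=2)
    config.save(out_dir / "config.yaml")
    return report
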