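"""Declarative run configuration: one YAML file drives the whole pipeline.

Defaults equal the tuned settings: 10 A contact cutoff, combined
embedding+substitution features, 2 attention layers, 16 heads, 1024 hidden
channels, learning rate 2e-6, batch size 4, 0.5 solubility threshold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .gat import GATModelConfig
from .train import TrainConfig, SOLUBLE_THRESHOLD


@dataclass
class RunConfig:
    dataset: str = "dataset.csv"
    out_dir: str = "run"
    cutoff: float = 10.0
    feature_mode: str = "esm+blosum"
    embeddings_dir: str | None = None   # None -> deterministic stub provider
    stub_seed: int = 0
    threshold: float = SOLUBLE_THRESHOLD
    test_fraction: float = 0.25
    split_seed: int = 0
    k_folds: int = 5
    model: GATModelConfig = field(default_factory=GATModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        model = GATModelConfig(**data.pop("model", {}))
        train = TrainConfig(**data.pop("train", {}))
        return cls(model=model, train=train, **data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Stable hash of the scientifically meaningful configuration
        (stamped into outputs; the output directory is excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
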