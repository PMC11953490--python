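"""YAML run configuration: one file + seed fully determines a run."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .federation import FederationConfig
from .losses import LossConfig
from .seg_model import NetworkConfig
from .synthetic_data import (
    AugmentConfig,
    SplitDataset,
    build_fixture,
    make_site_dataset,
)

__all__ = ["DataConfig", "RunConfig", "load_run_config", "config_hash",
           "build_datasets"]


@dataclass(frozen=True)
class DataConfig:
    """Which packaged fixture to instantiate and at what scale."""

    fixture: str = "toy4"
    image_size: tuple[int, int] = (64, 64)
    base_seed: int = 0
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/out"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    federation: FederationConfig = field(default_factory=FederationConfig)
    data: DataConfig = field(default_factory=DataConfig)
    checkpoint_every: int = 0

    def to_dict(self) -> dict:
        doc = asdict(self)
        return doc


def _loss_from(doc: dict) -> LossConfig:
    return LossConfig(**doc)


def _federation_from(doc: dict, seed: int) -> FederationConfig:
    doc = dict(doc)
    loss = _loss_from(doc.pop("loss", {}))
    aug_doc = doc.pop("augment", None)
    aug = AugmentConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                           for k, v in aug_doc.items()}) if aug_doc else None
    if "adam_betas" in doc:
        doc["adam_betas"] = tuple(doc["adam_betas"])
    if "partition_patterns" in doc:
        doc["partition_patterns"] = tuple(doc["partition_patterns"])
    doc.setdefault("seed", seed)
    return FederationConfig(loss=loss, augment=aug, **doc)


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    seed = int(doc.get("seed", 0))
    network = NetworkConfig(**doc.get("network", {}))
    federation = _federation_from(doc.get("federation", {}), seed)
    data_doc = dict(doc.get("data", {}))
    for key in ("image_size", "ratios"):
        if key in data_doc:
            data_doc[key] = tuple(data_doc[key])
    data_doc.setdefault("base_seed", seed)
    data = DataConfig(**data_doc)
    return RunConfig(
        seed=seed,
        output_dir=str(doc.get("output_dir", "runs/out")),
        network=network,
        federation=federation,
        data=data,
        checkpoint_every=int(doc.get("checkpoint_every", 0)),
    )


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full configuration (embedded in artifacts)."""
    canonical = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def build_datasets(data: DataConfig) -> tuple[list, list[SplitDataset]]:
    """Instantiate the fixture's site profiles and split datasets."""
    profiles = build_fixture(data.fixture, base_seed=data.base_seed,
                             image_size=data.image_size)
    datasets = [make_site_dataset(p, ratios=data.ratios) for p in profiles]
    return profiles, datasets


def dump_run_config(cfg: RunConfig, path) -> None:
    doc = cfg.to_dict()
    doc["config_hash"] = config_hash(cfg)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
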