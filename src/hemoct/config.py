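"""YAML run configuration: training, augmentation, and architecture blocks."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .augmentation import AugmentationScheme
from .model import ArchitectureSpec, table2_spec
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class RunConfig:
    """Bundle of the three configurable blocks plus the fold seed."""

    def __init__(
        self,
        train: TrainConfig = TrainConfig(),
        augmentation: AugmentationScheme = AugmentationScheme(),
        architecture: ArchitectureSpec | None = None,
        fold_seed: int = 0,
        k: int = 5,
    ):
        self.train = train
        self.augmentation = augmentation
        self.architecture = architecture or table2_spec(n_classes=2, dropout=train.dropout)
        self.fold_seed = fold_seed
        self.k = k

    def to_dict(self) -> dict:
        return {
            "train": asdict(self.train),
            "augmentation": asdict(self.augmentation),
            "architecture": self.architecture.to_dict(),
            "fold_seed": self.fold_seed,
            "k": self.k,
        }


def save_config(cfg: RunConfig, path) -> Path:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return Path(path)


def load_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    aug = d.get("augmentation", {})
    if "rotation_angles_deg" in aug:
        aug["rotation_angles_deg"] = tuple(aug["rotation_angles_deg"])
    return RunConfig(
        train=TrainConfig(**d.get("train", {})),
        augmentation=AugmentationScheme(**aug),
        architecture=(
            ArchitectureSpec.from_dict(d["architecture"]) if "architecture" in d else None
        ),
        fold_seed=int(d.get("fold_seed", 0)),
        k=int(d.get("k", 5)),
    )
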