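"""Architecture and training hyperparameters for the fusion network."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = ["FusionConfig", "TrainConfig"]

_BACKBONES = ("tiny", "resnet18", "resnet34", "resnet50", "resnet101", "vgg16", "vgg19")
_STRATEGIES = ("sum", "concat", "average")
_BRANCHES = ("both", "fcn", "cnn")

_DEFAULT_RESOLUTION = {"tiny": 32}


@dataclass
class FusionConfig:
    """Everything that defines a fusion-network instance, ablations included.

    ``n_groups`` is the number of channel groups refined inside the FEM;
    ``fim_tokens`` is the token count the FIM reshapes feature vectors into
    before scaled dot-product attention; ``branch`` restricts the model to a
    single branch for ablation baselines.
    """

    backbone: str = "resnet50"
    n_classes: int = 10
    n_features: int = 43
    n_groups: int = 3
    use_fem: bool = True
    use_fim: bool = True
    use_mlfm: bool = True
    fusion_strategy: str = "sum"
    fim_tokens: int = 4
    dropout: float = 0.5
    pretrained: bool = False
    input_resolution: int | None = None
    standardize_features: bool = True
    branch: str = "both"
    learned_qkv: bool = False

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {_BACKBONES}")
        if self.fusion_strategy not in _STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.fusion_strategy!r}")
        if self.branch not in _BRANCHES:
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.n_groups < 1 or self.fim_tokens < 1:
            raise ValueError("n_groups and fim_tokens must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.input_resolution is None:
            self.input_resolution = _DEFAULT_RESOLUTION.get(self.backbone, 224)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FusionConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "FusionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TrainConfig:
    """Optimization protocol: Adam at 1e-3 with cosine decay, batch 16."""

    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    cosine_decay: bool = True
    seed: int = 0
    early_stopping: bool = False
    patience: int = 10
    augment: bool = True  # random flips and small shifts on the image branch
    max_shift: int = 2

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
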