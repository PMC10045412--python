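"""Run configuration: one YAML document wiring every module together."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .blocks import StageSpec
from .losses import LossWeights
from .postprocess import PostprocessParams
from .synthetic import SynthConfig

__all__ = ["TrainParams", "NetworkParams", "RunConfig"]


@dataclass(frozen=True)
class TrainParams:
    epochs: int = 10
    batch_size: int = 4
    lr: float = 1e-4
    weight_decay: float = 0.1
    augment: tuple[str, ...] = ()

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class NetworkParams:
    n_types: int = 3
    with_classification: bool = True
    rgs_counts: tuple[int, ...] = (1, 2, 3, 1)
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    dgm_counts: tuple[int, int] = (8, 4)
    growth: int = 32

    def stage_spec(self) -> StageSpec:
        return StageSpec(rgs_counts=self.rgs_counts,
                         stage_channels=self.stage_channels,
                         dgm_counts=self.dgm_counts,
                         growth=self.growth)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "gsnhv_run"
    synth: SynthConfig = field(default_factory=SynthConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    loss: LossWeights = field(default_factory=LossWeights)
    post: PostprocessParams = field(default_factory=PostprocessParams)
    train: TrainParams = field(default_factory=TrainParams)

    _TUPLE_FIELDS = {
        "synth": ("nuclei_per_image", "radius_range"),
        "network": ("rgs_counts", "stage_channels", "dgm_counts"),
        "train": ("augment",),
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        sections = {"synth": SynthConfig, "network": NetworkParams,
                    "loss": LossWeights, "post": PostprocessParams,
                    "train": TrainParams}
        for key, value in raw.items():
            if key in sections:
                sub = dict(value or {})
                for tf in cls._TUPLE_FIELDS.get(key, ()):
                    if tf in sub:
                        sub[tf] = tuple(sub[tf])
                kwargs[key] = sections[key](**sub)
            elif key in ("seed", "output_dir"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config section: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
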