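"""Pipeline configuration: one YAML file drives every command.

The config nests the dataclasses of the individual stages (phantom spec,
augmentation, patch sampling, network, training, evaluation) plus dataset
handling flags and a global seed, and round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Literal

import yaml

from .augment import AxialSubsampleParams, CarveParams, StandardAugmentParams
from .metrics import DEFAULT_MIN_VOLUME_MM3
from .patches import PatchSpec
from .phantom import PhantomSpec
from .nn import NetworkConfig
from .training import AugmentConfig, TrainConfig


@dataclass(frozen=True)
class EvaluationConfig:
    min_volume_mm3: float = DEFAULT_MIN_VOLUME_MM3
    connectivity: Literal[6, 18, 26] = 26
    outside_denominator: Literal["pred", "gt"] = "pred"


@dataclass(frozen=True)
class PipelineConfig:
    train_dir: str = "data/train"
    output_dir: str = "output"
    exclude_no_new_lesion_cases: bool = True
    resample_to_median: bool = True
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    patches: PatchSpec = field(default_factory=PatchSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_tuples_to_lists(self.to_dict()), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name == "phantom":
                kwargs[f.name] = _build(PhantomSpec, val)
            elif f.name == "augmentation":
                kwargs[f.name] = AugmentConfig(
                    standard=_build(StandardAugmentParams, val.get("standard", {})),
                    axial=_build(AxialSubsampleParams, val.get("axial", {})),
                    carve=_build(CarveParams, val.get("carve", {})),
                    enabled=val.get("enabled", True),
                )
            elif f.name == "patches":
                kwargs[f.name] = _build(PatchSpec, val)
            elif f.name == "network":
                kwargs[f.name] = _build(NetworkConfig, val)
            elif f.name == "training":
                kwargs[f.name] = _build(TrainConfig, val)
            elif f.name == "evaluation":
                kwargs[f.name] = _build(EvaluationConfig, val)
            else:
                kwargs[f.name] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Short stable hash of the resolved configuration, for provenance logs."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _tuples_to_lists(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _build(cls: type, raw: dict[str, Any]):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        val = raw[f.name]
        if isinstance(val, list):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)
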