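"""Experiment configuration: the pipeline's hyper-parameters with their
admissible ranges, YAML round-tripping, and resolved-config snapshots.

The four pipeline hyper-parameters are TWS (tensor window size, > 3), SPC
(samples per class, >= 10), SPS (selected patch size, 32-512) and TSS
(tensor step size, >= 1); ranges are enforced at construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantoms import ClassMix, PhantomSpec
from .rankr_fnn import TrainConfig
from .sampling import SPC_MIN, SPS_MAX, SPS_MIN, TWS_MIN_EXCLUSIVE

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, from phantom cohort to training."""

    # data source: synthetic cohort (or an on-disk image directory for `prepare`)
    n_images: int = 12
    image_size: tuple[int, int] = (192, 192)
    class_mix: ClassMix = field(default_factory=ClassMix)
    phantom_overrides: dict = field(default_factory=dict)

    # patch extraction
    sps: int = 64
    scan_step: int = 32
    max_patches: int = 10
    coverage_min: float = 0.9

    # tensorization / sampling
    tws: int = 21
    spc: int = 60
    tss: int = 2

    # model dims
    Q: int = 25
    R: int = 4
    C: int = 3

    train: TrainConfig = field(default_factory=TrainConfig)
    train_fraction: float = 0.30
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.tws <= TWS_MIN_EXCLUSIVE:
            raise ValueError(f"TWS must be > {TWS_MIN_EXCLUSIVE}")
        if self.spc < SPC_MIN:
            raise ValueError(f"SPC must be >= {SPC_MIN}")
        if not SPS_MIN <= self.sps <= SPS_MAX:
            raise ValueError(f"SPS must lie in [{SPS_MIN}, {SPS_MAX}]")
        if self.tss < 1:
            raise ValueError("TSS must be >= 1")
        if self.tws > self.sps:
            raise ValueError("TWS cannot exceed SPS")
        if isinstance(self.class_mix, dict):
            self.class_mix = ClassMix(**self.class_mix)
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)
        if isinstance(self.image_size, list):
            self.image_size = tuple(self.image_size)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(image_size=tuple(self.image_size), seed=self.seed,
                           **self.phantom_overrides)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def write_resolved(self, out_dir) -> Path:
        """Write the fully resolved config next to the run outputs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "config.resolved.yaml"
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)
        return path
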