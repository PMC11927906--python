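"""Run configuration: one YAML document, one global seed, full round-trip.

Every stage seed is derived deterministically from the single global seed,
so a config file plus a seed pins the entire run; no stage reads OS entropy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifier import ClassifierConfig
from .imaging import CropGridSpec
from .preprocessing import AUGMENT_OPS, AugmentationPolicy
from .synthetic import CompoundModel, MorphologyParams, PlateEffectSampler

__all__ = ["RunConfig", "SimulateConfig", "CropConfig", "ScreenCompound",
           "ScreenConfig", "TestSetConfig", "stage_seeds"]

_STAGES = ("simulate", "augment", "foldplan", "classifier", "test", "screen")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Derive one sub-seed (< 2^31) per pipeline stage from the global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(len(_STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(_STAGES, state)}


@dataclass
class SimulateConfig:
    n_plates: int = 7
    wells_per_class: int = 5
    tile_size: int = 200
    gain_log_sd: float = 0.25
    offset_max: float = 0.08
    blur_max_px: float = 0.8


@dataclass
class CropConfig:
    crop_size: int = 256
    overlap_fraction: float = 0.0


@dataclass
class AugmentConfig:
    fraction: float = 0.10
    ops: list = field(default_factory=lambda: sorted(AUGMENT_OPS))


@dataclass
class TrainConfig:
    batch_size: int = 8
    lr: float = 0.1
    lr_decay: float = 0.25
    decay_every: int = 5
    epochs: int = 20


@dataclass
class ScreenCompound:
    ec50: float = 1.0
    hill: float = 1.0
    max_rescue: float = 1.0
    doses: list = field(default_factory=lambda: [0.0, 0.1, 0.3, 1.0, 3.0, 10.0])

    def model(self) -> CompoundModel:
        return CompoundModel(ec50=self.ec50, hill=self.hill, max_rescue=self.max_rescue)


@dataclass
class ScreenConfig:
    compounds: dict = field(default_factory=lambda: {"demo": ScreenCompound()})
    wells_per_dose: int = 3


@dataclass
class TestSetConfig:
    ctl_wells: int = 6
    lps_wells: int = 6


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 0
    out_dir: str = "runs/demo"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    crop: CropConfig = field(default_factory=CropConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_groups: int = 4
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    test_set: TestSetConfig = field(default_factory=TestSetConfig)

    # -- factories for the stage objects ------------------------------------

    def morphology(self) -> MorphologyParams:
        return MorphologyParams()

    def effect_sampler(self) -> PlateEffectSampler:
        return PlateEffectSampler(
            gain_log_sd=self.simulate.gain_log_sd,
            offset_max=self.simulate.offset_max,
            blur_max_px=self.simulate.blur_max_px)

    def crop_spec(self) -> CropGridSpec:
        return CropGridSpec(crop_size=self.crop.crop_size)

    def augment_policy(self, seed: int) -> AugmentationPolicy:
        return AugmentationPolicy(
            fraction=self.augment.fraction, ops=tuple(self.augment.ops), rng_seed=seed)

    def classifier_config(self, n_classes: int, seed: int) -> ClassifierConfig:
        t = self.train
        return ClassifierConfig(
            n_classes=n_classes, batch_size=t.batch_size, lr=t.lr,
            lr_decay=t.lr_decay, decay_every=t.decay_every, epochs=t.epochs,
            seed=seed)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulate" in d:
            d["simulate"] = SimulateConfig(**d["simulate"])
        if "crop" in d:
            d["crop"] = CropConfig(**d["crop"])
        if "augment" in d:
            d["augment"] = AugmentConfig(**d["augment"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        if "screen" in d:
            s = dict(d["screen"])
            s["compounds"] = {k: ScreenCompound(**v) for k, v in s.get("compounds", {}).items()}
            d["screen"] = ScreenConfig(**s)
        if "test_set" in d:
            d["test_set"] = TestSetConfig(**d["test_set"])
        return cls(**d)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
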