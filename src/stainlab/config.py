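"""Pipeline configuration: every fixed constant of the training recipe.

Defaults reproduce the published recipe: marker thresholds 50 (mIHC)
and 100 (DAB), prediction threshold 2 (0-255 scale), dilation 5, CD3
blur kernel 101 with sigma ~11.875, 10% minimum CD3 area per kept tile,
90/10 train/test split, lambda_L1 = 100, lambda_IoU schedule
300 epochs @ 100 then 150 @ 250 (same-section) or 300 @ 250 then
150 @ 500 (serial-section), batch size 350, model input range
[-0.5, 0.5].
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

SAME_SECTION_SCHEDULE = ((300, 100.0), (150, 250.0))
SERIAL_SECTION_SCHEDULE = ((300, 250.0), (150, 500.0))


@dataclass
class PipelineConfig:
    patch_size: int = 256
    mihc_threshold: int = 50
    dab_threshold: int = 100
    pred_threshold: int = 2
    dilation_size: int = 5
    blur_kernel: int = 101
    blur_sigma: float = 11.875
    flag_min_frac: float = 0.10
    train_frac: float = 0.90
    lambda_l1: float = 100.0
    iou_schedule: tuple = SAME_SECTION_SCHEDULE
    batch_size: int = 350
    input_range: tuple = (-0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mihc_threshold", "dab_threshold", "pred_threshold"):
            if not 0 <= getattr(self, name) <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        for name in ("flag_min_frac", "train_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("dilation_size", "blur_kernel"):
            if getattr(self, name) % 2 == 0:
                raise ValueError(f"{name} must be odd")
        self.iou_schedule = tuple((int(e), float(v)) for e, v in self.iou_schedule)
        self.input_range = tuple(self.input_range)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iou_schedule"] = [list(t) for t in self.iou_schedule]
        d["input_range"] = list(self.input_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config; every field must be present in the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data, require_all=True)

    @classmethod
    def from_dict(cls, data: dict, require_all: bool = False) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - names)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        if require_all:
            missing = sorted(names - set(data))
            if missing:
                raise ValueError(f"missing config keys: {', '.join(missing)}")
        return cls(**data)

    def hash(self) -> str:
        """Stable content hash, independent of key order."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
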