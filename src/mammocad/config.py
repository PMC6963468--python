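"""Run configuration shared by the CLI and pipeline helpers.

Defaults follow the reference pipeline where it states values: 16x16
blocks, global artifact threshold 18, k=2 nearest neighbours, forests of
10 trees, ensembles of 10 members, fivefold cross-validation.  The CLAHE
tile grid / clip fraction and the region-growing tolerance are exposed
because the reference leaves them open.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    block_size: tuple[int, int] = (16, 16)
    artifact_threshold: int = 18
    srg_tolerance: float = 32.0
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01
    n_trees: int = 10
    ensemble_size: int = 10
    knn_k: int = 2
    cv_folds: int = 5
    rng_seed: int = 0
    rms_mode: str = "pixel"  # "pixel" or "row_col"
    mask_blocks: bool = False

    def __post_init__(self) -> None:
        self.block_size = tuple(int(v) for v in self.block_size)
        self.clahe_tiles = tuple(int(v) for v in self.clahe_tiles)
        for name in ("n_trees", "ensemble_size", "knn_k", "cv_folds"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if any(v < 1 for v in self.block_size + self.clahe_tiles):
            raise ParameterError("block_size and clahe_tiles entries must be >= 1")
        if not 0 <= self.artifact_threshold <= 255:
            raise ParameterError("artifact_threshold must lie in [0, 255]")
        if not 0 < self.clahe_clip <= 1:
            raise ParameterError("clahe_clip must lie in (0, 1]")
        if self.rms_mode not in ("pixel", "row_col"):
            raise ParameterError("rms_mode must be 'pixel' or 'row_col'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_size"] = list(self.block_size)
        d["clahe_tiles"] = list(self.clahe_tiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
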