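"""Run configuration: one YAML block per pipeline stage, one master seed.

Every random operation draws its generator from :func:`RunConfig.rng`,
which derives a child seed deterministically from the run seed and the
operation name, so a fixed run seed reproduces the whole pipeline
byte-for-byte regardless of execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig"]


def _default_blocks() -> dict:
    return {
        "rosette": {
            "n_tracks": 9,
            "total_time": 120.0,
            "dt": 0.05,
            "radius": 4.0,
            "gap": 0.8,
            "omega": 1.0,
            "q_true": 0.9,
            "speed": 3.6,
            "duration_mean": 1.0,
            "noise_xy": 0.05,
            "axis_diffusivity": 0.05,
        },
        "swarmer": {
            "n_tracks": 6,
            "total_time": 60.0,
            "dt": 1.0 / 208.0,
            "speed": 45.0,
            "duration_mean": 1.0,
        },
        "msd": {"max_lag": 30.0, "ballistic_max": 0.5, "diffusive_min": 5.0},
        "motor": {"angle_threshold": 1.5707963, "speed_floor": 0.5, "window": 0.25},
        "rolling": {"interval": 1.0, "omega_floor": 0.05, "bins": 36, "bandwidth": 0.2617994},
        "hydro": {
            "gaps": [0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0],
            "n_theta": 16,
            "n_phi": 20,
            "n_cells": 25,
            "division_time": 100.0,
            "active_window": 1.0,
        },
        "frames": {"enabled": False, "n_markers": 2000, "pixel_size": 0.1, "image_size": 96},
    }


@dataclass
class RunConfig:
    seed: int = 0
    blocks: dict = field(default_factory=_default_blocks)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(seed=int(raw.get("seed", 0)))
        for key, block in raw.items():
            if key == "seed":
                continue
            if key not in cfg.blocks:
                raise ValueError(f"unknown config block {key!r}")
            cfg.blocks[key].update(block)
        return cfg

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"seed": self.seed, **self.blocks}, sort_keys=True)
        )

    def child_seed(self, name: str) -> int:
        """Deterministic sub-seed (< 2**31) for a named operation."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def rng(self, name: str) -> np.random.Generator:
        return np.random.default_rng(self.child_seed(name))

    def hash(self) -> str:
        payload = json.dumps({"seed": self.seed, **self.blocks}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def as_dict(self) -> dict:
        return {"seed": self.seed, **self.blocks}
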