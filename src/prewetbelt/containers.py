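"""Shared in-memory containers: movies and generator ground truth."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["Movie", "GroundTruth"]


@dataclass
class Movie:
    """Intensity movie with physical calibration.

    Attributes
    ----------
    stack : (T, H, W) ndarray
        Non-negative intensities, arbitrary units.
    pixel_size : float
        Pixel edge in um.
    frame_interval : float
        Time between frames in min.
    """

    stack: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ValueError("movie stack must be (T, H, W)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.stack.size and self.stack.min() < 0:
            raise ValueError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """Generator-side record of everything needed to score an estimator.

    ``records`` holds one dict per generated object (condensate, trace,
    cluster set, ...); ``params`` the generating parameters, including
    the seed. Serializes to JSON.
    """

    kind: str
    seed: int | None
    params: dict[str, Any] = field(default_factory=dict)
    records: list[dict[str, Any]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "seed": self.seed,
            "params": _jsonable(self.params),
            "records": _jsonable(self.records),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            kind=d["kind"],
            seed=d["seed"],
            params=d.get("params", {}),
            records=d.get("records", []),
        )
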