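"""Run configuration: defaults, YAML round trip, provenance.

The packaged defaults are the calibrated study conditions: chi = 3.5,
kappa = 4 (interface width about 4 px), Gamma = 1, mu_bulk = -3,
off-stripe tilt eps0 + mu_bulk = -0.6 kT (dilute favoured), stripe
half-width 4, one nucleation disc of radius 6 at the stripe centre with
eps_nuc = 0.6 kT, dt = 0.012. Under these conditions the 2D pinning
threshold lies between relative affinities 0.28 and 0.31.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
import yaml

from . import __version__
from .model import AffinityField, GridGeometry, ModelParams, build_affinity_landscape

__all__ = ["RunConfig", "load_config", "save_config", "default_config"]


@dataclass
class RunConfig:
    """All parameters of a simulation/scan run, with sane defaults."""

    geometry: dict = field(
        default_factory=lambda: {
            "n_across": 128,
            "n_along": 512,
            "spacing": 1.0,
            "stripe_halfwidth": 4,
        }
    )
    params: dict = field(
        default_factory=lambda: {
            "chi": 3.5,
            "kappa": 4.0,
            "gamma": 1.0,
            "mu_bulk": -3.0,
            "dt": 0.012,
        }
    )
    affinity: dict = field(
        default_factory=lambda: {
            "eps0": 2.4,
            "eps_int": 3.43,  # delta_eps_bar = 0.43 with mu_bulk = -3
            "eps_nuc": 0.6,
            "sites": [[64, 256, 6]],
        }
    )
    run: dict = field(
        default_factory=lambda: {
            "n_steps": 20000,
            "snapshot_stride": 200,
            "seed": 0,
            "seed_discs": True,
            "init_noise": 0.0,
        }
    )
    provenance: dict | None = None

    _SECTIONS = ("geometry", "params", "affinity", "run")

    def to_dict(self, with_provenance: bool = True) -> dict:
        d = {k: dict(getattr(self, k)) for k in self._SECTIONS}
        if with_provenance and self.provenance:
            d["provenance"] = dict(self.provenance)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(with_provenance=False), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stamp_provenance(self) -> "RunConfig":
        return replace(
            self,
            provenance={
                "package_version": __version__,
                "timestamp": datetime.now(timezone.utc).isoformat(),
                "config_hash": self.config_hash(),
            },
        )

    # -- builders ---------------------------------------------------
    def build_geometry(self) -> GridGeometry:
        return GridGeometry(**self.geometry)

    def build_params(self) -> ModelParams:
        return ModelParams(**self.params)

    def build_affinity(self, geometry: GridGeometry | None = None) -> AffinityField:
        geometry = geometry or self.build_geometry()
        aff = dict(self.affinity)
        sites = [tuple(s) for s in aff.pop("sites", [])]
        return build_affinity_landscape(geometry, sites=sites, **aff)


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load YAML/JSON config; unknown keys are rejected by name.

    Missing sections or keys are filled with the packaged defaults; an
    empty (or absent) file yields all defaults.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = set(RunConfig._SECTIONS) | {"provenance"}
    for section in data:
        if section not in known:
            raise ValueError(f"unknown config section: {section!r}")
    for section in RunConfig._SECTIONS:
        overrides = data.get(section) or {}
        base = getattr(cfg, section)
        for key, value in overrides.items():
            if key not in base:
                raise ValueError(f"unknown config key: {section}.{key!r}")
            base[key] = value
    if "provenance" in data:
        cfg.provenance = data["provenance"]
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved config (with a provenance stamp) as YAML."""
    stamped = cfg.stamp_provenance()
    Path(path).write_text(yaml.safe_dump(stamped.to_dict(), sort_keys=False))
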