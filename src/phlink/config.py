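"""Study configuration: one YAML file drives every pipeline stage.

Defaults follow the conventions the analyses were designed around:
dissociation thresholds 3.3 nm COM distance / 1.2 nm RMSD, ACF threshold
0.1, ion-grid mesh 1 Å with 2 Å KDE bandwidth, SASA probe 0.14 nm, and
pH_ref equal to the lowest sampled pH. Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["AnalysisConfig", "OccupancyEntry", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration."""


@dataclass(frozen=True)
class OccupancyEntry:
    path: str
    form: str
    pH: float
    replicate: str = "r1"


_DEFAULTS: dict[str, Any] = {
    "temperature": 300.0,
    "pH_ref": None,  # None → lowest sampled pH
    "units": "kj",
    "seed": 1,
    "equilibration_ps": 0.0,
    "bootstrap": {"B": 100, "block_ps": 1000.0},
    "thresholds": {
        "d_max_nm": 3.3,
        "rmsd_max_nm": 1.2,
        "acf_threshold": 0.1,
        "correlation_cutoff": 0.15,
    },
    "grids": {
        "ion_mesh_A": 1.0,
        "ion_bandwidth_A": 2.0,
        "contour_mM": 200.0,
        "landscape_mesh": 0.2,
        "bulk_mM": 150.0,
    },
    "sasa": {"probe_nm": 0.14, "n_sphere_points": 960},
    "contact_area_convention": "half",
    "occupancy": [],
    "experimental": None,
    "potential_dx": None,
    "ion_tracks": None,
    "structures": None,
    "max_lag_ps": 10000.0,
}


@dataclass
class AnalysisConfig:
    raw: dict[str, Any]
    base_dir: Path = field(default_factory=Path)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    @property
    def occupancy_entries(self) -> list[OccupancyEntry]:
        out = []
        for e in self.raw["occupancy"]:
            out.append(
                OccupancyEntry(
                    path=str(e["path"]),
                    form=str(e["form"]),
                    pH=float(e["pH"]),
                    replicate=str(e.get("replicate", "r1")),
                )
            )
        return out

    def resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = dict(defaults)
    for k, v in given.items():
        if k not in defaults:
            raise ConfigError(f"unknown configuration key {path + k!r}")
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            out[k] = _merge(defaults[k], v, path + k + ".")
        else:
            out[k] = v
    return out


def load_config(path: str | Path, *, check_files: bool = True) -> AnalysisConfig:
    """Load and validate a YAML configuration."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        given = yaml.safe_load(fh) or {}
    if not isinstance(given, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    raw = _merge(_DEFAULTS, given)
    if raw["units"] not in ("kj", "kcal"):
        raise ConfigError("units must be 'kj' or 'kcal'")
    if raw["contact_area_convention"] not in ("half", "full"):
        raise ConfigError("contact_area_convention must be 'half' or 'full'")
    cfg = AnalysisConfig(raw=raw, base_dir=path.parent)
    if check_files:
        for e in cfg.occupancy_entries:
            p = cfg.resolve(e.path)
            if not p.exists():
                raise ConfigError(f"occupancy file not found: {p}")
        for key in ("experimental", "potential_dx"):
            if raw[key] and not cfg.resolve(raw[key]).exists():
                raise ConfigError(f"{key} file not found: {cfg.resolve(raw[key])}")
        if raw["ion_tracks"]:
            for species, p in raw["ion_tracks"].items():
                if not cfg.resolve(p).exists():
                    raise ConfigError(
                        f"ion track for {species} not found: {cfg.resolve(p)}"
                    )
        if raw["structures"]:
            for key in ("reference", "trajectory"):
                p = raw["structures"].get(key)
                if p and not cfg.resolve(p).exists():
                    raise ConfigError(
                        f"structure {key} not found: {cfg.resolve(p)}"
                    )
    return cfg
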