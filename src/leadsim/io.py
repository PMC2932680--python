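"""Configuration files, agent-roster I/O and run manifests.

The agent roster dialect is a whitespace-delimited text table of 10 rows by
n agents: identity, body mass (kg), daily protein and energy requirements,
protein and energy intake rates, daily water requirement, daily social and
resting time requirements, and category label.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import environment as env
from .parameters import AgentSpec, GroupSpec, NeedKind, build_dyad_group, build_macaque_group
from .simulator import SimConfig

__all__ = ["load_config", "save_config", "read_attributes", "write_attributes",
           "RunManifest", "AttributesFormatError"]

# configuration schema: key -> (validator, default)
_CONFIG_KEYS = {
    "model": (lambda v: v in ("dyad", "macaque"), "macaque"),
    "condition": (lambda v: v in (1, 2, 3), 1),
    "group_index": (lambda v: isinstance(v, int) and 1 <= v <= 10, 1),
    "n": (lambda v: isinstance(v, int) and 2 <= v <= 20, 10),
    "heterogeneous": (lambda v: isinstance(v, bool), True),
    "group_seed": (lambda v: isinstance(v, int) and v >= 0, 0),
    "attributes_file": (lambda v: v is None or isinstance(v, str), None),
    "days": (lambda v: isinstance(v, int) and v >= 1, 90),
    "replicates": (lambda v: isinstance(v, int) and v >= 1, 1000),
    "seed": (lambda v: isinstance(v, int) and v >= 0, 0),
    "deterministic": (lambda v: isinstance(v, bool), False),
    "normalizer": (lambda v: v in ("group_mean", "own"), "group_mean"),
    "bout_mode": (lambda v: v in ("takeover", "until_full"), "takeover"),
    "layout": (lambda v: v is None or isinstance(v, str), None),
}


def _build_group(cfg: dict) -> GroupSpec:
    if cfg["attributes_file"]:
        agents = read_attributes(cfg["attributes_file"])
        return GroupSpec(agents=agents, model_variant="macaque",
                         label=Path(cfg["attributes_file"]).stem)
    if cfg["model"] == "dyad":
        return build_dyad_group(cfg["condition"], cfg["group_index"])
    return build_macaque_group(cfg["n"], cfg["heterogeneous"], cfg["group_seed"],
                               allow_any_size=True)


def load_config(path: str | Path) -> SimConfig:
    """Load a simulation configuration from YAML or JSON.

    Every omitted key takes its standard default (one-minute timestep,
    90 days, 1000 replicates, 96x96 torus, 0.4 m/s walking speed are built
    into the simulator).  Unknown keys and out-of-range values are rejected
    with the offending key named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = {}
    for key, value in raw.items():
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}: unknown configuration key {key!r}")
        validator, _ = _CONFIG_KEYS[key]
        if not validator(value):
            raise ValueError(f"{path}: invalid value for {key!r}: {value!r}")
        cfg[key] = value
    for key, (_, default) in _CONFIG_KEYS.items():
        cfg.setdefault(key, default)
    layout = None
    if cfg["layout"] not in (None, "default"):
        layout = env.layout_from_json(Path(cfg["layout"]).read_text())
    group = _build_group(cfg)
    return SimConfig(
        group=group,
        layout=layout,
        max_days=cfg["days"],
        replicates=cfg["replicates"],
        rng_seed=cfg["seed"],
        deterministic=cfg["deterministic"],
        normalizer=cfg["normalizer"],
        bout_mode=cfg["bout_mode"],
    )


def save_config(cfg: dict, path: str | Path) -> None:
    """Write a configuration mapping as YAML (schema-validated)."""
    for key in cfg:
        if key not in _CONFIG_KEYS:
            raise ValueError(f"unknown configuration key {key!r}")
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


class AttributesFormatError(ValueError):
    pass


_ATTR_ROWS = 10


def read_attributes(path: str | Path) -> list[AgentSpec]:
    """Read an agent roster in the 10-row attributes dialect.

    Requirements in the file override the mass formulas.  Water, social
    and rest intake rates are category-level and not stored in the file.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) != _ATTR_ROWS:
        raise AttributesFormatError(
            f"{path}: expected {_ATTR_ROWS} non-empty rows, found {len(lines)}")
    rows = [ln.split() for ln in lines]
    ncols = len(rows[0])
    for i, row in enumerate(rows, start=1):
        if len(row) != ncols:
            raise AttributesFormatError(
                f"{path}: line {i} has {len(row)} columns, expected {ncols}")
    agents = []
    for c in range(ncols):
        try:
            mass = float(rows[1][c])
            protein = float(rows[2][c])
            energy = float(rows[3][c])
            intake_p = float(rows[4][c])
            intake_e = float(rows[5][c])
            water = float(rows[6][c])
            social = float(rows[7][c])
            rest = float(rows[8][c])
        except ValueError as err:
            raise AttributesFormatError(f"{path}: column {c + 1}: {err}") from err
        agents.append(
            AgentSpec(
                id=rows[0][c],
                category=rows[9][c],
                mass_kg=mass,
                daily_requirement={
                    NeedKind.PROTEIN: protein,
                    NeedKind.ENERGY: energy,
                    NeedKind.WATER: water,
                    NeedKind.SOCIAL: social,
                    NeedKind.REST: rest,
                },
                intake={NeedKind.PROTEIN: intake_p, NeedKind.ENERGY: intake_e},
            )
        )
    return agents


def write_attributes(agents: list[AgentSpec], path: str | Path) -> None:
    """Write a roster in the same 10-row dialect the reader accepts."""
    rows = [
        [a.id for a in agents],
        [f"{a.mass_kg:.6g}" for a in agents],
        [f"{a.daily_requirement[NeedKind.PROTEIN]:.6g}" for a in agents],
        [f"{a.daily_requirement[NeedKind.ENERGY]:.6g}" for a in agents],
        [f"{a.intake[NeedKind.PROTEIN]:.6g}" for a in agents],
        [f"{a.intake[NeedKind.ENERGY]:.6g}" for a in agents],
        [f"{a.daily_requirement[NeedKind.WATER]:.6g}" for a in agents],
        [f"{a.daily_requirement[NeedKind.SOCIAL]:.6g}" for a in agents],
        [f"{a.daily_requirement[NeedKind.REST]:.6g}" for a in agents],
        [a.category for a in agents],
    ]
    Path(path).write_text("\n".join("\t".join(row) for row in rows) + "\n")


@dataclass
class RunManifest:
    """Reproducibility record attached to every output artifact."""

    config: dict
    root_seed: int
    package_version: str
    created: str
    checksums: dict[str, str]

    @classmethod
    def create(cls, config: dict, root_seed: int,
               outputs: dict[str, str | Path] | None = None) -> "RunManifest":
        checksums = {}
        for name, p in (outputs or {}).items():
            checksums[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        return cls(
            config=config,
            root_seed=root_seed,
            package_version=__version__,
            created=time.strftime("%Y-%m-%dT%H:%M:%S"),
            checksums=checksums,
        )

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "root_seed": self.root_seed,
            "package_version": self.package_version,
            "created": self.created,
            "checksums": self.checksums,
        }
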