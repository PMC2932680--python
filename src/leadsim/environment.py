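"""Torus world, resource areas and group travel.

The world is a 96 x 96 m wrap-around grid (1 m cells). Resource areas are
fixed circles; the dyad variant has one area per need, the five-need variant
has a protein patch, an energy patch, a waterhole and a resting site. All
pairwise area distances must lie within 25-75 m, matching day-journey legs
of medium-bodied primates. The group travels as a single point at
0.4 m/s = 24 m per one-minute step.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

TORUS_SIZE = 96.0  # metres (= cells, 1 m each)
AREA_RADIUS = 2.0  # metres
SPEED_M_PER_MIN = 24.0  # 0.4 m/s
MIN_AREA_DISTANCE = 25.0
MAX_AREA_DISTANCE = 75.0

#: area roles in kernel order for the five-need variant
MACAQUE_ROLES = ("protein_patch", "energy_patch", "waterhole", "resting_site")
DYAD_ROLES = ("need1_patch", "need2_patch")


@dataclass(frozen=True)
class Area:
    role: str
    x: float
    y: float
    radius: float = AREA_RADIUS

    def to_dict(self) -> dict:
        return {"role": self.role, "x": self.x, "y": self.y, "radius": self.radius}


def wrap(v: float, size: float = TORUS_SIZE) -> float:
    return v % size


def toroidal_delta(a: float, b: float, size: float = TORUS_SIZE) -> float:
    """Signed shortest displacement from a to b along one axis."""
    d = (b - a) % size
    if d > size / 2:
        d -= size
    return d


def toroidal_distance(p: Sequence[float], q: Sequence[float], size: float = TORUS_SIZE) -> float:
    """Shortest wrapped Euclidean distance between two points."""
    dx = toroidal_delta(p[0], q[0], size)
    dy = toroidal_delta(p[1], q[1], size)
    return math.hypot(dx, dy)


def travel_time_minutes(distance_m: float) -> int:
    """Whole-minute point-to-point travel time at walking speed."""
    return int(math.ceil(distance_m / SPEED_M_PER_MIN))


def travel(position: Sequence[float], target: Area, minutes: int = 1) -> tuple[tuple[float, float], bool]:
    """Advance ``minutes`` one-minute steps toward ``target``.

    Moves along the shortest toroidal straight line at 24 m/min, never
    overshooting the area centre; arrival = within the area radius at the
    end of a step.
    """
    if minutes < 1 or int(minutes) != minutes:
        raise ValueError("minutes must be a positive integer")
    x, y = float(position[0]), float(position[1])
    for _ in range(int(minutes)):
        dx = toroidal_delta(x, target.x)
        dy = toroidal_delta(y, target.y)
        dist = math.hypot(dx, dy)
        if dist <= target.radius:
            return (x, y), True
        step = min(SPEED_M_PER_MIN, dist)
        x = wrap(x + dx / dist * step)
        y = wrap(y + dy / dist * step)
        if toroidal_distance((x, y), (target.x, target.y)) <= target.radius:
            return (x, y), True
    return (x, y), False


START_POSITION = (TORUS_SIZE / 2, TORUS_SIZE / 2)  # middle of the torus

# Default fixed layouts. Coordinates are a package design choice (the world
# layout is fixed but unprinted): areas sit at the corners of a centred
# square, so the group's start at the torus middle is exactly equidistant
# (33.9 m) from every area and the pairwise separations (48 m sides,
# 67.9 m toroidal diagonals) fill out the stated 25-75 m travel band.
DEFAULT_MACAQUE_LAYOUT = (
    Area("protein_patch", 24.0, 24.0),
    Area("energy_patch", 72.0, 24.0),
    Area("waterhole", 24.0, 72.0),
    Area("resting_site", 72.0, 72.0),
)
DEFAULT_DYAD_LAYOUT = (
    Area("need1_patch", 24.0, 48.0),
    Area("need2_patch", 72.0, 48.0),
)


def validate_layout(areas: Sequence[Area]) -> None:
    """Reject layouts violating the pairwise 25-75 m distance constraint."""
    for i in range(len(areas)):
        for j in range(i + 1, len(areas)):
            d = toroidal_distance((areas[i].x, areas[i].y), (areas[j].x, areas[j].y))
            if not MIN_AREA_DISTANCE <= d <= MAX_AREA_DISTANCE:
                raise ValueError(
                    f"areas {areas[i].role} and {areas[j].role} are {d:.1f} m apart; "
                    f"must be within [{MIN_AREA_DISTANCE}, {MAX_AREA_DISTANCE}] m"
                )


def place_areas(variant: str, rng_seed: int | None = None) -> tuple[Area, ...]:
    """Return a validated area layout for a model variant.

    ``rng_seed=None`` gives the deterministic default layout; an integer
    seed draws a random layout satisfying the distance constraint.
    """
    roles = {"dyad": DYAD_ROLES, "macaque": MACAQUE_ROLES}.get(variant)
    if roles is None:
        raise ValueError(f"unknown variant {variant!r}")
    if rng_seed is None:
        layout = DEFAULT_DYAD_LAYOUT if variant == "dyad" else DEFAULT_MACAQUE_LAYOUT
        validate_layout(layout)
        return layout
    rng = np.random.default_rng(rng_seed)
    for _ in range(10_000):
        pts = rng.uniform(0, TORUS_SIZE, size=(len(roles), 2))
        areas = tuple(Area(role, float(x), float(y)) for role, (x, y) in zip(roles, pts))
        try:
            validate_layout(areas)
        except ValueError:
            continue
        return areas
    raise RuntimeError("failed to sample a layout satisfying the distance constraint")


def layout_to_json(areas: Sequence[Area]) -> str:
    return json.dumps([a.to_dict() for a in areas], indent=2)


def layout_from_json(text: str) -> tuple[Area, ...]:
    payload = json.loads(text)
    areas = tuple(Area(a["role"], float(a["x"]), float(a["y"]), float(a.get("radius", AREA_RADIUS)))
                  for a in payload)
    validate_layout(areas)
    return areas
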