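"""Agents, needs, and group composition.

Two model variants are supported:

* **dyad** — two agents with two abstract needs whose daily requirement
  values come from a printed design table (three experimental conditions,
  ten groups each);
* **macaque** — 5 to 20 agents drawn from five age/sex categories (adult
  male, adult cycling female, lactating female, subadult, juvenile) with
  five needs: protein (g), energy (KJ), water (ml), social time (min) and
  resting time (min).

Nutrient requirements scale with body mass (protein 2.54 g/day/kg, energy
351.7 KJ/day/kg, water 0.24 ml/KJ); lactating females carry a 1.25x protein
and 2x energy multiplier (water follows energy). Social and resting time
requirements are category-level draws, independent of mass. A requirement
doubles as the capacity of the corresponding physiological reserve.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NeedKind",
    "MACAQUE_NEEDS",
    "DYAD_NEEDS",
    "Category",
    "CATEGORY_TABLE",
    "AgentSpec",
    "GroupSpec",
    "nutrient_requirements",
    "build_dyad_group",
    "build_macaque_group",
    "dyad_requirement_table",
    "COMPOSITION_TABLE",
    "sample_composition",
]

# --- needs ------------------------------------------------------------------


class NeedKind(str, Enum):
    """A physiological or social reserve an agent must keep above zero."""

    PROTEIN = "protein"
    ENERGY = "energy"
    WATER = "water"
    SOCIAL = "social"
    REST = "rest"
    NEED1 = "need1"
    NEED2 = "need2"

    @property
    def unit(self) -> str:
        return _NEED_UNITS[self]


_NEED_UNITS = {
    NeedKind.PROTEIN: "g",
    NeedKind.ENERGY: "KJ",
    NeedKind.WATER: "ml",
    NeedKind.SOCIAL: "min",
    NeedKind.REST: "min",
    NeedKind.NEED1: "unit",
    NeedKind.NEED2: "unit",
}

#: canonical need order for each model variant (index order is what the
#: simulation kernel uses)
MACAQUE_NEEDS: tuple[NeedKind, ...] = (
    NeedKind.PROTEIN,
    NeedKind.ENERGY,
    NeedKind.WATER,
    NeedKind.SOCIAL,
    NeedKind.REST,
)
DYAD_NEEDS: tuple[NeedKind, ...] = (NeedKind.NEED1, NeedKind.NEED2)

# requirement scaling constants (per kg of body mass, per day)
PROTEIN_PER_KG = 2.54  # g/day/kg
ENERGY_PER_KG = 351.7  # KJ/day/kg
WATER_PER_KJ = 0.24  # ml per KJ of energy requirement
LACTATING_PROTEIN_FACTOR = 1.25
LACTATING_ENERGY_FACTOR = 2.0

# --- categories -------------------------------------------------------------


@dataclass(frozen=True)
class Category:
    """An age/sex class with its empirical mass, time-requirement and
    intake-rate statistics (mean, sd pairs)."""

    name: str
    mass_kg: tuple[float, float]
    social_req_min: tuple[float, float]
    rest_req_min: tuple[float, float]
    intake_protein: tuple[float, float]  # g/min
    intake_energy: tuple[float, float]  # KJ/min
    lactating: bool = False

    def __post_init__(self) -> None:
        if self.mass_kg[0] <= 0:
            raise ValueError(f"category {self.name}: mean mass must be > 0")


# water/social/rest intake rates do not differ between categories
INTAKE_WATER = (50.0, 25.0)  # ml/min
INTAKE_SOCIAL = (1.0, 0.5)  # min/min
INTAKE_REST = (1.0, 0.5)  # min/min

CATEGORY_TABLE: dict[str, Category] = {
    "adult_male": Category(
        "adult_male",
        mass_kg=(15.18, 1.34),
        social_req_min=(100.0, 50.41),
        rest_req_min=(87.50, 55.71),
        intake_protein=(0.217, 0.108),
        intake_energy=(41.9, 23.1),
    ),
    "cycling_female": Category(
        "cycling_female",
        mass_kg=(9.62, 2.39),
        social_req_min=(112.73, 19.89),
        rest_req_min=(50.91, 33.52),
        intake_protein=(0.217, 0.108),
        intake_energy=(38.9, 18.7),
    ),
    "lactating_female": Category(
        "lactating_female",
        mass_kg=(9.85, 1.04),
        social_req_min=(86.67, 30.688),
        rest_req_min=(106.67, 37.41),
        intake_protein=(0.217, 0.108),
        intake_energy=(38.2, 20.2),
        lactating=True,
    ),
    "subadult": Category(
        "subadult",
        mass_kg=(4.43, 0.66),
        social_req_min=(170.53, 30.09),
        rest_req_min=(30.0, 28.72),
        intake_protein=(0.202, 0.101),
        intake_energy=(28.4, 15.2),
    ),
    # juvenile protein intake sd printed as 0.63 in the source table, an
    # order-of-magnitude outlier against mean 0.126; we use 0.063 (every
    # other cell has sd ~ mean/2)
    "juvenile": Category(
        "juvenile",
        mass_kg=(3.33, 1.43),
        social_req_min=(176.67, 14.14),
        rest_req_min=(80.83, 33.80),
        intake_protein=(0.126, 0.063),
        intake_energy=(23.7, 11.2),
    ),
}

MASS_FLOOR_KG = 0.5  # truncation of Normal mass draws
TIME_REQ_FLOOR_MIN = 5.0  # floor for drawn social/rest daily requirements


# --- agent / group specs ----------------------------------------------------


@dataclass
class AgentSpec:
    """One simulated individual.

    ``daily_requirement[k]`` is simultaneously the capacity of reserve *k*.
    ``intake`` holds fixed per-individual intake rates (units/min); needs
    missing from it use per-minute category-level noise draws instead.
    """

    id: str
    category: str
    mass_kg: float
    daily_requirement: dict[NeedKind, float]
    intake: dict[NeedKind, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError(f"agent {self.id}: mass must be > 0")
        for k, v in self.daily_requirement.items():
            if v <= 0:
                raise ValueError(f"agent {self.id}: requirement {k} must be > 0")


@dataclass
class GroupSpec:
    """An ordered roster of agents sharing one model variant."""

    agents: list[AgentSpec]
    model_variant: str  # "dyad" | "macaque"
    label: str = ""

    def __post_init__(self) -> None:
        if not 2 <= len(self.agents) <= 20:
            raise ValueError("group size must be between 2 and 20")
        if self.model_variant not in ("dyad", "macaque"):
            raise ValueError(f"unknown model variant {self.model_variant!r}")
        needsets = {tuple(sorted(a.daily_requirement)) for a in self.agents}
        if len(needsets) != 1:
            raise ValueError("all agents in a group must share one need set")

    @property
    def needs(self) -> tuple[NeedKind, ...]:
        return DYAD_NEEDS if self.model_variant == "dyad" else MACAQUE_NEEDS

    @property
    def n(self) -> int:
        return len(self.agents)

    def requirement_matrix(self) -> np.ndarray:
        """(n_agents, n_needs) array of requirements in need order."""
        return np.array(
            [[a.daily_requirement[k] for k in self.needs] for a in self.agents]
        )

    def to_json(self) -> str:
        payload = {
            "model_variant": self.model_variant,
            "label": self.label,
            "agents": [
                {
                    "id": a.id,
                    "category": a.category,
                    "mass_kg": a.mass_kg,
                    "daily_requirement": {k.value: v for k, v in a.daily_requirement.items()},
                    "intake": {k.value: v for k, v in a.intake.items()},
                }
                for a in self.agents
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroupSpec":
        payload = json.loads(text)
        agents = [
            AgentSpec(
                id=a["id"],
                category=a["category"],
                mass_kg=a["mass_kg"],
                daily_requirement={NeedKind(k): v for k, v in a["daily_requirement"].items()},
                intake={NeedKind(k): v for k, v in a["intake"].items()},
            )
            for a in payload["agents"]
        ]
        return cls(agents=agents, model_variant=payload["model_variant"], label=payload.get("label", ""))


# --- requirement formulas ---------------------------------------------------


def nutrient_requirements(category: str, mass_kg: float) -> dict[NeedKind, float]:
    """Mass-scaled daily nutrient requirements for one individual.

    protein = 2.54 g/kg, energy = 351.7 KJ/kg, water = 0.24 ml per KJ of the
    energy requirement.  Lactating females get 1.25x protein and 2x energy;
    water follows the (already doubled) energy requirement.  Social and
    resting requirements are not mass-scaled and are not returned here.
    """
    if mass_kg <= 0:
        raise ValueError(f"mass must be positive, got {mass_kg}")
    if category not in CATEGORY_TABLE:
        raise ValueError(f"unknown category {category!r}")
    protein = PROTEIN_PER_KG * mass_kg
    energy = ENERGY_PER_KG * mass_kg
    if CATEGORY_TABLE[category].lactating:
        protein *= LACTATING_PROTEIN_FACTOR
        energy *= LACTATING_ENERGY_FACTOR
    water = WATER_PER_KJ * energy
    return {NeedKind.PROTEIN: protein, NeedKind.ENERGY: energy, NeedKind.WATER: water}


# --- dyad groups ------------------------------------------------------------

# requirement design table: three conditions x ten groups x (a1, a2, b1, b2)
_C1 = [500, 600, 700, 800, 900, 1100, 1200, 1300, 1400, 1500]


def dyad_requirement_table() -> dict[tuple[int, int], tuple[float, float, float, float]]:
    """All 120 design-table cells as {(condition, group): (a1, a2, b1, b2)}."""
    table: dict[tuple[int, int], tuple[float, float, float, float]] = {}
    for g in range(1, 11):
        v = float(_C1[g - 1])
        table[(1, g)] = (v, v, v, v)
        table[(2, g)] = (v, float(_C1[10 - g]), float(_C1[10 - g]), v)
        a = 1000.0 + 50.0 * (g - 1)
        table[(3, g)] = (a, a, 1000.0, 1000.0)
    return table


# reference requirement at which the dyad per-minute drain equals its
# nominal printed value of 0.07 units/min (sd half the mean); drains scale
# proportionally with the requirement
DYAD_DRAIN_AT_1000 = 0.07
DYAD_DRAIN_REFERENCE = 1000.0
DYAD_INTAKE = 10.0  # units/min, both needs, both agents


def build_dyad_group(condition: int, group_index: int) -> GroupSpec:
    """Two-agent group with requirements from the printed design table."""
    if condition not in (1, 2, 3):
        raise ValueError(f"condition must be 1, 2 or 3, got {condition}")
    if not 1 <= group_index <= 10:
        raise ValueError(f"group_index must be in 1..10, got {group_index}")
    a1, a2, b1, b2 = dyad_requirement_table()[(condition, group_index)]
    agents = [
        AgentSpec(
            id="A",
            category="dyad",
            mass_kg=1.0,
            daily_requirement={NeedKind.NEED1: a1, NeedKind.NEED2: a2},
            intake={NeedKind.NEED1: DYAD_INTAKE, NeedKind.NEED2: DYAD_INTAKE},
        ),
        AgentSpec(
            id="B",
            category="dyad",
            mass_kg=1.0,
            daily_requirement={NeedKind.NEED1: b1, NeedKind.NEED2: b2},
            intake={NeedKind.NEED1: DYAD_INTAKE, NeedKind.NEED2: DYAD_INTAKE},
        ),
    ]
    return GroupSpec(agents=agents, model_variant="dyad", label=f"dyad-c{condition}-g{group_index}")


# AgentSpec validation requires a known category; register a pseudo-category
# for dyad agents
CATEGORY_TABLE.setdefault(
    "dyad",
    Category(
        "dyad",
        mass_kg=(1.0, 0.0),
        social_req_min=(1.0, 0.0),
        rest_req_min=(1.0, 0.0),
        intake_protein=(0.0, 0.0),
        intake_energy=(0.0, 0.0),
    ),
)


# --- macaque groups ---------------------------------------------------------

#: composition statistics for groups of 10: (mean, sd, min, max) individuals
COMPOSITION_TABLE: dict[str, tuple[float, float, int, int]] = {
    "adult_male": (1.6, 0.7, 1, 3),
    "cycling_female": (3.1, 1.3, 2, 6),
    "lactating_female": (1.7, 1.3, 0, 4),
    "subadult": (1.9, 1.3, 0, 4),
    "juvenile": (1.8, 0.9, 0, 3),
}

_CATEGORY_ORDER = list(COMPOSITION_TABLE)

HOMOGENEOUS_CATEGORY = "cycling_female"


def sample_composition(n: int, rng: np.random.Generator) -> dict[str, int]:
    """Draw per-category counts summing to ``n``.

    Counts are drawn from the empirical Normal(mean, sd) statistics (scaled
    by n/10 for other group sizes), rounded, clipped to the scaled min/max
    bounds, then repaired to sum to ``n`` by adjusting the currently largest
    adjustable category.
    """
    scale = n / 10.0
    bounds = {}
    counts = {}
    for cat, (mean, sd, lo, hi) in COMPOSITION_TABLE.items():
        lo_s = int(np.floor(lo * scale))
        hi_s = max(int(np.ceil(hi * scale)), 1)
        if cat == "adult_male":
            lo_s = max(lo_s, 1)  # a group always has at least one adult male
        draw = int(np.rint(rng.normal(mean * scale, sd * np.sqrt(scale))))
        counts[cat] = int(np.clip(draw, lo_s, hi_s))
        bounds[cat] = (lo_s, hi_s)
    # repair to the target total
    for _ in range(10 * n):
        total = sum(counts.values())
        if total == n:
            break
        if total > n:
            adjustable = [c for c in _CATEGORY_ORDER if counts[c] > bounds[c][0]]
            victim = max(adjustable, key=lambda c: counts[c])
            counts[victim] -= 1
        else:
            adjustable = [c for c in _CATEGORY_ORDER if counts[c] < bounds[c][1]]
            victim = max(adjustable, key=lambda c: counts[c])
            counts[victim] += 1
    else:  # pragma: no cover - bounds always admit a solution for n in 5..20
        raise RuntimeError("could not repair composition to target size")
    return counts


def _category_intake(cat: Category) -> dict[NeedKind, float]:
    """Per-individual protein/energy intake rates (units/min).

    Intake rates are category-level constants: an animal whose feeding rate
    fell materially below its class mean could not cover its own daily
    drain inside any feasible activity budget, so per-agent Gaussian draws
    at the printed spreads produce non-viable agents.  Individual
    heterogeneity enters through body mass and requirements instead.
    """
    return {
        NeedKind.PROTEIN: cat.intake_protein[0],
        NeedKind.ENERGY: cat.intake_energy[0],
    }


def _make_agent(idx: int, cat: Category, mass: float, social_req: float,
                rest_req: float, intake: dict[NeedKind, float]) -> AgentSpec:
    req = nutrient_requirements(cat.name, mass)
    req[NeedKind.SOCIAL] = social_req
    req[NeedKind.REST] = rest_req
    return AgentSpec(
        id=f"{cat.name}-{idx}",
        category=cat.name,
        mass_kg=float(mass),
        daily_requirement=req,
        intake=intake,
    )


def build_macaque_group(
    n: int,
    heterogeneous: bool,
    rng_seed: int | np.random.Generator,
    *,
    allow_any_size: bool = False,
    homogeneous_category: str = HOMOGENEOUS_CATEGORY,
    label: str = "",
) -> GroupSpec:
    """Build a five-need group of ``n`` agents.

    heterogeneous=True draws a category composition and per-individual
    masses; heterogeneous=False ("equal needs") uses one category at its
    mean mass so every agent has identical requirements.  Per-individual
    protein/energy intake rates are drawn in both cases (they are agent
    attributes, not needs).
    """
    if n not in (5, 10, 20) and not allow_any_size:
        raise ValueError(f"group size {n} not in (5, 10, 20); pass allow_any_size=True to override")
    if not 2 <= n <= 20:
        raise ValueError("group size must be between 2 and 20")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    agents: list[AgentSpec] = []
    if heterogeneous:
        composition = sample_composition(n, rng)
        idx = 0
        for cat_name in _CATEGORY_ORDER:
            cat = CATEGORY_TABLE[cat_name]
            for _ in range(composition[cat_name]):
                mass = max(MASS_FLOOR_KG, rng.normal(*cat.mass_kg))
                agents.append(_make_agent(idx, cat, mass, cat.social_req_min[0],
                                          cat.rest_req_min[0], _category_intake(cat)))
                idx += 1
    else:
        cat = CATEGORY_TABLE[homogeneous_category]
        for idx in range(n):
            agents.append(
                _make_agent(idx, cat, cat.mass_kg[0], cat.social_req_min[0],
                            cat.rest_req_min[0], _category_intake(cat))
            )
    kind = "het" if heterogeneous else "hom"
    return GroupSpec(agents=agents, model_variant="macaque",
                     label=label or f"macaque-{kind}-n{n}")
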