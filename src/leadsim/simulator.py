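"""Discrete-time simulation driver.

A simulation advances in one-minute steps.  At every activity boundary the
most motivated agent becomes leader and steers the whole group (travel to
the serving area if needed, then the activity until the leader's reserve is
full).  In the five-need variant the group is forced to the resting site at
step 720 of each day and rests there until dawn.  A run stops when any
reserve of any agent reaches zero (death) or after ``max_days`` days.

Replicates are independently seeded from a root seed with a counter-based
splitter, so a (config, seed) pair is fully reproducible and replicate
results do not depend on execution order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import environment as env
from ._kernel import simulate_kernel
from .dynamics import PackedGroup, pack_group
from .parameters import GroupSpec, MACAQUE_NEEDS, DYAD_NEEDS

__all__ = ["SimConfig", "SimulationResult", "ReplicateAggregate", "run", "run_replicates"]

STEPS_PER_DAY = 1440
DAY_STEPS = 720  # daytime steps per day (night occupies the other 720)


@dataclass
class SimConfig:
    group: GroupSpec
    layout: tuple[env.Area, ...] | None = None
    max_days: int = 90
    replicates: int = 1000
    rng_seed: int = 0
    deterministic: bool = False
    normalizer: Literal["group_mean", "own"] = "group_mean"
    bout_mode: Literal["takeover", "until_full"] = "takeover"
    initial_reserve_fraction: float | np.ndarray = 1.0
    record_events: bool = False
    max_events: int = 500_000

    def __post_init__(self) -> None:
        if self.max_days < 1:
            raise ValueError("max_days must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.layout is None:
            self.layout = env.place_areas(self.group.model_variant)
        env.validate_layout(self.layout)
        if self.group.model_variant == "macaque" and len(self.layout) != 4:
            raise ValueError("five-need variant needs a 4-area layout")
        if self.group.model_variant == "dyad" and len(self.layout) != 2:
            raise ValueError("dyad variant needs a 2-area layout")


@dataclass
class SimulationResult:
    """Outcome of one replicate."""

    seed: int
    leadership_count: np.ndarray  # (n,) decision events led
    day_activity_minutes: np.ndarray  # (k+1,): per-activity day minutes + moving
    night_rest_minutes: int
    night_move_minutes: int
    total_minutes: int
    days_completed: int
    died: bool
    death: tuple[int, int, int] | None  # (agent, need, timestep)
    reserves_final: np.ndarray
    reserve_floor: float  # closest approach to an empty reserve over the
    # whole run, measured after expenditure and before the same minute's
    # intake (can be slightly negative for a reserve rescued by intake)
    n_decisions: int
    events: pd.DataFrame | None = None

    @property
    def leadership_share(self) -> np.ndarray:
        tot = self.leadership_count.sum()
        if tot == 0:
            raise ValueError("no decision events in this replicate")
        return self.leadership_count / tot

    def budget_fractions(self, needs: Sequence) -> dict[str, float]:
        """Four-way daytime activity budget (moving/foraging/resting/socializing).

        Scored over daytime steps only; drinking counts as foraging.
        """
        k = len(needs)
        mins = self.day_activity_minutes
        day_total = mins.sum()
        if day_total == 0:
            return {"moving": np.nan, "foraging": np.nan, "resting": np.nan, "socializing": np.nan}
        names = [n.value for n in needs]
        forage = sum(mins[i] for i, nm in enumerate(names) if nm in ("protein", "energy", "water"))
        rest = sum(mins[i] for i, nm in enumerate(names) if nm == "rest")
        soc = sum(mins[i] for i, nm in enumerate(names) if nm == "social")
        return {
            "moving": mins[k] / day_total,
            "foraging": forage / day_total,
            "resting": rest / day_total,
            "socializing": soc / day_total,
        }


@dataclass
class ReplicateAggregate:
    """Pooled summary over replicates of one group."""

    counts: np.ndarray  # (reps, n) leadership counts
    shares: np.ndarray  # (reps, n) per-replicate shares (NaN if no decisions)
    pooled_share: np.ndarray  # (n,) counts pooled over replicates, normalized
    mean_budget: dict[str, float]
    deaths: int
    replicates: int


def _replicate_seed(root_seed: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(root_seed), int(rep)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _norm_matrix(packed: PackedGroup, normalizer: str) -> np.ndarray:
    if normalizer == "own":
        return packed.R.copy()
    if normalizer == "group_mean":
        return np.broadcast_to(packed.R.mean(axis=0, keepdims=True), packed.R.shape).copy()
    raise ValueError(f"unknown normalizer {normalizer!r}")


def _prepare(config: SimConfig):
    packed = pack_group(config.group)
    if config.deterministic:
        packed.drain_always = packed.drain_always.copy()
        packed.act_exp = packed.act_exp.copy()
        packed.intake_noise = packed.intake_noise.copy()
        packed.drain_always[:, :, 1] = 0.0
        packed.act_exp[:, :, 1] = 0.0
        packed.intake_noise[:, 1] = 0.0
    norm = _norm_matrix(packed, config.normalizer)
    area_x = np.array([a.x for a in config.layout])
    area_y = np.array([a.y for a in config.layout])
    radius = float(config.layout[0].radius)
    rest_area = -1
    if config.group.model_variant == "macaque":
        roles = [a.role for a in config.layout]
        rest_area = roles.index("resting_site")
    r0 = packed.R * np.asarray(config.initial_reserve_fraction)
    return packed, norm, area_x, area_y, radius, rest_area, r0


def run(config: SimConfig, seed: int | None = None) -> SimulationResult:
    """Run a single replicate and return its result."""
    packed, norm, area_x, area_y, radius, rest_area, r0 = _prepare(config)
    kseed = _replicate_seed(config.rng_seed, 0) if seed is None else int(seed)
    return _run_packed(config, packed, norm, area_x, area_y, radius, rest_area, r0, kseed)


def _run_packed(config, packed, norm, area_x, area_y, radius, rest_area, r0, kseed) -> SimulationResult:
    out = simulate_kernel(
        kseed,
        packed.R,
        r0,
        packed.mass,
        norm,
        packed.intake_fixed,
        packed.intake_noise,
        packed.drain_always,
        packed.act_exp,
        packed.need_area,
        packed.min_bout_len,
        packed.preempt_mask,
        packed.night_refill_mask,
        area_x,
        area_y,
        radius,
        rest_area,
        env.START_POSITION[0],
        env.START_POSITION[1],
        config.max_days * STEPS_PER_DAY,
        config.max_events if config.record_events else 0,
        packed.drain_night_mask,
        packed.drain_own_mask,
        config.bout_mode == "takeover",
    )
    (counts, day_minutes, night_rest, night_move, total_minutes, days_completed,
     died_agent, died_need, died_time, r_final, r_min, n_boundaries,
     ev_t, ev_leader, ev_need, ev_bout) = out
    events = None
    if config.record_events:
        needs = config.group.needs
        events = pd.DataFrame(
            {
                "timestep": ev_t,
                "leader": [config.group.agents[i].id for i in ev_leader],
                "leader_index": ev_leader,
                "need": [needs[j].value for j in ev_need],
                "bout_minutes": ev_bout,
            }
        )
    return SimulationResult(
        seed=kseed,
        leadership_count=counts,
        day_activity_minutes=day_minutes,
        night_rest_minutes=int(night_rest),
        night_move_minutes=int(night_move),
        total_minutes=int(total_minutes),
        days_completed=int(days_completed),
        died=died_agent >= 0,
        death=(int(died_agent), int(died_need), int(died_time)) if died_agent >= 0 else None,
        reserves_final=r_final,
        reserve_floor=float(r_min),
        n_decisions=int(n_boundaries),
        events=events,
    )


def run_replicates(config: SimConfig) -> tuple[list[SimulationResult], ReplicateAggregate]:
    """Run all replicates of a config and aggregate leadership and budgets."""
    packed, norm, area_x, area_y, radius, rest_area, r0 = _prepare(config)
    results: list[SimulationResult] = []
    for rep in range(config.replicates):
        kseed = _replicate_seed(config.rng_seed, rep)
        results.append(
            _run_packed(config, packed, norm, area_x, area_y, radius, rest_area, r0, kseed)
        )
    n = config.group.n
    counts = np.array([res.leadership_count for res in results])
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        shares = np.where(totals > 0, counts / totals, np.nan)
    pooled = counts.sum(axis=0)
    pooled_share = pooled / pooled.sum() if pooled.sum() > 0 else np.full(n, np.nan)
    budgets = [res.budget_fractions(config.group.needs) for res in results]
    mean_budget = {key: float(np.nanmean([b[key] for b in budgets])) for key in budgets[0]}
    agg = ReplicateAggregate(
        counts=counts,
        shares=shares,
        pooled_share=pooled_share,
        mean_budget=mean_budget,
        deaths=sum(res.died for res in results),
        replicates=config.replicates,
    )
    return results, agg


def results_to_tidy(config: SimConfig, results: Sequence[SimulationResult],
                    group_label: str | None = None) -> pd.DataFrame:
    """One row per replicate x agent, for the analysis module and CSV export."""
    rows = []
    label = group_label or config.group.label
    for rep, res in enumerate(results):
        total = res.leadership_count.sum()
        budget = res.budget_fractions(config.group.needs)
        for i, agent in enumerate(config.group.agents):
            rows.append(
                {
                    "group": label,
                    "replicate": rep,
                    "agent": agent.id,
                    "agent_index": i,
                    "category": agent.category,
                    "mass_kg": agent.mass_kg,
                    "leadership_count": int(res.leadership_count[i]),
                    "leadership_share": res.leadership_count[i] / total if total else np.nan,
                    "died": res.died,
                    "days_completed": res.days_completed,
                    **{f"budget_{k}": v for k, v in budget.items()},
                }
            )
    return pd.DataFrame(rows)
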