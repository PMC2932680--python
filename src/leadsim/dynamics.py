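"""Reserve bookkeeping and the probability-to-lead rule.

Each agent *i* holds one reserve per need *A*, bounded between 0 (death)
and its capacity ``R[i, A]`` (the daily requirement).  The motivation, or
probability to lead, for need A is the reserve deficit scaled by the
group-typical requirement for that need::

    alpha[i, A] = (R[i, A] - r[i, A]) / norm[A]

with ``norm[A]`` the group mean requirement (default) or the agent's own
capacity (``normalizer="own"``, the classic 1 - r/R form).  An agent's
overall probability to lead is its worst need, ``P[i] = max_A alpha[i, A]``,
and at every activity boundary the agent with the highest P becomes the
leader and steers the group toward refilling that need.  Group-mean
normalization makes the comparison between individuals one of absolute
deficits, so an agent whose requirements outstrip its groupmates' spends
more time with the highest motivation — the mechanism behind leader
emergence.  alpha is 0 at a full reserve and reaches R[i,A]/norm[A]
(about 1 for a typical group member) at an empty one.

Expenditure (per one-minute step) has three components:

* activity-dependent nutrient drains, Normal(mean, sd) per kg of body mass,
  truncated at 0, from the per-activity expenditure table;
* time-budget drains: social and resting reserves lose requirement/720 per
  daytime minute, whatever the group does, except during the bout that
  refills them; they are frozen at night (the resting reserve refills
  then).  Dyad reserves instead lose a requirement-proportional Gaussian
  drain every minute, unconditionally;
* nothing else — blank table cells mean zero drain.

Intake refills only the reserve matching the current group activity, for
every agent present (followers benefit), clamped at capacity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .parameters import (
    DYAD_DRAIN_AT_1000,
    DYAD_DRAIN_REFERENCE,
    GroupSpec,
    INTAKE_REST,
    INTAKE_SOCIAL,
    INTAKE_WATER,
    CATEGORY_TABLE,
    MACAQUE_NEEDS,
    NeedKind,
)

__all__ = [
    "Activity",
    "MACAQUE_ACTIVITIES",
    "EXPENDITURE_TABLE",
    "probability_to_lead",
    "select_leader",
    "step_expenditure",
    "step_intake",
    "activity_done",
    "pack_group",
    "PackedGroup",
    "MIN_BOUT_MINUTES",
]

MIN_BOUT_MINUTES = 5  # minimal rest/social bout length
NUTRIENT_MIN_BOUT = 2  # minutes a feeding/drinking bout holds before any handover
STEPS_PER_DAY = 1440
NIGHT_START_STEP = 720
NIGHT_LENGTH = 720
SOCIAL_REST_DIVISOR = 720.0  # social/rest drain = daily requirement / 720 per min

# activity indices: 0..k-1 = refill need k ("forage_protein", ..., "rest"),
# k = moving, k+1 = night rest
MACAQUE_ACTIVITIES = ("forage_protein", "forage_energy", "drink", "socialize", "rest")
DYAD_ACTIVITIES = ("fill_need1", "fill_need2")
MOVE = "move"
NIGHT = "night"

Activity = str

# Per-activity nutrient expenditure, (mean, sd) per kg per minute, keyed by
# [activity][need]. Drinking shares the foraging row (no drinking row is
# printed); the night and day resting rows coincide; moving uses walking.
# Protein is handled as a continuous daytime drain (see PROTEIN_DRAIN
# below), not per activity row.
_FORAGE_ROW = {
    NeedKind.ENERGY: (0.29, 0.15),
    NeedKind.WATER: (0.07, 0.035),
}
_WALK_ROW = {NeedKind.ENERGY: (0.24, 0.10), NeedKind.WATER: (0.0575, 0.023)}
_SOCIAL_ROW = {NeedKind.ENERGY: (0.29, 0.15), NeedKind.WATER: (0.07, 0.035)}
_REST_ROW = {NeedKind.ENERGY: (0.10, 0.05), NeedKind.WATER: (0.025, 0.012)}

EXPENDITURE_TABLE: dict[str, dict[NeedKind, tuple[float, float]]] = {
    "forage_protein": _FORAGE_ROW,
    "forage_energy": _FORAGE_ROW,
    "drink": _FORAGE_ROW,
    "socialize": _SOCIAL_ROW,
    "rest": _REST_ROW,
    MOVE: _WALK_ROW,
    NIGHT: _REST_ROW,
}

#: protein catabolism, (mean, sd) g per kg per minute, applied over every
#: daytime minute whatever the activity (including protein foraging itself);
#: a per-activity-row protein drain would make protein a need that almost
#: never drives leadership, whereas protein turnover is continuous
PROTEIN_DRAIN = (0.0027, 0.0013)

#: which activity refills which need (macaque)
ACTIVITY_NEED = {
    "forage_protein": NeedKind.PROTEIN,
    "forage_energy": NeedKind.ENERGY,
    "drink": NeedKind.WATER,
    "socialize": NeedKind.SOCIAL,
    "rest": NeedKind.REST,
}


def probability_to_lead(r: np.ndarray, R: np.ndarray,
                        normalizer: Literal["group_mean", "own"] = "group_mean",
                        ) -> np.ndarray:
    """Motivation matrix alpha[i, A] from reserves ``r`` and capacities ``R``.

    Monotone decreasing in r; 0 at a full reserve. With ``own``
    normalization it is exactly 1 - r/R.
    """
    r = np.asarray(r, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("capacities must be positive")
    if np.any(r < -1e-9) or np.any(r > R + 1e-9):
        raise ValueError("reserves must lie in [0, capacity]")
    if normalizer == "own":
        norm = R
    elif normalizer == "group_mean":
        norm = np.broadcast_to(R.mean(axis=0, keepdims=True), R.shape) if R.ndim == 2 else R
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    return (R - r) / norm


def select_leader(alpha: np.ndarray, rng: np.random.Generator,
                  tie_tol: float = 1e-12) -> tuple[int, int]:
    """Pick (leader index, need index) from a motivation matrix.

    The leader is the agent with the highest P_i = max_A alpha[i, A]; its
    target is the need attaining that maximum.  Exact ties are broken
    uniformly at random.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if alpha.shape[0] < 1:
        raise ValueError("need at least one agent")
    P = alpha.max(axis=1)
    best = P.max()
    tied = np.flatnonzero(P >= best - tie_tol)
    leader = int(tied[rng.integers(len(tied))]) if len(tied) > 1 else int(tied[0])
    row = alpha[leader]
    tied_needs = np.flatnonzero(row >= row.max() - tie_tol)
    need = int(tied_needs[rng.integers(len(tied_needs))]) if len(tied_needs) > 1 else int(tied_needs[0])
    return leader, need


@dataclass
class PackedGroup:
    """Array view of a GroupSpec, ready for the simulation kernel.

    All per-minute rates are float64 arrays in canonical need order.
    ``intake_fixed`` is NaN where intake uses per-minute noise draws
    (water/social/rest) instead of a fixed per-individual rate.
    """

    n: int
    k: int
    R: np.ndarray  # (n, k) capacities
    mass: np.ndarray  # (n,)
    intake_fixed: np.ndarray  # (n, k); NaN -> use noise
    intake_noise: np.ndarray  # (k, 2) per-minute (mean, sd) draws
    drain_always: np.ndarray  # (n, k, 2) continuous per-minute (mean, sd)
    drain_night_mask: np.ndarray  # (k,) bool: continuous drain runs at night
    drain_own_mask: np.ndarray  # (k,) bool: drain runs during the own bout
    act_exp: np.ndarray  # (k + 2, k, 2) per-kg (mean, sd) by activity row
    need_area: np.ndarray  # (k,) area index refilling need, -1 = in place
    min_bout_len: np.ndarray  # (k,) int: minimum bout length in minutes
    preempt_mask: np.ndarray  # (k,) bool: bout may be handed over before the
                              # leader is full (per-minute motivation race)
    night_refill_mask: np.ndarray  # (k,) bool: refilled during night rest
    is_dyad: bool


def pack_group(group: GroupSpec) -> PackedGroup:
    needs = group.needs
    k = len(needs)
    n = group.n
    R = group.requirement_matrix()
    mass = np.array([a.mass_kg for a in group.agents])
    intake_fixed = np.full((n, k), np.nan)
    intake_noise = np.zeros((k, 2))
    drain_always = np.zeros((n, k, 2))
    act_exp = np.zeros((k + 2, k, 2))
    if group.model_variant == "dyad":
        for i, a in enumerate(group.agents):
            for j, need in enumerate(needs):
                intake_fixed[i, j] = a.intake[need]
                scale = R[i, j] / DYAD_DRAIN_REFERENCE
                drain_always[i, j] = (DYAD_DRAIN_AT_1000 * scale, DYAD_DRAIN_AT_1000 * scale / 2.0)
        need_area = np.array([0, 1], dtype=np.int64)
        min_bout_len = np.ones(k, dtype=np.int64)
        preempt_mask = np.ones(k, dtype=np.bool_)
        night_refill_mask = np.zeros(k, dtype=np.bool_)
        return PackedGroup(n, k, R, mass, intake_fixed, intake_noise, drain_always,
                           np.ones(k, dtype=np.bool_), np.ones(k, dtype=np.bool_),
                           act_exp, need_area, min_bout_len, preempt_mask,
                           night_refill_mask, True)

    idx = {need: j for j, need in enumerate(needs)}
    for i, a in enumerate(group.agents):
        intake_fixed[i, idx[NeedKind.PROTEIN]] = a.intake[NeedKind.PROTEIN]
        intake_fixed[i, idx[NeedKind.ENERGY]] = a.intake[NeedKind.ENERGY]
        drain_always[i, idx[NeedKind.PROTEIN]] = (PROTEIN_DRAIN[0] * mass[i], PROTEIN_DRAIN[1] * mass[i])
        # social/rest drains carry the same relative spread (sd = mean/2)
        # as every other expenditure entry in the table
        s_mean = R[i, idx[NeedKind.SOCIAL]] / SOCIAL_REST_DIVISOR
        r_mean = R[i, idx[NeedKind.REST]] / SOCIAL_REST_DIVISOR
        drain_always[i, idx[NeedKind.SOCIAL]] = (s_mean, s_mean / 2.0)
        drain_always[i, idx[NeedKind.REST]] = (r_mean, r_mean / 2.0)
    intake_noise[idx[NeedKind.WATER]] = INTAKE_WATER
    intake_noise[idx[NeedKind.SOCIAL]] = INTAKE_SOCIAL
    intake_noise[idx[NeedKind.REST]] = INTAKE_REST
    # continuous drains pause overnight; protein keeps draining during its
    # own foraging bout (ingestion outpaces catabolism), social/rest cannot
    # be spent while being replenished
    drain_night_mask = np.zeros(k, dtype=np.bool_)
    drain_own_mask = np.zeros(k, dtype=np.bool_)
    drain_own_mask[idx[NeedKind.PROTEIN]] = True
    activities = list(MACAQUE_ACTIVITIES) + [MOVE, NIGHT]
    for a_i, act in enumerate(activities):
        for need, (m, s) in EXPENDITURE_TABLE[act].items():
            act_exp[a_i, idx[need]] = (m, s)
    # protein patch 0, energy patch 1, waterhole 2; social/rest in place
    need_area = np.array([0, 1, 2, -1, -1], dtype=np.int64)
    # bout commitment times: rest/social carry the fixed 5-minute minimum;
    # feeding and drinking commit the group for at least 2 minutes once the
    # patch is reached
    min_bout_len = np.full(k, NUTRIENT_MIN_BOUT, dtype=np.int64)
    min_bout_len[idx[NeedKind.SOCIAL]] = MIN_BOUT_MINUTES
    min_bout_len[idx[NeedKind.REST]] = MIN_BOUT_MINUTES
    # resting and socializing run until the leader is satisfied; feeding and
    # drinking bouts can be handed over by the per-minute motivation race
    preempt_mask = np.ones(k, dtype=np.bool_)
    preempt_mask[idx[NeedKind.SOCIAL]] = False
    preempt_mask[idx[NeedKind.REST]] = False
    # the night refills only the resting reserve; the social reserve is
    # frozen overnight (it neither drains nor refills while the group sleeps)
    night_refill_mask = np.zeros(k, dtype=np.bool_)
    night_refill_mask[idx[NeedKind.REST]] = True
    return PackedGroup(n, k, R, mass, intake_fixed, intake_noise, drain_always,
                       drain_night_mask, drain_own_mask,
                       act_exp, need_area, min_bout_len, preempt_mask,
                       night_refill_mask, False)


def _activity_row(packed: PackedGroup, activity: int) -> int:
    """Kernel row index for an activity code (0..k-1, k=move, k+1=night)."""
    if not 0 <= activity <= packed.k + 1:
        raise ValueError(f"invalid activity code {activity}")
    return activity


def step_expenditure(packed: PackedGroup, activity: int,
                     rng: np.random.Generator | None,
                     deterministic: bool = False,
                     night: bool = False) -> np.ndarray:
    """Per-agent, per-need reserve decrements for one minute.

    ``activity`` uses kernel codes (need index, or k for moving, k+1 for
    night rest).  Gaussian components are truncated at 0; deterministic
    mode uses the means.  Unconditional drains (social/rest req/720; the
    dyad per-minute drains) are suspended during night minutes in the
    five-need variant and, for that variant, for the need currently being
    refilled; the dyad drains run unconditionally.
    """
    row = _activity_row(packed, activity)
    gate = np.ones((packed.n, packed.k), dtype=bool)
    if night:
        gate[:, ~packed.drain_night_mask] = False
    if activity < packed.k and not packed.drain_own_mask[activity]:
        gate[:, activity] = False
    da_mean = np.where(gate, packed.drain_always[:, :, 0], 0.0)
    da_sd = np.where(gate, packed.drain_always[:, :, 1], 0.0)
    mean = da_mean + packed.act_exp[row, :, 0][None, :] * packed.mass[:, None]
    if deterministic:
        return mean
    if rng is None:
        raise ValueError("rng required unless deterministic")
    sd = np.sqrt(da_sd ** 2 + (packed.act_exp[row, :, 1][None, :] * packed.mass[:, None]) ** 2)
    dec = mean.copy()
    noisy = sd > 0
    dec[noisy] = np.maximum(0.0, rng.normal(mean[noisy], sd[noisy]))
    return dec


def step_intake(packed: PackedGroup, activity: int, at_area: bool,
                rng: np.random.Generator | None,
                deterministic: bool = False) -> np.ndarray:
    """Per-agent, per-need reserve increments for one minute of ``activity``.

    Only the need matching the activity is refilled, for every agent in the
    group.  A nutrient activity attempted away from its serving area is a
    driver bug and is rejected.
    """
    inc = np.zeros((packed.n, packed.k))
    if activity >= packed.k:  # moving / night handled by caller
        return inc
    if packed.need_area[activity] >= 0 and not at_area:
        raise ValueError(
            f"intake for need {activity} requires the group to be at its serving area"
        )
    fixed = packed.intake_fixed[:, activity]
    if np.all(np.isfinite(fixed)):
        inc[:, activity] = fixed
    else:
        mean, sd = packed.intake_noise[activity]
        if deterministic:
            inc[:, activity] = mean
        else:
            if rng is None:
                raise ValueError("rng required unless deterministic")
            inc[:, activity] = np.maximum(0.0, rng.normal(mean, sd, size=packed.n))
    return inc


def activity_done(packed: PackedGroup, r: np.ndarray, leader: int, activity: int,
                  bout_length: int, night: bool = False,
                  step_of_day: int | None = None) -> bool:
    """Has the current activity period ended?

    Nutrient bouts end when the leader's target reserve is full; rest and
    social bouts additionally require the 5-minute minimum; night rest ends
    only at dawn.
    """
    if night:
        if step_of_day is None:
            raise ValueError("night bouts need step_of_day")
        return step_of_day == 0
    full = r[leader, activity] >= packed.R[leader, activity] - 1e-9
    return full and bout_length >= packed.min_bout_len[activity]
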