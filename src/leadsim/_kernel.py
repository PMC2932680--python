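"""Compiled per-minute simulation loop.

One kernel drives both model variants; everything variant-specific arrives
packed as arrays (see :func:`leadsim.dynamics.pack_group`).  Gaussian noise
is drawn through a shared standard-normal buffer (``mean + sd * z``,
truncated at zero), refilled in blocks from the seeded global generator;
the pure-Python reference driver used in the tests reproduces the same
draw order, so deterministic configurations match it exactly.

Minute order of operations: (1) night interruption at step 720 of each day,
(2) dawn boundary, (3) leader (re)selection -- at activity boundaries, and
every minute for preemptible bouts past their commitment time, (4) execute
the minute (travel, activity intake, or night rest), (5) expenditure for
all agents, (6) death check, (7) bout-completion check.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# mode codes
_BOUNDARY = 0
_ACT = 1
_MOVE = 2
_NIGHT_MOVE = 3
_NIGHT_REST = 4
_BOUNDARY_GO = 5  # boundary whose (leader, need) selection is already made

TORUS = 96.0
SPEED = 24.0
EPS_FULL = 1e-9
EPS_DEATH = 1e-9

STEPS_PER_DAY = 1440
NIGHT_START = 720

_ZN = 8192  # standard-normal buffer block size


@njit(cache=True)
def _delta(a, b):
    d = (b - a) % TORUS
    if d > TORUS / 2:
        d -= TORUS
    return d


@njit(cache=True)
def _select(R, r, norm):
    """Leader and target need by highest motivation; ties uniform at random.

    Consumes random draws only when ties occur, so deterministic tie-free
    configurations consume no randomness here.
    """
    n, k = R.shape
    best_p = -1.0
    for i in range(n):
        p = -1.0
        for j in range(k):
            a = (R[i, j] - r[i, j]) / norm[i, j]
            if a > p:
                p = a
        if p > best_p:
            best_p = p
    n_tied = 0
    for i in range(n):
        p = -1.0
        for j in range(k):
            a = (R[i, j] - r[i, j]) / norm[i, j]
            if a > p:
                p = a
        if p >= best_p - 1e-12:
            n_tied += 1
    pick = 0
    if n_tied > 1:
        pick = np.random.randint(0, n_tied)
    m = 0
    leader = 0
    for i in range(n):
        p = -1.0
        for j in range(k):
            a = (R[i, j] - r[i, j]) / norm[i, j]
            if a > p:
                p = a
        if p >= best_p - 1e-12:
            if m == pick:
                leader = i
            m += 1
    best_a = -1.0
    for j in range(k):
        a = (R[leader, j] - r[leader, j]) / norm[leader, j]
        if a > best_a:
            best_a = a
    n_tied = 0
    for j in range(k):
        a = (R[leader, j] - r[leader, j]) / norm[leader, j]
        if a >= best_a - 1e-12:
            n_tied += 1
    pick = 0
    if n_tied > 1:
        pick = np.random.randint(0, n_tied)
    m = 0
    need = 0
    for j in range(k):
        a = (R[leader, j] - r[leader, j]) / norm[leader, j]
        if a >= best_a - 1e-12:
            if m == pick:
                need = j
            m += 1
    return leader, need


@njit(cache=True)
def simulate_kernel(
    seed,
    R,              # (n, k) capacities
    r0,             # (n, k) initial reserves
    mass,           # (n,)
    norm,           # (n, k) motivation normalizer
    intake_fixed,   # (n, k), NaN -> per-minute noise
    intake_noise,   # (k, 2)
    drain_always,   # (n, k, 2) continuous per-minute (mean, sd)
    act_exp,        # (k + 2, k, 2) per-kg rows: 0..k-1 activity, k move, k+1 night
    need_area,      # (k,) area index or -1
    min_bout_len,   # (k,) minimum bout minutes per need
    preempt_mask,   # (k,) bool: per-minute handover allowed for this need
    night_refill_mask,  # (k,) bool: refilled during night rest
    area_x, area_y,  # (n_areas,)
    radius,
    rest_area,      # area index used for the night, -1 disables night
    start_x, start_y,
    max_minutes,
    max_events,
    drain_night_mask,  # (k,) bool: continuous drain keeps running at night
    drain_own_mask,    # (k,) bool: drain keeps running during the own bout
    takeover,          # bool: preemptible bouts last only while their leader
                       # holds the highest P
):
    np.random.seed(seed)
    n, k = R.shape
    r = r0.copy()
    counts = np.zeros(n, dtype=np.int64)
    day_minutes = np.zeros(k + 1, dtype=np.int64)  # 0..k-1 activities, k moving
    night_rest_minutes = 0
    night_move_minutes = 0
    ev_t = np.empty(max_events, dtype=np.int64)
    ev_leader = np.empty(max_events, dtype=np.int64)
    ev_need = np.empty(max_events, dtype=np.int64)
    ev_bout = np.full(max_events, -1, dtype=np.int64)
    n_events = 0
    cur_event = -1

    # effective per-minute expenditure (mean, sd) per agent and need, one row
    # per execution context: 0..k-1 activity bouts, k day travel, k+1 night
    # rest, k+2 night travel; the continuous-drain gating is baked in
    nrows = k + 3
    eff_mean = np.zeros((nrows, n, k))
    eff_sd = np.zeros((nrows, n, k))
    for row in range(nrows):
        if row == k + 1:
            base = k + 1  # night rest -> resting expenditure row
        elif row == k + 2:
            base = k  # night travel -> walking expenditure row
        else:
            base = row
        night_row = row >= k + 1
        for i in range(n):
            for j in range(k):
                m_ = act_exp[base, j, 0] * mass[i]
                s_ = act_exp[base, j, 1] * mass[i]
                gate = True
                if night_row and not drain_night_mask[j]:
                    gate = False
                if row < k and j == row and not drain_own_mask[j]:
                    gate = False
                if gate:
                    m_ += drain_always[i, j, 0]
                    s_ = np.sqrt(s_ * s_ + drain_always[i, j, 1] ** 2)
                eff_mean[row, i, j] = m_
                eff_sd[row, i, j] = s_

    zbuf = np.random.standard_normal(_ZN)
    zpos = 0

    px, py = start_x, start_y
    mode = _BOUNDARY
    cur_need = -1
    leader = -1
    target_area = -1
    bout_len = 0
    died_agent = -1
    died_need = -1
    died_time = -1
    r_min = 1e300
    n_boundaries = 0
    night_on = rest_area >= 0

    t = 0
    while t < max_minutes:
        sod = t % STEPS_PER_DAY
        if night_on and sod == NIGHT_START:
            dx = _delta(px, area_x[rest_area])
            dy = _delta(py, area_y[rest_area])
            if np.sqrt(dx * dx + dy * dy) <= radius:
                mode = _NIGHT_REST
            else:
                mode = _NIGHT_MOVE
        if night_on and sod == 0 and mode == _NIGHT_REST:
            mode = _BOUNDARY

        # per-minute preemption: motivations are re-compared every step and
        # a preemptible bout continues only while its leader keeps the
        # highest P; bouts are protected for their minimum length
        if (takeover and mode == _ACT and preempt_mask[cur_need]
                and bout_len >= min_bout_len[cur_need]):
            new_leader, new_need = _select(R, r, norm)
            if new_need == cur_need:
                leader = new_leader  # silent handover, same group activity
            else:
                if cur_event >= 0:
                    ev_bout[cur_event] = bout_len
                leader = new_leader
                mode = _BOUNDARY_GO  # new initiation, selection already made
                cur_need = new_need

        if mode == _BOUNDARY or mode == _BOUNDARY_GO:
            if mode == _BOUNDARY:
                leader, cur_need = _select(R, r, norm)
            counts[leader] += 1
            n_boundaries += 1
            if n_events < max_events:
                ev_t[n_events] = t
                ev_leader[n_events] = leader
                ev_need[n_events] = cur_need
                cur_event = n_events
                n_events += 1
            else:
                cur_event = -1
            aidx = need_area[cur_need]
            if aidx >= 0:
                dx = _delta(px, area_x[aidx])
                dy = _delta(py, area_y[aidx])
                if np.sqrt(dx * dx + dy * dy) > radius:
                    mode = _MOVE
                    target_area = aidx
                else:
                    mode = _ACT
                    bout_len = 0
            else:
                mode = _ACT
                bout_len = 0

        # ---- execute the minute ----
        if mode == _MOVE or mode == _NIGHT_MOVE:
            tgt = target_area if mode == _MOVE else rest_area
            dx = _delta(px, area_x[tgt])
            dy = _delta(py, area_y[tgt])
            dist = np.sqrt(dx * dx + dy * dy)
            step = SPEED if SPEED < dist else dist
            if dist > 0:
                px = (px + dx / dist * step) % TORUS
                py = (py + dy / dist * step) % TORUS
            if mode == _MOVE:
                day_minutes[k] += 1
                exp_row = k
            else:
                night_move_minutes += 1
                exp_row = k + 2
            dx = _delta(px, area_x[tgt])
            dy = _delta(py, area_y[tgt])
            if np.sqrt(dx * dx + dy * dy) <= radius:
                if mode == _MOVE:
                    mode = _ACT
                    bout_len = 0
                else:
                    mode = _NIGHT_REST
        elif mode == _NIGHT_REST:
            night_rest_minutes += 1
            exp_row = k + 1
        else:  # _ACT
            day_minutes[cur_need] += 1
            bout_len += 1
            exp_row = cur_need

        # expenditure: all agents, all needs (agent-outer, need-inner);
        # a reserve driven strictly below empty is lethal unless the current
        # minute's intake lifts it back above zero -- exactly-empty (within
        # tolerance) is the brink, still alive
        pend_agent = -1
        pend_need = -1
        for i in range(n):
            for j in range(k):
                s_ = eff_sd[exp_row, i, j]
                if s_ > 0.0:
                    if zpos == _ZN:
                        zbuf = np.random.standard_normal(_ZN)
                        zpos = 0
                    dec = eff_mean[exp_row, i, j] + s_ * zbuf[zpos]
                    zpos += 1
                    if dec < 0.0:
                        dec = 0.0
                else:
                    dec = eff_mean[exp_row, i, j]
                    if dec == 0.0:
                        continue
                r[i, j] -= dec
                if r[i, j] < r_min:
                    r_min = r[i, j]  # closest approach to empty, pre-intake
                if r[i, j] < -EPS_DEATH and pend_agent < 0:
                    pend_agent = i
                    pend_need = j
                if r[i, j] < 0.0:
                    r[i, j] = 0.0

        # intake
        if mode == _ACT:
            j = cur_need
            if np.isfinite(intake_fixed[0, j]):
                for i in range(n):
                    r[i, j] += intake_fixed[i, j]
                    if r[i, j] > R[i, j]:
                        r[i, j] = R[i, j]
            else:
                mean_ = intake_noise[j, 0]
                sd_ = intake_noise[j, 1]
                for i in range(n):
                    if sd_ > 0.0:
                        if zpos == _ZN:
                            zbuf = np.random.standard_normal(_ZN)
                            zpos = 0
                        inc = mean_ + sd_ * zbuf[zpos]
                        zpos += 1
                        if inc < 0.0:
                            inc = 0.0
                    else:
                        inc = mean_
                    r[i, j] += inc
                    if r[i, j] > R[i, j]:
                        r[i, j] = R[i, j]
        elif mode == _NIGHT_REST:
            for j in range(k):
                if night_refill_mask[j]:
                    if np.isfinite(intake_fixed[0, j]):
                        for i in range(n):
                            r[i, j] += intake_fixed[i, j]
                            if r[i, j] > R[i, j]:
                                r[i, j] = R[i, j]
                    else:
                        mean_ = intake_noise[j, 0]
                        sd_ = intake_noise[j, 1]
                        for i in range(n):
                            if sd_ > 0.0:
                                if zpos == _ZN:
                                    zbuf = np.random.standard_normal(_ZN)
                                    zpos = 0
                                inc = mean_ + sd_ * zbuf[zpos]
                                zpos += 1
                                if inc < 0.0:
                                    inc = 0.0
                            else:
                                inc = mean_
                            r[i, j] += inc
                            if r[i, j] > R[i, j]:
                                r[i, j] = R[i, j]

        # death confirmation after intake
        if pend_agent >= 0 and r[pend_agent, pend_need] <= 0.0:
            died_agent = pend_agent
            died_need = pend_need
            died_time = t
            t += 1
            break

        # bout completion for non-preemptible bouts (until the leader's
        # reserve is full); preemption handles the rest
        if mode == _ACT and not (takeover and preempt_mask[cur_need]):
            if r[leader, cur_need] >= R[leader, cur_need] - EPS_FULL:
                if bout_len >= min_bout_len[cur_need]:
                    if cur_event >= 0:
                        ev_bout[cur_event] = bout_len
                    mode = _BOUNDARY
        t += 1

    total_minutes = t
    days_completed = t // STEPS_PER_DAY
    return (
        counts,
        day_minutes,
        night_rest_minutes,
        night_move_minutes,
        total_minutes,
        days_completed,
        died_agent,
        died_need,
        died_time,
        r,
        r_min,
        n_boundaries,
        ev_t[:n_events],
        ev_leader[:n_events],
        ev_need[:n_events],
        ev_bout[:n_events],
    )
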