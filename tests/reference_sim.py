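"""Independent pure-Python reference driver for the two-need dyad model.

Written directly from the model description (one-minute steps, group moves
as a point at 24 m/min on the torus, requirement-proportional reserve
drains, 10 units/min intake at the serving area, leader = largest deficit
scaled by the group-mean requirement, per-minute handover race) and used
to cross-check the compiled kernel step for step.  Deterministic mode only
(mean drains, no noise); exact motivation ties are broken uniformly with
the same seeded legacy generator the kernel uses.
"""
from __future__ import annotations

import math

import numpy as np

TORUS = 96.0
SPEED = 24.0
DRAIN_PER_UNIT = 0.07 / 1000.0  # mean drain per unit of requirement per minute
INTAKE = 10.0


def _delta(a, b):
    d = (b - a) % TORUS
    if d > TORUS / 2:
        d -= TORUS
    return d


def _dist(p, q):
    return math.hypot(_delta(p[0], q[0]), _delta(p[1], q[1]))


def simulate_dyad_reference(R, r0, areas, start, radius, max_minutes, seed):
    """Simulate a deterministic dyad run; returns (counts, reserves, events).

    R, r0: (2, 2) arrays; areas: [(x, y), (x, y)] serving need 0 and 1.
    """
    R = np.asarray(R, dtype=float)
    r = np.asarray(r0, dtype=float).copy()
    norm = R.mean(axis=0)
    np.random.seed(seed)
    np.random.standard_normal(8192)  # the noise buffer, unused when sd = 0
    counts = np.zeros(2, dtype=int)
    events = []
    pos = [float(start[0]), float(start[1])]

    mode = "boundary"
    leader = cur_need = -1
    target = -1
    bout_len = 0

    def select():
        alpha = (R - r) / norm[None, :]
        P = alpha.max(axis=1)
        tied = np.flatnonzero(P >= P.max() - 1e-12)
        lead = int(tied[np.random.randint(0, len(tied))]) if len(tied) > 1 else int(tied[0])
        row = alpha[lead]
        tied = np.flatnonzero(row >= row.max() - 1e-12)
        need = int(tied[np.random.randint(0, len(tied))]) if len(tied) > 1 else int(tied[0])
        return lead, need

    t = 0
    while t < max_minutes:
        if mode == "act" and bout_len >= 1:
            new_leader, new_need = select()
            if new_need == cur_need:
                leader = new_leader
            else:
                leader, cur_need = new_leader, new_need
                mode = "boundary_go"
        if mode in ("boundary", "boundary_go"):
            if mode == "boundary":
                leader, cur_need = select()
            counts[leader] += 1
            events.append((t, leader, cur_need))
            if _dist(pos, areas[cur_need]) > radius:
                mode, target = "move", cur_need
            else:
                mode, bout_len = "act", 0

        if mode == "move":
            d = _dist(pos, areas[target])
            step = min(SPEED, d)
            if d > 0:
                pos[0] = (pos[0] + _delta(pos[0], areas[target][0]) / d * step) % TORUS
                pos[1] = (pos[1] + _delta(pos[1], areas[target][1]) / d * step) % TORUS
            if _dist(pos, areas[target]) <= radius:
                mode, bout_len = "act", 0
        else:
            bout_len += 1

        # requirement-proportional drain on every reserve, every minute
        for i in range(2):
            for j in range(2):
                r[i, j] -= DRAIN_PER_UNIT * R[i, j]
                if r[i, j] < 0:
                    r[i, j] = 0.0
        if mode == "act":
            for i in range(2):
                r[i, cur_need] = min(R[i, cur_need], r[i, cur_need] + INTAKE)
        t += 1
    return counts, r, events
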