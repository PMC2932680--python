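"""Canonical leadership experiments.

Bundles the study designs used throughout: the 3 x 10 dyad requirement
conditions and the replicated macaque-group experiments (10 sampled groups
per condition), with deterministic seeding from a single root seed so any
experiment is reproducible from (design, seed, replicates, days).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import LeadershipDistribution, leadership_shares
from .parameters import GroupSpec, build_dyad_group, build_macaque_group
from .simulator import SimConfig, run_replicates

__all__ = ["GroupRun", "run_group", "dyad_experiment", "macaque_experiment"]


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class GroupRun:
    """Replicated simulation of one group plus its leadership summary."""

    group: GroupSpec
    counts: np.ndarray  # (reps, n)
    distribution: LeadershipDistribution
    mean_budget: dict[str, float]
    deaths: int
    replicates: int

    @property
    def rank_mean_per_replicate(self) -> np.ndarray:
        """Mean over replicates of the within-replicate ranked shares."""
        shares = self.distribution.per_replicate
        shares = shares[~np.isnan(shares).any(axis=1)]
        return np.sort(shares, axis=1)[:, ::-1].mean(axis=0)


def run_group(group: GroupSpec, replicates: int, days: int, seed: int,
              **config_kwargs) -> GroupRun:
    cfg = SimConfig(group=group, max_days=days, replicates=replicates,
                    rng_seed=seed, **config_kwargs)
    _, agg = run_replicates(cfg)
    dist = leadership_shares(agg.counts, agents=[a.id for a in group.agents])
    return GroupRun(group=group, counts=agg.counts, distribution=dist,
                    mean_budget=agg.mean_budget, deaths=agg.deaths,
                    replicates=replicates)


def dyad_experiment(condition: int, replicates: int, days: int, seed: int,
                    ) -> list[GroupRun]:
    """All ten requirement groups of one dyad condition."""
    runs = []
    for gi in range(1, 11):
        group = build_dyad_group(condition, gi)
        runs.append(run_group(group, replicates, days,
                              _derive_seed(seed, condition, gi)))
    return runs


def macaque_experiment(n: int, heterogeneous: bool, n_groups: int,
                       replicates: int, days: int, seed: int) -> list[GroupRun]:
    """``n_groups`` independently sampled macaque groups of size ``n``."""
    runs = []
    for gi in range(n_groups):
        gseed = _derive_seed(seed, n, int(heterogeneous), gi, 1)
        group = build_macaque_group(n, heterogeneous, gseed)
        runs.append(run_group(group, replicates, days,
                              _derive_seed(seed, n, int(heterogeneous), gi, 2)))
    return runs
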