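"""Statistics on simulated leadership distributions.

Covers the downstream analyses of the leadership experiments: pooled and
per-replicate leadership shares, rank curves with linear / exponential /
power / logarithmic fits, relative-requirement and relative-mass ratios,
nonparametric comparisons (two-sample Kolmogorov-Smirnov for dyads,
Kruskal-Wallis for larger groups), and the Hill-sigmoid threshold analysis
relating an individual's leadership share to how far its requirements (or
body mass) exceed those of its groupmates::

    y = x^n / (x^n + S^n)

with threshold ``S`` (the ratio at which leadership switches on) and
sensitivity ``n`` (the steepness of the switch).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .parameters import GroupSpec

__all__ = [
    "LeadershipDistribution",
    "FitResult",
    "leadership_shares",
    "rank_curve",
    "need_ratio",
    "mass_ratio",
    "fit_curve",
    "compare_distributions",
    "threshold_analysis",
    "never_leader_counts",
]


@dataclass
class LeadershipDistribution:
    """Leadership shares for one group, pooled over replicates."""

    agents: list[str]
    shares: np.ndarray  # (n,) pooled over replicates
    per_replicate: np.ndarray  # (reps, n); rows with no decisions are NaN
    ranked_shares: np.ndarray = field(init=False)  # descending

    def __post_init__(self) -> None:
        if np.any(self.shares < 0):
            raise ValueError("shares must be non-negative")
        if not np.isclose(self.shares.sum(), 1.0):
            raise ValueError("shares must sum to 1")
        self.ranked_shares = np.sort(self.shares)[::-1]


@dataclass
class FitResult:
    family: str  # linear | exponential | power | logarithmic | hill
    params: dict[str, float]
    r_squared: float
    n_points: int
    f_statistic: float | None = None
    p_value: float | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "linear":
            return p["slope"] * x + p["intercept"]
        if self.family == "exponential":
            return p["A"] * np.exp(-p["k"] * x)
        if self.family == "power":
            return p["A"] * x ** (-p["k"])
        if self.family == "logarithmic":
            return p["a"] + p["b"] * np.log(x)
        if self.family == "hill":
            return x ** p["n"] / (x ** p["n"] + p["S"] ** p["n"])
        raise ValueError(f"unknown family {self.family!r}")


def leadership_shares(counts: np.ndarray, agents: Sequence[str] | None = None,
                      ) -> LeadershipDistribution:
    """Pooled and per-replicate leadership shares from raw counts.

    ``counts`` is (replicates, n_agents) leadership counts (a 1-D array is
    treated as a single replicate).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.sum() == 0:
        raise ValueError("no decision events across replicates")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_rep = np.where(totals > 0, counts / totals, np.nan)
    pooled = counts.sum(axis=0)
    names = list(agents) if agents is not None else [str(i) for i in range(counts.shape[1])]
    return LeadershipDistribution(agents=names, shares=pooled / pooled.sum(),
                                  per_replicate=per_rep)


def rank_curve(distributions: Iterable[LeadershipDistribution]) -> pd.DataFrame:
    """Mean / min / max pooled share per rank across groups.

    Within each group agents are ranked from most- to least-frequent
    leader; ranks are then aggregated across groups.
    """
    ranked = np.array([d.ranked_shares for d in distributions])
    n = ranked.shape[1]
    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "mean_share": ranked.mean(axis=0),
            "min_share": ranked.min(axis=0),
            "max_share": ranked.max(axis=0),
        }
    )


def need_ratio(group: GroupSpec, agent_index: int) -> float:
    """Max over needs of agent's requirement over its groupmates' mean."""
    if group.n < 2:
        raise ValueError("need at least two agents")
    R = group.requirement_matrix()
    others = np.delete(np.arange(group.n), agent_index)
    return float(np.max(R[agent_index] / R[others].mean(axis=0)))


def mass_ratio(group: GroupSpec, agent_index: int) -> float:
    """Agent's body mass over the mean mass of its groupmates."""
    if group.n < 2:
        raise ValueError("need at least two agents")
    masses = np.array([a.mass_kg for a in group.agents])
    others = np.delete(np.arange(group.n), agent_index)
    return float(masses[agent_index] / masses[others].mean())


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def _fit_stats(y: np.ndarray, yhat: np.ndarray, n_params: int):
    n = len(y)
    df1, df2 = 1, n - n_params
    r2 = _r_squared(y, yhat)
    if df2 <= 0 or r2 >= 1.0:
        return r2, None, None
    f = (r2 / df1) / ((1 - r2) / df2)
    p = float(stats.f.sf(f, df1, df2))
    return r2, float(f), p


HILL_S_BOUNDS = (1e-3, 10.0)
HILL_N_BOUNDS = (1.0, 100.0)


def fit_curve(x: np.ndarray, y: np.ndarray, family: str) -> FitResult:
    """Least-squares fit of one curve family.

    Families: linear, exponential (A·e^(−kx)), power (A·x^(−k)),
    logarithmic (a + b·ln x), hill (x^n/(x^n+S^n), S and n bounded, fitted
    with a multi-start grid).  R² is computed against the mean-only model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_params = 2
    if len(x) != len(y) or len(x) < n_params + 1:
        raise ValueError("need len(x) == len(y) >= number of parameters + 1")
    if family == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        if np.allclose(y, y[0]):
            slope = 0.0
            intercept = float(y[0])
        yhat = slope * x + intercept
        r2, f, p = _fit_stats(y, yhat, n_params)
        return FitResult("linear", {"slope": float(slope), "intercept": float(intercept)},
                         r2, len(x), f, p)
    if family in ("exponential", "power", "logarithmic"):
        if family == "exponential":
            fn = lambda x, A, k: A * np.exp(-k * x)
            p0s = [(max(y.max(), 1e-6), k0) for k0 in (0.5, 2.0, 5.0, 10.0)]
            names = ("A", "k")
        elif family == "power":
            if np.any(x <= 0):
                raise ValueError("power fit needs positive x")
            fn = lambda x, A, k: A * x ** (-k)
            p0s = [(max(y.max(), 1e-6), k0) for k0 in (0.5, 2.0, 5.0)]
            names = ("A", "k")
        else:
            if np.any(x <= 0):
                raise ValueError("logarithmic fit needs positive x")
            fn = lambda x, a, b: a + b * np.log(x)
            b0 = (y[-1] - y[0]) / max(np.log(x[-1] / x[0]), 1e-9) if x[-1] != x[0] else 1.0
            p0s = [(float(y.mean()), float(b0))]
            names = ("a", "b")
        best = None
        last_err: Exception | None = None
        for p0 in p0s:
            try:
                popt, _ = optimize.curve_fit(fn, x, y, p0=p0, maxfev=20000)
            except (RuntimeError, optimize.OptimizeWarning) as err:  # pragma: no cover
                last_err = err
                continue
            r2 = _r_squared(y, fn(x, *popt))
            if best is None or r2 > best[1]:
                best = (popt, r2)
        if best is None:
            raise RuntimeError(f"{family} fit failed to converge: {last_err}")
        popt, _ = best
        yhat = fn(x, *popt)
        r2, f, p = _fit_stats(y, yhat, n_params)
        return FitResult(family, dict(zip(names, map(float, popt))), r2, len(x), f, p)
    if family == "hill":
        if np.any(x <= 0):
            raise ValueError("hill fit needs positive x")
        fn = lambda x, S, n: x ** n / (x ** n + S ** n)
        best = None
        for S0 in (0.5, 1.0, 1.37, 1.7, 2.0, 3.0):
            for n0 in (2.0, 5.0, 15.0, 30.0, 60.0):
                try:
                    popt, _ = optimize.curve_fit(
                        fn, x, y, p0=[S0, n0],
                        bounds=([HILL_S_BOUNDS[0], HILL_N_BOUNDS[0]],
                                [HILL_S_BOUNDS[1], HILL_N_BOUNDS[1]]),
                        maxfev=20000,
                    )
                except RuntimeError:
                    continue
                r2 = _r_squared(y, fn(x, *popt))
                if best is None or r2 > best[1]:
                    best = (popt, r2)
        if best is None:
            raise RuntimeError("hill fit failed to converge from every start")
        popt, _ = best
        yhat = fn(x, *popt)
        r2, f, p = _fit_stats(y, yhat, n_params)
        return FitResult("hill", {"S": float(popt[0]), "n": float(popt[1])}, r2, len(x), f, p)
    raise ValueError(f"unknown family {family!r}")


def fit_rank_curve(ranked_mean_shares: np.ndarray, family: str) -> FitResult:
    """Fit a family to a mean rank curve.

    x is the rank fraction rank/n and y the leadership ratio share·n
    (share relative to the equal-share baseline 1/n), the scale on which
    exponential decay constants of rank curves are comparable across group
    sizes.
    """
    y = np.asarray(ranked_mean_shares, dtype=float)
    n = len(y)
    x = np.arange(1, n + 1) / n
    return fit_curve(x, y * n, family)


def compare_distributions(per_replicate_shares: np.ndarray, alpha: float = 0.05) -> dict:
    """Test whether leadership differs between individuals.

    Dyads: two-sample Kolmogorov-Smirnov on the agents' per-replicate
    shares.  Groups of three or more: Kruskal-Wallis across agents.
    """
    shares = np.asarray(per_replicate_shares, dtype=float)
    shares = shares[~np.isnan(shares).any(axis=1)]
    if shares.shape[0] < 2:
        raise ValueError("need at least two replicates with decisions")
    n = shares.shape[1]
    if n == 2:
        stat, p = stats.ks_2samp(shares[:, 0], shares[:, 1])
        test = "kolmogorov-smirnov"
    else:
        stat, p = stats.kruskal(*[shares[:, i] for i in range(n)])
        test = "kruskal-wallis"
    return {"test": test, "statistic": float(stat), "p_value": float(p),
            "significant": bool(p < alpha), "alpha": alpha}


def threshold_analysis(groups: Sequence[GroupSpec],
                       distributions: Sequence[LeadershipDistribution],
                       predictor: str = "need") -> tuple[FitResult, pd.DataFrame]:
    """Hill-sigmoid threshold of leadership share vs relative requirement.

    Pools one point per individual per group: x = the agent's need ratio
    (or mass ratio), y = its pooled leadership share.  Returns the Hill
    fit and the pooled point table.
    """
    if len(groups) != len(distributions):
        raise ValueError("one distribution per group required")
    if len(groups) < 2:
        raise ValueError("pool at least two groups")
    rows = []
    for g, d in zip(groups, distributions):
        for i, agent in enumerate(g.agents):
            x = need_ratio(g, i) if predictor == "need" else mass_ratio(g, i)
            rows.append({"group": g.label, "agent": agent.id, "ratio": x,
                         "share": d.shares[i]})
    pts = pd.DataFrame(rows)
    if pts["ratio"].max() - pts["ratio"].min() < 1e-6:
        raise ValueError("degenerate predictor range; pooled groups are too similar")
    fit = fit_curve(pts["ratio"].to_numpy(), pts["share"].to_numpy(), "hill")
    return fit, pts


def never_leader_counts(counts: np.ndarray) -> np.ndarray:
    """Number of agents with zero leads in each replicate.

    ``counts`` is (replicates, n_agents).
    """
    counts = np.atleast_2d(np.asarray(counts))
    return (counts == 0).sum(axis=1)
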