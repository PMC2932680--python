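import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leadsim as ls
from leadsim import analysis


class TestLeadershipShares:
    def test_normalization(self):
        dist = analysis.leadership_shares(np.array([[30, 10]]))
        assert dist.shares == pytest.approx([0.75, 0.25])
        assert dist.ranked_shares == pytest.approx([0.75, 0.25])

    def test_pooled_vs_per_replicate(self):
        counts = np.array([[10, 0], [0, 30]])
        dist = analysis.leadership_shares(counts)
        assert dist.shares == pytest.approx([0.25, 0.75])
        assert np.allclose(dist.per_replicate, [[1, 0], [0, 1]])

    def test_zero_decisions_rejected(self):
        with pytest.raises(ValueError, match="no decision"):
            analysis.leadership_shares(np.zeros((3, 4)))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.lists(st.integers(0, 50), min_size=4, max_size=4),
                    min_size=1, max_size=6))
    def test_shares_sum_to_one_on_every_path(self, counts):
        counts = np.array(counts)
        if counts.sum() == 0:
            return
        dist = analysis.leadership_shares(counts)
        assert dist.shares.sum() == pytest.approx(1.0)
        ok = ~np.isnan(dist.per_replicate).any(axis=1)
        assert dist.per_replicate[ok].sum(axis=1) == pytest.approx(np.ones(ok.sum()))


class TestRatios:
    def test_dyad_condition3_ratio(self):
        g = ls.build_dyad_group(3, 10)
        # per-need ratio equals the sum convention for this symmetric design
        assert analysis.need_ratio(g, 0) == pytest.approx(1.45)

    def test_identical_agents_ratio_one(self):
        g = ls.build_macaque_group(10, False, rng_seed=0)
        assert analysis.need_ratio(g, 3) == pytest.approx(1.0)
        assert analysis.mass_ratio(g, 3) == pytest.approx(1.0)

    def test_mass_ratio_hand_computed(self):
        g = ls.build_macaque_group(5, True, rng_seed=1)
        for a, m in zip(g.agents, (15.0, 10.0, 5.0, 5.0, 5.0)):
            a.mass_kg = m
        assert analysis.mass_ratio(g, 0) == pytest.approx(15.0 / 6.25)
        g.agents[1].mass_kg = 10.0
        masses = np.array([a.mass_kg for a in g.agents])
        assert analysis.mass_ratio(g, 1) == pytest.approx(10.0 / np.delete(masses, 1).mean())


class TestFitCurve:
    def test_exponential_self_consistency(self):
        x = np.arange(1, 11) / 10.0
        y = 3.5727 * np.exp(-4.602 * x)
        fit = analysis.fit_curve(x, y, "exponential")
        assert fit.params["A"] == pytest.approx(3.5727, rel=1e-4)
        assert fit.params["k"] == pytest.approx(4.602, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0)

    def test_power_self_consistency(self):
        x = np.arange(1, 21, dtype=float)
        y = 11.48 * x ** -4.86
        fit = analysis.fit_curve(x, y, "power")
        assert fit.params["A"] == pytest.approx(11.48, rel=1e-3)
        assert fit.params["k"] == pytest.approx(4.86, rel=1e-3)

    def test_hill_parameter_recovery_noiseless(self):
        x = np.linspace(1.0, 2.0, 40)
        y = x ** 30 / (x ** 30 + 1.37 ** 30)
        fit = analysis.fit_curve(x, y, "hill")
        assert fit.params["S"] == pytest.approx(1.37, abs=0.01)
        assert fit.params["n"] == pytest.approx(30, rel=0.05)

    def test_constant_y_gives_zero_r2_zero_slope(self):
        x = np.arange(10, dtype=float)
        y = np.full(10, 3.3)
        fit = analysis.fit_curve(x, y, "linear")
        assert fit.params["slope"] == 0.0
        assert fit.r_squared == 0.0

    def test_step_function_pushes_hill_to_bounds(self):
        x = np.linspace(0.5, 4.0, 60)
        y = (x > 2.0).astype(float)
        fit = analysis.fit_curve(x, y, "hill")
        assert fit.params["S"] == pytest.approx(2.0, abs=0.1)
        assert fit.params["n"] == pytest.approx(analysis.HILL_N_BOUNDS[1], rel=0.05)

    def test_hill_recovery_under_noise(self, rng):
        """Median |S_hat - S| < 0.05 over 100 noisy synthetic datasets."""
        errs = []
        for _ in range(100):
            S = rng.uniform(1.1, 2.2)
            x = np.linspace(0.8, 3.0, 50)
            y = x ** 25 / (x ** 25 + S ** 25) + rng.normal(0, 0.05, size=50)
            fit = analysis.fit_curve(x, y, "hill")
            errs.append(abs(fit.params["S"] - S))
        assert np.median(errs) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            analysis.fit_curve(np.array([1.0, 2.0]), np.array([1.0, 2.0]), "linear")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            analysis.fit_curve(np.arange(5.0), np.arange(5.0), "spline")


class TestCompareDistributions:
    def test_identical_samples_ks_zero(self):
        shares = np.tile([0.5, 0.5], (20, 1))
        report = analysis.compare_distributions(shares)
        assert report["test"] == "kolmogorov-smirnov"
        assert report["statistic"] == pytest.approx(0.0)
        assert not report["significant"]

    def test_separated_samples_significant(self, rng):
        a = rng.normal(0.8, 0.01, 50)
        shares = np.column_stack([a, 1 - a])
        report = analysis.compare_distributions(shares)
        assert report["significant"]

    def test_kruskal_for_larger_groups(self, rng):
        shares = rng.dirichlet(np.ones(5), size=30)
        report = analysis.compare_distributions(shares)
        assert report["test"] == "kruskal-wallis"

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            analysis.compare_distributions(np.array([[0.5, 0.5]]))


class TestThresholdAnalysis:
    def test_degenerate_predictor_rejected(self):
        groups = [ls.build_macaque_group(10, False, rng_seed=s) for s in (0, 1)]
        dists = [analysis.leadership_shares(np.ones((1, 10))) for _ in groups]
        with pytest.raises(ValueError, match="degenerate"):
            analysis.threshold_analysis(groups, dists, predictor="need")

    def test_pooled_points_cover_all_individuals(self):
        groups = [ls.build_macaque_group(10, True, rng_seed=s) for s in (0, 1)]
        dists = [analysis.leadership_shares(np.ones((1, 10))) for _ in groups]
        fit, pts = analysis.threshold_analysis(groups, dists, predictor="mass")
        assert len(pts) == 20
        assert fit.family == "hill"


class TestNeverLeaders:
    def test_counts_per_replicate(self):
        counts = np.array([[0, 3, 0, 9], [1, 1, 1, 1]])
        assert analysis.never_leader_counts(counts).tolist() == [2, 0]
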