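import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leadsim.dynamics as dyn
from leadsim.dynamics import (
    activity_done,
    pack_group,
    probability_to_lead,
    select_leader,
    step_expenditure,
    step_intake,
)
from leadsim.parameters import NeedKind, build_dyad_group, build_macaque_group


@pytest.fixture(scope="module")
def packed_het():
    return pack_group(build_macaque_group(10, True, rng_seed=42))


@pytest.fixture(scope="module")
def packed_dyad():
    return pack_group(build_dyad_group(3, 10))


class TestProbabilityToLead:
    def test_bounds_own_normalization(self):
        R = np.array([[100.0, 200.0]])
        assert probability_to_lead(R, R, "own") == pytest.approx(np.zeros((1, 2)))
        assert probability_to_lead(np.zeros((1, 2)), R, "own") == pytest.approx(np.ones((1, 2)))
        assert probability_to_lead(R / 2, R, "own") == pytest.approx(0.5 * np.ones((1, 2)))

    def test_group_mean_scales_deficits(self):
        R = np.array([[200.0], [100.0]])
        r = np.array([[100.0], [50.0]])
        alpha = probability_to_lead(r, R, "group_mean")
        # equal halves, but the large agent's absolute deficit is twice as big
        assert alpha[0, 0] == pytest.approx(2 * alpha[1, 0])

    def test_monotone_decreasing_in_reserve(self):
        R = np.full((3, 2), 50.0)
        lo = probability_to_lead(np.full((3, 2), 10.0), R)
        hi = probability_to_lead(np.full((3, 2), 40.0), R)
        assert np.all(lo > hi)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            probability_to_lead(np.zeros((1, 1)), np.zeros((1, 1)))
        with pytest.raises(ValueError, match="reserves"):
            probability_to_lead(np.array([[2.0]]), np.array([[1.0]]))

    @settings(max_examples=100, deadline=None)
    @given(frac=st.floats(0.0, 1.0))
    def test_alpha_in_unit_interval_own(self, frac):
        R = np.array([[123.0, 7.0], [50.0, 9.0]])
        alpha = probability_to_lead(R * frac, R, "own")
        assert np.all((alpha >= 0) & (alpha <= 1))


class TestSelectLeader:
    def test_argmax(self, rng):
        alpha = np.array([[0.9, 0.1], [0.2, 0.1]])
        leader, need = select_leader(alpha, rng)
        assert (leader, need) == (0, 0)

    def test_target_is_leaders_worst_need(self, rng):
        alpha = np.array([[0.1, 0.6, 0.3], [0.2, 0.2, 0.5]])
        leader, need = select_leader(alpha, rng)
        assert (leader, need) == (0, 1)

    def test_tie_broken_uniformly(self):
        rng = np.random.default_rng(1234)
        alpha = np.array([[0.5], [0.5]])
        picks = [select_leader(alpha, rng)[0] for _ in range(10_000)]
        share = np.mean(picks)
        assert abs(share - 0.5) < 0.02

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            select_leader(np.empty((0, 2)), rng)


class TestStepExpenditure:
    def test_resting_energy_decrement_scales_with_mass(self, packed_het):
        # deterministic resting decrement = 0.10 KJ/min/kg x mass
        k_energy = 1
        k_rest = 4
        dec = step_expenditure(packed_het, activity=k_rest, rng=None, deterministic=True)
        assert dec[:, k_energy] == pytest.approx(0.10 * packed_het.mass)

    def test_adult_male_reference_value(self):
        g = build_macaque_group(10, False, rng_seed=0, homogeneous_category="adult_male")
        p = pack_group(g)
        dec = step_expenditure(p, activity=4, rng=None, deterministic=True)
        assert dec[0, 1] == pytest.approx(0.10 * 15.18)  # 1.518 KJ/min

    def test_blank_cells_zero(self, packed_het):
        # water foraging: no social-time expenditure row entry beyond req/720,
        # and no energy drain is charged to the social reserve
        dec = step_expenditure(packed_het, activity=2, rng=None, deterministic=True)
        soc = 3
        expected_soc = packed_het.drain_always[:, soc, 0]
        assert dec[:, soc] == pytest.approx(expected_soc)

    def test_own_bout_suspends_social_drain(self, packed_het):
        dec = step_expenditure(packed_het, activity=3, rng=None, deterministic=True)
        assert np.all(dec[:, 3] == 0.0)

    def test_night_freezes_social_and_protein(self, packed_het):
        dec = step_expenditure(packed_het, activity=packed_het.k + 1, rng=None,
                               deterministic=True, night=True)
        assert np.all(dec[:, 0] == 0.0)  # protein
        assert np.all(dec[:, 3] == 0.0)  # social
        assert np.all(dec[:, 1] > 0.0)  # energy still burns overnight

    def test_noise_truncated_at_zero(self, packed_het, rng):
        for _ in range(50):
            dec = step_expenditure(packed_het, activity=1, rng=rng)
            assert np.all(dec >= 0.0)

    def test_dyad_drain_proportional_to_requirement(self, packed_dyad):
        dec = step_expenditure(packed_dyad, activity=0, rng=None, deterministic=True)
        assert dec[0, 0] == pytest.approx(0.07 * 1.45)  # requirement 1450
        assert dec[1, 0] == pytest.approx(0.07)  # requirement 1000


class TestStepIntake:
    def test_dyad_fill_rate(self, packed_dyad):
        inc = step_intake(packed_dyad, activity=0, at_area=True, rng=None,
                          deterministic=True)
        assert inc[:, 0] == pytest.approx(10.0)
        assert inc[:, 1] == pytest.approx(0.0)

    def test_only_matching_need_refills(self, packed_het, rng):
        inc = step_intake(packed_het, activity=1, at_area=True, rng=rng)
        others = [j for j in range(packed_het.k) if j != 1]
        assert np.all(inc[:, others] == 0.0)

    def test_away_from_area_is_a_driver_bug(self, packed_het, rng):
        with pytest.raises(ValueError, match="serving area"):
            step_intake(packed_het, activity=2, at_area=False, rng=rng)

    def test_in_place_activities_need_no_area(self, packed_het, rng):
        inc = step_intake(packed_het, activity=3, at_area=False, rng=rng)
        assert np.all(inc[:, 3] >= 0.0)

    def test_water_noise_never_negative(self, packed_het, rng):
        for _ in range(200):
            inc = step_intake(packed_het, activity=2, at_area=True, rng=rng)
            assert np.all(inc[:, 2] >= 0.0)


class TestActivityDone:
    def test_nutrient_done_at_leader_capacity(self, packed_het):
        r = packed_het.R.copy()
        assert activity_done(packed_het, r, leader=0, activity=1, bout_length=3)
        r[0, 1] -= 1.0
        assert not activity_done(packed_het, r, leader=0, activity=1, bout_length=3)

    def test_social_requires_minimum_bout(self, packed_het):
        r = packed_het.R.copy()
        assert not activity_done(packed_het, r, leader=0, activity=3, bout_length=3)
        assert activity_done(packed_het, r, leader=0, activity=3, bout_length=5)

    def test_night_ends_only_at_dawn(self, packed_het):
        r = packed_het.R.copy()
        assert not activity_done(packed_het, r, leader=0, activity=4, bout_length=700,
                                 night=True, step_of_day=700)
        assert activity_done(packed_het, r, leader=0, activity=4, bout_length=720,
                             night=True, step_of_day=0)


class TestReserveAccounting:
    def test_conservation_in_deterministic_mode(self, packed_dyad):
        """Reserve change per step equals intake minus expenditure pre-clamp."""
        r = packed_dyad.R * 0.5
        dec = step_expenditure(packed_dyad, activity=0, rng=None, deterministic=True)
        inc = step_intake(packed_dyad, activity=0, at_area=True, rng=None,
                          deterministic=True)
        r_new = r - dec + inc
        assert r_new - r == pytest.approx(inc - dec)

    def test_bounds_hold_over_many_random_steps(self, packed_het, rng):
        r = packed_het.R.copy() * rng.uniform(0.2, 1.0, size=packed_het.R.shape)
        for step in range(2000):
            act = int(rng.integers(0, packed_het.k))
            r -= step_expenditure(packed_het, act, rng)
            r = np.maximum(r, 0.0)
            r += step_intake(packed_het, act, at_area=True, rng=rng)
            r = np.minimum(r, packed_het.R)
            assert np.all(r >= 0.0) and np.all(r <= packed_het.R)
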