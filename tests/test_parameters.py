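import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leadsim.parameters as par
from leadsim.parameters import (
    COMPOSITION_TABLE,
    NeedKind,
    build_dyad_group,
    build_macaque_group,
    dyad_requirement_table,
    nutrient_requirements,
    sample_composition,
)

# the full dyad requirement design table, written out independently:
# condition 1: all four values equal, rising 500..1500 (no 1000);
# condition 2: a2 and b1 mirror a1 and b2; condition 3: A rises 1000..1450
# in steps of 50 against a constant 1000 for B
_SEQ = [500, 600, 700, 800, 900, 1100, 1200, 1300, 1400, 1500]
EXPECTED_TABLE = {}
for g in range(1, 11):
    v = _SEQ[g - 1]
    EXPECTED_TABLE[(1, g)] = (v, v, v, v)
    EXPECTED_TABLE[(2, g)] = (v, _SEQ[10 - g], _SEQ[10 - g], v)
    EXPECTED_TABLE[(3, g)] = (1000 + 50 * (g - 1), 1000 + 50 * (g - 1), 1000, 1000)


class TestNutrientRequirements:
    def test_adult_male_protein_matches_category_table(self):
        req = nutrient_requirements("adult_male", 15.18)
        assert req[NeedKind.PROTEIN] == pytest.approx(38.557, abs=1e-3)
        # category table prints 38.55 +/- 3.40 for adult males
        assert abs(req[NeedKind.PROTEIN] - 38.55) < 0.01

    def test_cycling_female_formulas(self):
        req = nutrient_requirements("cycling_female", 10.0)
        assert req[NeedKind.PROTEIN] == pytest.approx(25.4)
        assert req[NeedKind.ENERGY] == pytest.approx(3517.0)
        assert req[NeedKind.WATER] == pytest.approx(844.08)

    def test_water_tracks_energy(self):
        for cat in ("adult_male", "cycling_female", "lactating_female", "juvenile"):
            req = nutrient_requirements(cat, 6.5)
            assert req[NeedKind.WATER] == pytest.approx(0.24 * req[NeedKind.ENERGY])

    def test_lactating_multipliers(self):
        base = nutrient_requirements("cycling_female", 9.85)
        lact = nutrient_requirements("lactating_female", 9.85)
        assert lact[NeedKind.PROTEIN] / base[NeedKind.PROTEIN] == pytest.approx(1.25)
        assert lact[NeedKind.ENERGY] / base[NeedKind.ENERGY] == pytest.approx(2.0)
        assert lact[NeedKind.WATER] / base[NeedKind.WATER] == pytest.approx(2.0)

    @pytest.mark.parametrize("mass", [0.0, -3.2])
    def test_nonpositive_mass_rejected(self, mass):
        with pytest.raises(ValueError, match="mass"):
            nutrient_requirements("cycling_female", mass)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            nutrient_requirements("gibbon", 5.0)


class TestDyadBuilder:
    def test_full_design_table(self):
        assert dyad_requirement_table() == EXPECTED_TABLE

    @pytest.mark.parametrize(
        "condition,group,expected",
        [
            (3, 10, (1450, 1450, 1000, 1000)),
            (1, 1, (500, 500, 500, 500)),
            (2, 5, (900, 1100, 1100, 900)),
        ],
    )
    def test_printed_examples(self, condition, group, expected):
        g = build_dyad_group(condition, group)
        a, b = g.agents
        got = (
            a.daily_requirement[NeedKind.NEED1],
            a.daily_requirement[NeedKind.NEED2],
            b.daily_requirement[NeedKind.NEED1],
            b.daily_requirement[NeedKind.NEED2],
        )
        assert got == expected

    def test_condition2_sums_balance(self):
        for gi in range(1, 11):
            g = build_dyad_group(2, gi)
            a, b = g.agents
            assert sum(a.daily_requirement.values()) == sum(b.daily_requirement.values())

    @pytest.mark.parametrize("condition,group", [(0, 1), (4, 1), (1, 0), (1, 11)])
    def test_out_of_range_rejected(self, condition, group):
        with pytest.raises(ValueError):
            build_dyad_group(condition, group)


class TestMacaqueBuilder:
    def test_composition_respects_bounds(self, rng):
        for _ in range(1000):
            comp = sample_composition(10, rng)
            assert sum(comp.values()) == 10
            for cat, (_, _, lo, hi) in COMPOSITION_TABLE.items():
                assert lo <= comp[cat] <= hi

    def test_heterogeneous_roster(self):
        g = build_macaque_group(10, True, rng_seed=3)
        assert g.n == 10
        cats = {a.category for a in g.agents}
        assert "adult_male" in cats  # at least one male always
        for a in g.agents:
            req = nutrient_requirements(a.category, a.mass_kg)
            assert a.daily_requirement[NeedKind.PROTEIN] == pytest.approx(req[NeedKind.PROTEIN])
            assert a.daily_requirement[NeedKind.WATER] == pytest.approx(
                0.24 * a.daily_requirement[NeedKind.ENERGY])

    def test_homogeneous_roster_identical(self):
        g = build_macaque_group(10, False, rng_seed=3)
        first = g.agents[0]
        for a in g.agents[1:]:
            assert a.category == first.category
            assert a.mass_kg == first.mass_kg
            assert a.daily_requirement == first.daily_requirement
            assert a.intake == first.intake

    def test_partition_sums_for_n20(self):
        g = build_macaque_group(20, True, rng_seed=9)
        assert g.n == 20

    def test_bad_size_rejected_unless_permitted(self):
        with pytest.raises(ValueError, match="allow_any_size"):
            build_macaque_group(7, True, rng_seed=0)
        g = build_macaque_group(7, True, rng_seed=0, allow_any_size=True)
        assert g.n == 7

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_masses_positive_and_floored(self, seed):
        g = build_macaque_group(10, True, rng_seed=seed)
        for a in g.agents:
            assert a.mass_kg >= par.MASS_FLOOR_KG


class TestGroupSpecSerialization:
    def test_json_round_trip(self):
        g = build_macaque_group(5, True, rng_seed=1)
        g2 = par.GroupSpec.from_json(g.to_json())
        assert g2.model_variant == g.model_variant
        for a, b in zip(g.agents, g2.agents):
            assert a == b

    def test_mixed_need_sets_rejected(self):
        g1 = build_dyad_group(1, 1)
        g2 = build_macaque_group(5, False, rng_seed=0)
        with pytest.raises(ValueError, match="need set"):
            par.GroupSpec(agents=[g1.agents[0], g2.agents[0]], model_variant="dyad")
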