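"""The six policy constructors and their effect mechanics."""
import numpy as np
import pytest

from oncosim import (
    PriceShock,
    apply_mup,
    apply_price_intervention,
    build_intervention,
    effect_at_time,
    initialize_population,
    select_exposed,
)
from oncosim.constants import F_ALCOHOL
from oncosim.interventions import (
    INTERVENTION_NAMES,
    alcohol_cell_changes,
    apply_risk_factor_effect,
    eligible_mask,
    mup_price_uplift,
    schedule_fraction,
    shifted_exposure,
    with_magnitude,
)


class TestConstructors:
    """Each policy carries its published target, exposure, and effect values."""

    def test_menu_labelling(self):
        s = build_intervention("menu_labelling")
        assert s.target_age == (6, None)
        assert s.exposure_fraction == 0.12
        assert s.magnitude_range == (0.0105, 0.0131)
        assert schedule_fraction(s, 1.0) == 1.0  # full effect after 1 year

    def test_food_labelling(self):
        s = build_intervention("food_labelling")
        assert s.target_age == (6, None)
        assert s.exposure_fraction == 0.15
        assert s.effect_magnitude == 0.0040
        assert s.magnitude_range is None

    def test_mass_media(self):
        s = build_intervention("mass_media")
        assert s.target_age == (19, None)
        assert s.exposure_fraction == 1.0
        assert effect_at_time(s, 1.0 / 12.0) == pytest.approx(0.60)
        assert effect_at_time(s, 1.0) == pytest.approx(0.30)
        assert effect_at_time(s, 2.0) == 0.0
        assert effect_at_time(s, 7.5) == 0.0

    def test_workplace_sedentary(self):
        s = build_intervention("workplace_sedentary")
        assert s.target_age == (18, 65)
        assert s.exposure_range == (0.0231, 0.0695)
        assert s.exposure_fraction == 0.0463  # range midpoint
        assert s.participation == 0.5  # enterprise uptake
        assert s.effect_magnitude == 72.78  # minutes per 8-h workday

    def test_alcohol_tax(self):
        s = build_intervention("alcohol_tax")
        assert s.target_age == (0, None)
        assert s.exposure_fraction == 1.0
        assert s.price_shock.price_change == 0.10
        assert s.price_shock.mup_floor is None

    def test_minimum_unit_pricing(self):
        s = build_intervention("minimum_unit_pricing")
        assert s.exposure_fraction == 1.0
        assert s.price_shock.mup_floor is not None

    def test_aliases_resolve(self):
        assert build_intervention("workplace_sb").name == "workplace_sedentary"
        assert build_intervention("mup").name == "minimum_unit_pricing"

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_intervention("bicycle_subsidy")


class TestEffectSchedule:
    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            effect_at_time(build_intervention("mass_media"), -0.1)

    def test_sustained_policies_hold_full_effect(self):
        for name in ("food_labelling", "workplace_sedentary", "alcohol_tax"):
            s = build_intervention(name)
            for t in (0.0, 1.0, 10.0, 31.0):
                assert schedule_fraction(s, t) == 1.0

    def test_media_decays_linearly_between_knots(self):
        s = build_intervention("mass_media")
        t_mid = (1.0 / 12.0 + 1.0) / 2.0
        expected = (1.0 + 0.5) / 2.0 * 0.60
        assert effect_at_time(s, t_mid) == pytest.approx(expected)


class TestExposureSampling:
    @pytest.fixture()
    def pop(self, world):
        return initialize_population(world.profile, world.distributions, seed=40)

    @pytest.mark.parametrize(
        "name,expected_p",
        [("menu_labelling", 0.12), ("food_labelling", 0.15), ("workplace_sedentary", 0.0463 * 0.5)],
    )
    def test_exposed_share_within_three_se(self, pop, name, expected_p):
        spec = build_intervention(name)
        select_exposed(pop, spec, seed=40)
        elig = eligible_mask(pop, spec)
        n = int(elig.sum())
        share = pop.exposed[elig].mean()
        se = np.sqrt(expected_p * (1 - expected_p) / n)
        assert abs(share - expected_p) <= 3 * se

    def test_zero_exposure_fraction_exposes_nobody(self, pop):
        spec = build_intervention("menu_labelling")
        spec = type(spec)(**{**spec.__dict__, "exposure_fraction": 0.0})
        select_exposed(pop, spec, seed=40)
        assert not pop.exposed.any()

    def test_mass_media_reaches_every_adult(self, pop):
        spec = build_intervention("mass_media")
        select_exposed(pop, spec, seed=40)
        elig = eligible_mask(pop, spec)
        assert np.array_equal(pop.exposed, elig)
        assert (pop.ages()[pop.exposed] > 18).all()

    @pytest.mark.parametrize("name", INTERVENTION_NAMES)
    def test_no_ineligible_individual_is_exposed(self, pop, name):
        spec = build_intervention(name)
        select_exposed(pop, spec, seed=40)
        assert not (pop.exposed & ~eligible_mask(pop, spec)).any()

    def test_menu_effect_draws_span_the_published_range(self, pop):
        spec = build_intervention("menu_labelling")
        select_exposed(pop, spec, seed=40)
        draws = pop.effect_draw[pop.exposed]
        assert (draws >= 0.0105).all() and (draws <= 0.0131).all()


class TestPriceMechanics:
    def test_elasticity_identity(self, world):
        """Elasticity -0.5 and +10% price cut consumption by exactly 5%."""
        e = world.elasticities
        elas = e.elasticity.copy()
        e2 = type(e)(
            elasticity=np.full_like(elas, -0.5),
            beverage_shares=e.beverage_shares,
            price_bins=e.price_bins,
            price_shares=e.price_shares,
        )
        consumption = np.full((3, 3, 2), 20.0)
        adjusted = apply_price_intervention(consumption, e2, PriceShock(0.10))
        np.testing.assert_allclose(adjusted, 19.0)

    def test_zero_elasticity_leaves_consumption_unchanged(self, world):
        e = world.elasticities
        e0 = type(e)(
            elasticity=np.zeros_like(e.elasticity),
            beverage_shares=e.beverage_shares,
            price_bins=e.price_bins,
            price_shares=e.price_shares,
        )
        consumption = np.full((3, 3, 2), 20.0)
        np.testing.assert_array_equal(
            apply_price_intervention(consumption, e0, PriceShock(0.10)), consumption
        )

    def test_consumption_never_negative(self, world):
        adjusted = apply_price_intervention(
            np.full((3, 3, 2), 1.0), world.elasticities, PriceShock(5.0)
        )
        assert (adjusted >= 0).all()

    def test_default_tax_cut_inside_published_band(self, world):
        before = np.full((3, 3, 2), 10.0)
        after = apply_price_intervention(before, world.elasticities, PriceShock(0.10))
        cut = 1 - after / before
        assert (cut >= 0.04).all() and (cut <= 0.07).all()

    def test_mup_floor_below_market_changes_nothing(self, world):
        change = apply_mup(world.elasticities, floor=0.01)
        np.testing.assert_array_equal(change, 0.0)

    def test_mup_toy_distribution_hand_arithmetic(self):
        """Half the volume at 0.8x the floor: uplift 25% on a 50% share."""
        share, uplift = mup_price_uplift([0.8, 1.2], [0.5, 0.5], floor=1.0)
        assert share == pytest.approx(0.5)
        assert uplift == pytest.approx(0.25)
        # consumption change = share x uplift x elasticity
        assert share * uplift * -0.5 == pytest.approx(-0.0625)

    def test_default_mup_cut_inside_published_band(self, world):
        cut = -apply_mup(world.elasticities, floor=0.65)
        assert (cut >= 0.006).all() and (cut <= 0.033).all()

    def test_cell_changes_are_beverage_share_weighted(self, world):
        e = world.elasticities
        change = alcohol_cell_changes(e, PriceShock(0.10))
        expected = np.tensordot(e.beverage_shares, e.elasticity * 0.10, axes=(0, 0))
        np.testing.assert_allclose(change, expected)


class TestRiskFactorEffects:
    def test_food_labelling_shifts_bmi_30_to_29_88(self):
        spec = build_intervention("food_labelling")
        assert shifted_exposure(spec, np.array([30.0]), t=1.0)[0] == pytest.approx(29.88)

    def test_workday_to_week_conversion(self):
        """-72.78 min per workday averages to -72.78 x 5/7 per calendar day."""
        spec = build_intervention("workplace_sedentary")
        v = shifted_exposure(spec, np.array([480.0]), t=1.0)
        assert v[0] == pytest.approx(480.0 - 72.78 * 5.0 / 7.0)

    def test_abstainers_unaffected_by_pricing(self, world):
        spec = build_intervention("alcohol_tax")
        v = shifted_exposure(
            spec, np.array([0.0, 20.0]), t=1.0, cell_change=np.array([-0.05, -0.05])
        )
        assert v[0] == 0.0
        assert v[1] == pytest.approx(19.0)

    def test_zero_effect_leaves_risk_shifts_zero(self, world):
        pop = initialize_population(world.profile, world.distributions, seed=41)
        spec = with_magnitude(build_intervention("food_labelling"), 0.0)
        select_exposed(pop, spec, seed=41)
        pop.reset_effective()
        apply_risk_factor_effect(pop, spec, 1.0, world.distributions, world.rr)
        assert not pop.rr_shift.any()

    def test_bmi_drop_lowers_risk_only_for_exposed(self, world):
        pop = initialize_population(world.profile, world.distributions, seed=41)
        spec = build_intervention("food_labelling")
        select_exposed(pop, spec, seed=41)
        pop.reset_effective()
        apply_risk_factor_effect(pop, spec, 1.0, world.distributions, world.rr)
        assert (pop.rr_shift[~pop.exposed] == 0).all()
        assert (pop.rr_shift[pop.exposed] <= 0).all()
        assert (pop.rr_shift[pop.exposed] < 0).any()

    def test_stronger_effect_never_weakens_risk_reduction(self, world):
        """Dominance at the individual level for two effect sizes."""
        pop_a = initialize_population(world.profile, world.distributions, seed=42)
        pop_b = initialize_population(world.profile, world.distributions, seed=42)
        weak = with_magnitude(build_intervention("food_labelling"), 0.004)
        strong = with_magnitude(build_intervention("food_labelling"), 0.04)
        select_exposed(pop_a, weak, seed=42)
        select_exposed(pop_b, strong, seed=42)
        pop_a.reset_effective()
        pop_b.reset_effective()
        apply_risk_factor_effect(pop_a, weak, 1.0, world.distributions, world.rr)
        apply_risk_factor_effect(pop_b, strong, 1.0, world.distributions, world.rr)
        assert (pop_b.rr_shift <= pop_a.rr_shift + 1e-15).all()

    def test_media_raises_activity_and_lowers_risk(self, world):
        pop = initialize_population(world.profile, world.distributions, seed=43)
        spec = build_intervention("mass_media")
        select_exposed(pop, spec, seed=43)
        pop.reset_effective()
        apply_risk_factor_effect(pop, spec, 0.5, world.distributions, world.rr)
        assert (pop.rr_shift[pop.exposed] <= 0).all()
        # after the schedule has fully decayed the effect vanishes
        pop.reset_effective()
        apply_risk_factor_effect(pop, spec, 3.0, world.distributions, world.rr)
        assert not pop.rr_shift.any()
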