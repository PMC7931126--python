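"""Relative risks, calibrated hazards, fatality, and remission."""
import itertools

import numpy as np
import pytest

from oncosim import (
    apply_remission,
    assign_survival_outcome,
    calibrated_hazard,
    execute_cancer_deaths,
    individual_relative_risk,
    initialize_population,
    mean_relative_risk,
    sample_incident_cases,
)
from oncosim.constants import (
    C_COLORECTAL,
    F_ALCOHOL,
    F_BMI,
    MALE,
    N_BANDS,
    N_CANCERS,
    N_FACTORS,
    age_band,
)
from oncosim.disease import at_risk_mask
from oncosim.synthetic_country import RelativeRiskTable


def make_rr_table(n_quantiles=5, tops=None):
    """RR table with a chosen top-quantile RR per factor (flat over cancers)."""
    rr = np.ones((N_FACTORS, n_quantiles, N_CANCERS, N_BANDS, 2))
    if tops:
        grad = np.arange(n_quantiles) / (n_quantiles - 1)
        for f, top in tops.items():
            rr[f] = (top ** grad)[:, None, None, None]
    return RelativeRiskTable(rr=rr)


@pytest.fixture()
def pop(world):
    return initialize_population(world.profile, world.distributions, seed=21)


class TestIndividualRelativeRisk:
    def test_reference_quantiles_give_unity(self, pop):
        table = make_rr_table(tops={F_BMI: 2.0, F_ALCOHOL: 3.0})
        pop.quantile[:] = 0
        rr = individual_relative_risk(pop, C_COLORECTAL, table)
        assert np.all(rr == 1.0)

    def test_factors_combine_multiplicatively(self, pop):
        """Two factors at RRs 1.2 and 1.5 compound to 1.8."""
        n_q = 5
        rr = np.ones((N_FACTORS, n_q, N_CANCERS, N_BANDS, 2))
        rr[F_BMI, 4] = 1.2
        rr[F_ALCOHOL, 4] = 1.5
        table = RelativeRiskTable(rr=rr)
        pop.quantile[:] = 0
        pop.quantile[0, F_BMI] = 4
        pop.quantile[0, F_ALCOHOL] = 4
        out = individual_relative_risk(pop, C_COLORECTAL, table, rows=np.array([0]))
        assert np.isclose(out[0], 1.8)

    def test_population_mean_matches_exhaustive_enumeration(self, world, pop):
        """Oracle: average RR over the full joint quantile grid.

        Quantiles are uniform and independent across factors, so the
        population mean RR (one band, one sex, many individuals) must
        approach the exhaustive mean over all Q^4 combinations.
        """
        table = world.rr
        n_q = table.n_quantiles
        c = C_COLORECTAL
        band, sex = 3, MALE
        grid = 0.0
        for combo in itertools.product(range(n_q), repeat=N_FACTORS):
            v = 1.0
            for f, q in enumerate(combo):
                v *= table.rr[f, q, c, band, sex]
            grid += v
        grid /= n_q**N_FACTORS

        rows = np.flatnonzero((age_band(pop.ages()) == band) & (pop.sex == sex))
        rr = individual_relative_risk(pop, c, table, rows=rows)
        # Monte-Carlo error of the sample mean
        assert abs(rr.mean() - grid) <= 3 * rr.std() / np.sqrt(len(rows))

    def test_quantile_outside_table_rejected(self, pop):
        table = make_rr_table(n_quantiles=3)
        pop.quantile[:] = 4
        with pytest.raises(ValueError):
            individual_relative_risk(pop, C_COLORECTAL, table)


class TestCalibratedHazard:
    def test_two_quantile_toy(self):
        """RRs {1, 3} at equal shares, baseline 0.01 -> hazards {0.005, 0.015}."""
        mean_rr = 2.0
        h = calibrated_hazard(0.01, np.array([1.0, 3.0]), mean_rr)
        np.testing.assert_allclose(h, [0.005, 0.015])
        assert np.isclose(h.mean(), 0.01)

    def test_unit_rr_recovers_baseline(self):
        assert calibrated_hazard(0.0123, 1.0, 1.0) == 0.0123

    def test_zero_baseline_gives_zero(self):
        assert calibrated_hazard(0.0, 99.0, 1.0) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            calibrated_hazard(0.01, 1.0, 0.0)

    def test_clipped_to_unit_interval(self):
        assert calibrated_hazard(0.9, 10.0, 1.0) == 1.0


class TestIncidenceSampling:
    def test_case_count_within_three_se_of_hazard_sum(self, world, pop):
        """Poisson-binomial oracle on one year's draws."""
        epi = world.epidemiology[C_COLORECTAL]
        mask = at_risk_mask(pop, C_COLORECTAL)
        rows = np.flatnonzero(mask)
        ages = pop.ages()[rows]
        base = epi.baseline_incidence[ages, pop.sex[rows]]
        rr = individual_relative_risk(pop, C_COLORECTAL, world.rr, rows=rows)
        mrr = mean_relative_risk(pop, C_COLORECTAL, world.rr, mask)
        h = calibrated_hazard(base, rr, mrr[age_band(ages), pop.sex[rows]])
        new, _ = sample_incident_cases(pop, epi, world.rr, 2020, seed=21)
        se = np.sqrt((h * (1 - h)).sum())
        assert abs(len(new) - h.sum()) <= 3 * se

    def test_zero_hazard_produces_no_cases(self, world, pop):
        epi = world.epidemiology[C_COLORECTAL]
        silent = type(epi)(
            cancer=epi.cancer,
            baseline_incidence=np.zeros_like(epi.baseline_incidence),
            p_death_5y=epi.p_death_5y,
            mortality_year_weights=epi.mortality_year_weights,
        )
        new, _ = sample_incident_cases(pop, silent, world.rr, 2020, seed=21)
        assert len(new) == 0

    def test_fixed_seed_reproduces_case_set(self, world):
        a = initialize_population(world.profile, world.distributions, seed=22)
        b = initialize_population(world.profile, world.distributions, seed=22)
        epi = world.epidemiology[C_COLORECTAL]
        na, _ = sample_incident_cases(a, epi, world.rr, 2020, seed=22)
        nb, _ = sample_incident_cases(b, epi, world.rr, 2020, seed=22)
        assert np.array_equal(na, nb)

    def test_no_reincidence_of_same_cancer(self, world, pop):
        epi = world.epidemiology[C_COLORECTAL]
        new, _ = sample_incident_cases(pop, epi, world.rr, 2020, seed=21)
        again, _ = sample_incident_cases(pop, epi, world.rr, 2021, seed=21)
        assert not np.intersect1d(new, again).size

    def test_raising_harmful_rr_raises_expected_incidence(self, world, pop):
        """Monotonicity of the expected case load in the top-quantile group."""
        epi = world.epidemiology[C_COLORECTAL]
        mask = at_risk_mask(pop, C_COLORECTAL)
        top = mask & (pop.quantile[:, F_ALCOHOL] == world.n_quantiles - 1)
        rows = np.flatnonzero(top)
        ages = pop.ages()[rows]
        base = epi.baseline_incidence[ages, pop.sex[rows]]

        def expected_cases(table):
            rr = individual_relative_risk(pop, C_COLORECTAL, table, rows=rows)
            mrr = mean_relative_risk(pop, C_COLORECTAL, table, mask)
            return calibrated_hazard(base, rr, mrr[age_band(ages), pop.sex[rows]]).sum()

        lo = expected_cases(make_rr_table(tops={F_ALCOHOL: 1.4}))
        hi = expected_cases(make_rr_table(tops={F_ALCOHOL: 2.0}))
        assert hi > lo


class TestSurvivalOutcome:
    def test_zero_fatality_never_plans_a_death(self, world, pop):
        epi = world.epidemiology[C_COLORECTAL]
        safe = type(epi)(
            cancer=epi.cancer,
            baseline_incidence=epi.baseline_incidence,
            p_death_5y=np.zeros_like(epi.p_death_5y),
            mortality_year_weights=epi.mortality_year_weights,
        )
        rows = np.arange(200)
        pop.dx_year[rows, C_COLORECTAL] = pop.current_year
        assign_survival_outcome(pop, rows, safe, seed=21)
        assert not pop.will_die[rows, C_COLORECTAL].any()

    def test_certain_death_with_degenerate_weights(self, world, pop):
        epi = world.epidemiology[C_COLORECTAL]
        w = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        doomed = type(epi)(
            cancer=epi.cancer,
            baseline_incidence=epi.baseline_incidence,
            p_death_5y=np.ones_like(epi.p_death_5y),
            mortality_year_weights=w,
        )
        rows = np.arange(200)
        pop.dx_year[rows, C_COLORECTAL] = pop.current_year
        assign_survival_outcome(pop, rows, doomed, seed=21)
        assert pop.will_die[rows, C_COLORECTAL].all()
        assert (pop.cancer_death_year[rows, C_COLORECTAL] == pop.current_year).all()

    def test_death_timing_matches_weights(self, world):
        """Multinomial oracle on 10^4 simulated fatal cases."""
        big = initialize_population(world.profile, world.distributions, seed=30)
        epi = world.epidemiology[C_COLORECTAL]
        n = big.n
        certain = type(epi)(
            cancer=epi.cancer,
            baseline_incidence=epi.baseline_incidence,
            p_death_5y=np.ones_like(epi.p_death_5y),
            mortality_year_weights=epi.mortality_year_weights,
        )
        rows = np.arange(n)
        big.dx_year[rows, C_COLORECTAL] = big.current_year
        assign_survival_outcome(big, rows, certain, seed=30)
        k = big.cancer_death_year[rows, C_COLORECTAL] - big.current_year
        counts = np.bincount(k, minlength=5)
        for j, w in enumerate(epi.mortality_year_weights):
            se = np.sqrt(n * w * (1 - w))
            assert abs(counts[j] - n * w) <= 3 * se


class TestRemission:
    def test_five_full_years_trigger_remission(self, world, pop):
        pop.dx_year[0, C_COLORECTAL] = 2020
        apply_remission(pop, 2025)
        assert pop.remission[0, C_COLORECTAL]

    def test_four_years_do_not(self, world, pop):
        pop.dx_year[0, C_COLORECTAL] = 2020
        apply_remission(pop, 2024)
        assert not pop.remission[0, C_COLORECTAL]

    def test_fatal_cases_never_remit(self, world, pop):
        pop.dx_year[0, C_COLORECTAL] = 2020
        pop.will_die[0, C_COLORECTAL] = True
        pop.cancer_death_year[0, C_COLORECTAL] = 2023
        apply_remission(pop, 2025)
        assert not pop.remission[0, C_COLORECTAL]

    def test_planned_deaths_fire_on_schedule(self, world, pop):
        pop.dx_year[0, C_COLORECTAL] = 2020
        pop.will_die[0, C_COLORECTAL] = True
        pop.cancer_death_year[0, C_COLORECTAL] = 2022
        assert len(execute_cancer_deaths(pop, 2021)) == 0
        died = execute_cancer_deaths(pop, 2022)
        assert list(died) == [0]
        assert not pop.alive[0]
        assert pop.death_cause[0] == C_COLORECTAL
        # a dead case cannot die again
        assert len(execute_cancer_deaths(pop, 2022)) == 0
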