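"""Synthetic life histories on an annual cycle.

A :class:`Population` is a struct-of-arrays over individuals: fixed
attributes (birth year, sex, lifelong risk-factor quantiles), the evolving
demographic state (alive, migration status), and per-cancer disease state.
Each simulated year resolves events in a fixed order — ageing, births,
migration, background mortality — with disease events layered on top by the
scenario runner.  Rows are never deleted: the dead and the emigrated stay in
place so that positional random streams remain aligned across paired runs.
"""
from __future__ import annotations

import numpy as np

from .constants import FEMALE, MALE, N_CANCERS, N_FACTORS, age_band
from .rng import stream
from .synthetic_country import CountryProfile, RiskFactorDistribution

NATIVE, IMMIGRANT, EMIGRATED = 0, 1, 2
CAUSE_NONE, CAUSE_BACKGROUND = -1, 8
FERTILE_MIN, FERTILE_MAX = 15, 49


class Population:
    """Cross-sectional array representation of all simulated individuals."""

    def __init__(self, current_year: int, seed: int, n_quantiles: int):
        self.current_year = int(current_year)
        self.seed = int(seed)
        self.n_quantiles = int(n_quantiles)
        self.ids = np.empty(0, dtype=np.int64)
        self.birth_year = np.empty(0, dtype=np.int32)
        self.sex = np.empty(0, dtype=np.int8)
        self.alive = np.empty(0, dtype=bool)
        self.migration_status = np.empty(0, dtype=np.int8)
        self.quantile = np.empty((0, N_FACTORS), dtype=np.int16)
        self.ufrac = np.empty((0, N_FACTORS), dtype=np.float64)
        self.rr_shift = np.empty((0, N_CANCERS), dtype=np.float64)
        self.exposed = np.empty(0, dtype=bool)
        self.effect_draw = np.empty(0, dtype=np.float64)
        self.dx_year = np.empty((0, N_CANCERS), dtype=np.int32)
        self.will_die = np.empty((0, N_CANCERS), dtype=bool)
        self.cancer_death_year = np.empty((0, N_CANCERS), dtype=np.int32)
        self.remission = np.empty((0, N_CANCERS), dtype=bool)
        self.death_year = np.empty(0, dtype=np.int32)
        self.death_cause = np.empty(0, dtype=np.int8)

    # -- views ------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.ids.size

    def ages(self) -> np.ndarray:
        return self.current_year - self.birth_year

    def present(self) -> np.ndarray:
        """Alive and in the country."""
        return self.alive & (self.migration_status != EMIGRATED)

    def reset_effective(self) -> None:
        """Clear this year's intervention log-RR shifts."""
        self.rr_shift[...] = 0.0

    # -- growth -----------------------------------------------------------

    def append(self, sex, birth_year, migration_status, quantile, ufrac) -> np.ndarray:
        """Add individuals (newborns or immigrants); returns their ids."""
        m = len(sex)
        new_ids = np.arange(self.n, self.n + m, dtype=np.int64)
        self.ids = np.concatenate([self.ids, new_ids])
        self.birth_year = np.concatenate([self.birth_year, np.asarray(birth_year, np.int32)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.int8)])
        self.alive = np.concatenate([self.alive, np.ones(m, bool)])
        self.migration_status = np.concatenate(
            [self.migration_status, np.asarray(migration_status, np.int8)]
        )
        self.quantile = np.concatenate([self.quantile, np.asarray(quantile, np.int16)])
        self.ufrac = np.concatenate([self.ufrac, np.asarray(ufrac, np.float64)])
        self.rr_shift = np.concatenate([self.rr_shift, np.zeros((m, N_CANCERS))])
        self.exposed = np.concatenate([self.exposed, np.zeros(m, bool)])
        self.effect_draw = np.concatenate([self.effect_draw, np.zeros(m)])
        self.dx_year = np.concatenate(
            [self.dx_year, np.full((m, N_CANCERS), -1, np.int32)]
        )
        self.will_die = np.concatenate([self.will_die, np.zeros((m, N_CANCERS), bool)])
        self.cancer_death_year = np.concatenate(
            [self.cancer_death_year, np.full((m, N_CANCERS), -1, np.int32)]
        )
        self.remission = np.concatenate([self.remission, np.zeros((m, N_CANCERS), bool)])
        self.death_year = np.concatenate([self.death_year, np.full(m, -1, np.int32)])
        self.death_cause = np.concatenate(
            [self.death_cause, np.full(m, CAUSE_NONE, np.int8)]
        )
        return new_ids

    def copy(self) -> "Population":
        other = Population(self.current_year, self.seed, self.n_quantiles)
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                setattr(other, name, val.copy())
        return other

    # -- exposure values --------------------------------------------------

    def exposure_values(self, dist: RiskFactorDistribution, rows: np.ndarray) -> np.ndarray:
        """Continuous exposure of ``rows`` for one factor at current ages."""
        band = age_band(self.ages()[rows])
        return dist.values_for(
            band, self.sex[rows], self.quantile[rows, dist.factor], self.ufrac[rows, dist.factor]
        )


def _draw_attributes(rng: np.random.Generator, m: int, n_quantiles: int):
    sex = (rng.random(m) >= 0.512).astype(np.int8)  # 0=male with p=0.512
    quantile = rng.integers(0, n_quantiles, size=(m, N_FACTORS), dtype=np.int16)
    ufrac = rng.random((m, N_FACTORS))
    return sex, quantile, ufrac


def initialize_population(
    profile: CountryProfile, distributions, seed: int
) -> Population:
    """Materialize the starting population from the pyramid.

    The (age, sex) composition matches the pyramid exactly; everyone starts
    alive and disease-free, with risk quantiles drawn uniformly (quantiles
    are equal-probability bins by construction).
    """
    counts = profile.pyramid.astype(np.int64)
    total = int(counts.sum())
    if total <= 0:
        raise ValueError("profile pyramid is empty")
    n_quantiles = distributions[0].n_quantiles
    pop = Population(profile.start_year, seed, n_quantiles)
    ages = np.repeat(
        np.arange(counts.shape[0]), counts[:, MALE] + counts[:, FEMALE]
    )
    sex = np.concatenate(
        [
            np.repeat([MALE, FEMALE], counts[a])
            for a in range(counts.shape[0])
        ]
    ).astype(np.int8)
    rng = stream(seed, "init_population")
    quantile = rng.integers(0, n_quantiles, size=(total, N_FACTORS), dtype=np.int16)
    ufrac = rng.random((total, N_FACTORS))
    pop.append(sex, profile.start_year - ages, np.zeros(total, np.int8), quantile, ufrac)
    return pop


def step_demographics(pop: Population, profile: CountryProfile) -> dict:
    """Advance one calendar year: ageing, births, migration, background deaths.

    Returns an accounting dict whose identity
    ``end = start + births + immigrants - emigrants - background_deaths``
    holds exactly (cancer deaths are resolved separately by the disease
    layer and appended to the same accounting by the runner).
    """
    pop.current_year += 1
    year = pop.current_year
    seed = pop.seed
    start_n = int(pop.present().sum())

    # Births: per-woman Bernoulli at the fertility rate of her (new) age.
    ages = pop.ages()
    women = pop.present() & (pop.sex == FEMALE) & (ages >= FERTILE_MIN) & (ages <= FERTILE_MAX)
    u = stream(seed, "births", year).random(pop.n)
    mothers = women & (u < profile.fertility[np.clip(ages, 0, len(profile.fertility) - 1)])
    n_births = int(mothers.sum())
    if n_births:
        rng = stream(seed, "newborns", year)
        sex, quantile, ufrac = _draw_attributes(rng, n_births, pop.n_quantiles)
        pop.append(sex, np.full(n_births, year), np.zeros(n_births, np.int8), quantile, ufrac)

    # Immigration: Poisson arrivals per (age, sex) stratum at positive rates.
    n_immigrants = 0
    rate = profile.net_migration
    if (rate > 0).any():
        rngm = stream(seed, "immigration", year)
        present = pop.present()
        ages = pop.ages()
        counts = np.zeros(rate.shape, np.int64)
        for s in (MALE, FEMALE):
            sel = present & (pop.sex == s)
            np.add.at(counts[:, s], np.clip(ages[sel], 0, rate.shape[0] - 1), 1)
        lam = np.maximum(rate, 0.0) * counts
        arrivals = rngm.poisson(lam)
        n_immigrants = int(arrivals.sum())
        if n_immigrants:
            im_age = np.repeat(np.arange(rate.shape[0]), arrivals.sum(axis=1))
            im_sex = np.concatenate(
                [np.repeat([MALE, FEMALE], arrivals[a]) for a in range(rate.shape[0])]
            ).astype(np.int8)
            _, quantile, ufrac = _draw_attributes(rngm, n_immigrants, pop.n_quantiles)
            pop.append(
                im_sex,
                year - im_age,
                np.ones(n_immigrants, np.int8) * IMMIGRANT,
                quantile,
                ufrac,
            )

    # Emigration: Bernoulli departures at negative net rates.
    n_emigrants = 0
    if (rate < 0).any():
        er = np.maximum(-rate, 0.0)
        u2 = stream(seed, "emigration", year).random(pop.n)
        ages = pop.ages()
        leave = pop.present() & (
            u2 < er[np.clip(ages, 0, er.shape[0] - 1), pop.sex]
        )
        n_emigrants = int(leave.sum())
        pop.migration_status[leave] = EMIGRATED

    # Background mortality (excludes modelled cancer deaths).
    u3 = stream(seed, "background_mortality", year).random(pop.n)
    ages = pop.ages()
    q = profile.background_mortality[np.clip(ages, 0, profile.background_mortality.shape[0] - 1), pop.sex]
    die = pop.present() & (u3 < q)
    n_deaths = int(die.sum())
    pop.alive[die] = False
    pop.death_year[die] = year
    pop.death_cause[die] = CAUSE_BACKGROUND

    return {
        "year": year,
        "start": start_n,
        "births": n_births,
        "immigrants": n_immigrants,
        "emigrants": n_emigrants,
        "background_deaths": n_deaths,
        "end": int(pop.present().sum()),
    }
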