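"""The six primary-prevention policies and their effect mechanics.

Each policy is an :class:`InterventionSpec`: who is eligible (age filter),
what share of the eligible population is exposed, what the effect does to a
risk factor (in the effect's own units), and how the effect evolves over
time (a piecewise-linear schedule of fractions of the maximum effect).
Published input values:

======================  =========  ==========  ====================================
policy                  target age  exposure    effect on risk factor
======================  =========  ==========  ====================================
menu labelling          > 5 years   12%         1.05-1.31% lower BMI after 1 year
food labelling          > 5 years   15%         0.40% lower BMI
mass media campaigns    > 18 years  100%        +60% activity at 1 month, +30% at
                                                1 year, 0% after 2 years
workplace sedentary     18-65       2.31-6.95%  -72.78 min sitting per 8-h workday,
                                                50% of enterprises participating
alcohol tax             all ages    100%        +10% price via elasticities
                                                (consumption -4% to -7%)
minimum unit pricing    all ages    100%        floor price per unit
                                                (consumption -0.6% to -3.3%)
======================  =========  ==========  ====================================

Only the mass-media effect decays; the other policies hold their maximum
effect for the full horizon.  Percentage effects on BMI and alcohol are
relative changes to the individual's current exposure level.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import F_ACTIVITY, F_ALCOHOL, F_BMI, F_SEDENTARY, age_band
from .population import Population
from .rng import stream
from .synthetic_country import (
    ElasticityTable,
    HEAVY_DRINKING_G_PER_DAY,
    RiskFactorDistribution,
)

WORKDAYS_PER_WEEK = 5
SEDENTARY_DROP_MIN_PER_WORKDAY = 72.78
ENTERPRISE_PARTICIPATION = 0.5


@dataclass(frozen=True)
class PriceShock:
    """A uniform fractional price change and/or a floor price per unit."""

    price_change: float = 0.0
    mup_floor: float | None = None

    def __post_init__(self):
        if self.price_change <= -1:
            raise ValueError("price_change must exceed -1")
        if self.mup_floor is not None and self.mup_floor <= 0:
            raise ValueError("mup_floor must be positive")


@dataclass(frozen=True)
class InterventionSpec:
    """One policy: eligibility, exposure, effect kind/size, and time course.

    ``schedule`` is a piecewise-linear list of (years since implementation,
    fraction of maximum effect) knots; beyond the last knot the fraction
    holds at the last knot's value.  ``magnitude_range``, when present,
    is sampled per exposed individual (uniformly) in place of the scalar
    ``effect_magnitude``.
    """

    name: str
    target_age: tuple  # (min_age, max_age or None), inclusive
    exposure_fraction: float
    effect_kind: str
    effect_magnitude: float
    magnitude_range: tuple | None = None
    exposure_range: tuple | None = None
    participation: float = 1.0
    schedule: tuple = ((0.0, 1.0),)
    price_shock: PriceShock | None = None

    def __post_init__(self):
        if not 0.0 <= self.exposure_fraction <= 1.0:
            raise ValueError("exposure_fraction must lie in [0, 1]")
        if self.magnitude_range is not None and self.magnitude_range[0] > self.magnitude_range[1]:
            raise ValueError("magnitude_range must be ordered low <= high")
        if self.exposure_range is not None and self.exposure_range[0] > self.exposure_range[1]:
            raise ValueError("exposure_range must be ordered low <= high")


EFFECT_FACTOR = {
    "bmi_percent_drop": F_BMI,
    "activity_percent_increase": F_ACTIVITY,
    "sedentary_minutes_drop": F_SEDENTARY,
    "consumption_percent_change_via_elasticity": F_ALCOHOL,
    "consumption_percent_change_via_mup": F_ALCOHOL,
}

_ALIASES = {
    "workplace_sb": "workplace_sedentary",
    "mup": "minimum_unit_pricing",
    "mass_media_campaigns": "mass_media",
}

INTERVENTION_NAMES = (
    "menu_labelling",
    "food_labelling",
    "mass_media",
    "workplace_sedentary",
    "alcohol_tax",
    "minimum_unit_pricing",
)

DEFAULT_MUP_FLOOR = 0.65  # USD PPP per unit of alcohol


def build_intervention(name: str) -> InterventionSpec:
    """Construct one of the six policies with its published input values."""
    name = _ALIASES.get(name, name)
    if name == "menu_labelling":
        return InterventionSpec(
            name=name,
            target_age=(6, None),
            exposure_fraction=0.12,
            effect_kind="bmi_percent_drop",
            effect_magnitude=0.0118,
            magnitude_range=(0.0105, 0.0131),
            schedule=((0.0, 0.0), (1.0, 1.0)),
        )
    if name == "food_labelling":
        return InterventionSpec(
            name=name,
            target_age=(6, None),
            exposure_fraction=0.15,
            effect_kind="bmi_percent_drop",
            effect_magnitude=0.0040,
        )
    if name == "mass_media":
        return InterventionSpec(
            name=name,
            target_age=(19, None),
            exposure_fraction=1.0,
            effect_kind="activity_percent_increase",
            effect_magnitude=0.60,
            schedule=((0.0, 0.0), (1.0 / 12.0, 1.0), (1.0, 0.5), (2.0, 0.0)),
        )
    if name == "workplace_sedentary":
        return InterventionSpec(
            name=name,
            target_age=(18, 65),
            exposure_fraction=0.0463,
            exposure_range=(0.0231, 0.0695),
            participation=ENTERPRISE_PARTICIPATION,
            effect_kind="sedentary_minutes_drop",
            effect_magnitude=SEDENTARY_DROP_MIN_PER_WORKDAY,
        )
    if name == "alcohol_tax":
        return InterventionSpec(
            name=name,
            target_age=(0, None),
            exposure_fraction=1.0,
            effect_kind="consumption_percent_change_via_elasticity",
            effect_magnitude=0.10,
            price_shock=PriceShock(price_change=0.10),
        )
    if name == "minimum_unit_pricing":
        return InterventionSpec(
            name=name,
            target_age=(0, None),
            exposure_fraction=1.0,
            effect_kind="consumption_percent_change_via_mup",
            effect_magnitude=0.0,
            price_shock=PriceShock(price_change=0.0, mup_floor=DEFAULT_MUP_FLOOR),
        )
    raise ValueError(f"unknown intervention: {name!r}")


def with_magnitude(spec: InterventionSpec, magnitude: float) -> InterventionSpec:
    """A copy of ``spec`` with a fixed scalar effect magnitude (no range)."""
    return replace(spec, effect_magnitude=magnitude, magnitude_range=None)


# ---------------------------------------------------------------------------
# Effect schedule
# ---------------------------------------------------------------------------


def schedule_fraction(spec: InterventionSpec, t: float) -> float:
    """Fraction of maximum effect at ``t`` years since implementation."""
    if t < 0:
        raise ValueError("t must be non-negative")
    knots = spec.schedule
    times = [k[0] for k in knots]
    values = [k[1] for k in knots]
    if t >= times[-1]:
        return values[-1]
    return float(np.interp(t, times, values))


def effect_at_time(spec: InterventionSpec, t: float) -> float:
    """Effect magnitude (in the spec's units) at ``t`` years."""
    return schedule_fraction(spec, t) * spec.effect_magnitude


# ---------------------------------------------------------------------------
# Exposure sampling
# ---------------------------------------------------------------------------


def eligible_mask(pop: Population, spec: InterventionSpec) -> np.ndarray:
    ages = pop.ages()
    lo, hi = spec.target_age
    m = pop.present() & (ages >= lo)
    if hi is not None:
        m &= ages <= hi
    return m


def select_exposed(pop: Population, spec: InterventionSpec, seed: int) -> np.ndarray:
    """Flag exposed individuals among the age-eligible.

    Bernoulli at ``exposure_fraction x participation`` (the participation
    term thins workplace programmes by the enterprises that opt in).  Also
    draws each exposed individual's effect magnitude when the spec gives a
    range.  Returns the exposure mask.
    """
    elig = eligible_mask(pop, spec)
    p = spec.exposure_fraction * spec.participation
    u = stream(seed, f"exposure_{spec.name}").random(pop.n)
    pop.exposed = elig & (u < p)
    if spec.magnitude_range is not None:
        lo, hi = spec.magnitude_range
        um = stream(seed, f"effect_draw_{spec.name}").random(pop.n)
        pop.effect_draw = lo + um * (hi - lo)
    else:
        pop.effect_draw = np.full(pop.n, spec.effect_magnitude)
    return pop.exposed


# ---------------------------------------------------------------------------
# Alcohol price mechanics
# ---------------------------------------------------------------------------


def apply_price_intervention(
    consumption: np.ndarray, elasticities: ElasticityTable, shock: PriceShock
) -> np.ndarray:
    """Adjust per-cell consumption (g/day) for a uniform price change.

    Fractional change per (beverage, age band, category) cell is
    elasticity x price change; consumption never goes negative.
    """
    if shock.mup_floor is not None:
        raise ValueError("use apply_mup for floor-price shocks")
    change = elasticities.elasticity * shock.price_change
    return np.maximum(np.asarray(consumption) * (1.0 + change), 0.0)


def mup_price_uplift(price_bins, price_shares, floor: float):
    """Below-floor market share and its volume-weighted mean price uplift."""
    price_bins = np.asarray(price_bins, dtype=float)
    price_shares = np.asarray(price_shares, dtype=float)
    if floor <= 0:
        raise ValueError("floor must be positive")
    below = price_bins < floor
    share = price_shares[below].sum()
    if share == 0:
        return 0.0, 0.0
    uplift = (price_shares[below] * (floor / price_bins[below] - 1.0)).sum() / share
    return float(share), float(uplift)


def apply_mup(
    elasticities: ElasticityTable, floor: float
) -> np.ndarray:
    """Fractional consumption change per cell under a floor price.

    Only below-floor volume faces a price rise, so the elasticity response
    is weighted by the below-floor market share:
    change = share x uplift x elasticity.  A floor below the whole price
    distribution changes nothing.
    """
    share, uplift = mup_price_uplift(
        elasticities.price_bins, elasticities.price_shares, floor
    )
    return share * uplift * elasticities.elasticity


def alcohol_cell_changes(
    elasticities: ElasticityTable, shock: PriceShock
) -> np.ndarray:
    """Beverage-share-weighted fractional consumption change per
    (drinker age band, drinking category) cell."""
    if shock.mup_floor is not None:
        per_bev = apply_mup(elasticities, shock.mup_floor)
    else:
        per_bev = elasticities.elasticity * shock.price_change
    return np.tensordot(elasticities.beverage_shares, per_bev, axes=(0, 0))


def drinker_cells(ages: np.ndarray, alcohol_values: np.ndarray):
    """Map individuals to (drinker age band, drinking category) indices."""
    ab = np.where(ages < 30, 0, np.where(ages < 50, 1, 2))
    cat = (alcohol_values >= HEAVY_DRINKING_G_PER_DAY).astype(int)
    return ab, cat


# ---------------------------------------------------------------------------
# Applying effects to individuals
# ---------------------------------------------------------------------------


def shifted_exposure(
    spec: InterventionSpec,
    values: np.ndarray,
    t: float,
    draws: np.ndarray | None = None,
    cell_change: np.ndarray | None = None,
) -> np.ndarray:
    """Exposure values after the intervention's effect at time ``t``.

    ``draws`` holds per-individual effect magnitudes (defaults to the
    spec's scalar magnitude); ``cell_change`` holds per-individual
    fractional alcohol consumption changes for the pricing policies.
    """
    values = np.asarray(values, dtype=float)
    frac = schedule_fraction(spec, t)
    if draws is None:
        draws = np.full(values.shape, spec.effect_magnitude)
    kind = spec.effect_kind
    if kind == "bmi_percent_drop":
        return values * (1.0 - np.asarray(draws) * frac)
    if kind == "activity_percent_increase":
        return values * (1.0 + np.asarray(draws) * frac)
    if kind == "sedentary_minutes_drop":
        daily = np.asarray(draws) * WORKDAYS_PER_WEEK / 7.0
        return np.maximum(values - daily * frac, 0.0)
    if kind in (
        "consumption_percent_change_via_elasticity",
        "consumption_percent_change_via_mup",
    ):
        if cell_change is None:
            raise ValueError("pricing effects need per-individual cell changes")
        return np.maximum(values * (1.0 + np.asarray(cell_change) * frac), 0.0)
    raise ValueError(f"unknown effect kind {kind!r}")


def log_rr_delta(
    rr_table,
    dist: RiskFactorDistribution,
    cancer: int,
    band: np.ndarray,
    sex: np.ndarray,
    v_from: np.ndarray,
    v_to: np.ndarray,
) -> np.ndarray:
    """Log-RR change along the continuous risk gradient of one factor.

    The gradient is the piecewise-linear curve through the cell's
    (quantile mean, log RR) anchor points, held flat beyond the end means.
    An unchanged value gives exactly zero.
    """
    from .constants import MALE, FEMALE, N_BANDS  # local to avoid cycle noise

    out = np.zeros(len(v_from))
    logrr = np.log(np.maximum(rr_table.rr[dist.factor, :, cancer], 1e-300))
    for b in range(N_BANDS):
        for s in (MALE, FEMALE):
            m = (band == b) & (sex == s)
            if not m.any():
                continue
            x = dist.means[b, s]
            y = logrr[:, b, s]
            out[m] = np.interp(v_to[m], x, y) - np.interp(v_from[m], x, y)
    return out


def apply_risk_factor_effect(
    pop: Population,
    spec: InterventionSpec,
    t: float,
    distributions: list[RiskFactorDistribution],
    rr_table,
    elasticities: ElasticityTable | None = None,
) -> None:
    """Shift exposed individuals' effective risk for the current year.

    The intervention moves each exposed individual's continuous exposure,
    and the resulting per-cancer log-RR change along the factor's RR
    gradient is stored as this year's risk shift.  An exactly unchanged
    exposure yields an exactly zero shift, so a zero-effect policy is
    bit-identical to no policy under common random numbers.  Unexposed
    individuals are untouched, and alcohol effects act multiplicatively,
    so abstainers (zero consumption) are unaffected by construction.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    factor = EFFECT_FACTOR[spec.effect_kind]
    dist = distributions[factor]
    rows = np.flatnonzero(pop.exposed & pop.present())
    if len(rows) == 0 or schedule_fraction(spec, t) == 0.0:
        return
    v = pop.exposure_values(dist, rows)
    cell_change = None
    if spec.price_shock is not None:
        if elasticities is None:
            raise ValueError("pricing interventions need an elasticity table")
        table = alcohol_cell_changes(elasticities, spec.price_shock)
        ab, cat = drinker_cells(pop.ages()[rows], v)
        cell_change = table[ab, cat]
    v2 = shifted_exposure(spec, v, t, draws=pop.effect_draw[rows], cell_change=cell_change)
    changed = v2 != v
    if not changed.any():
        return
    ch = rows[changed]
    band = age_band(pop.ages()[ch])
    sex = pop.sex[ch]
    from .constants import N_CANCERS

    for c in range(N_CANCERS):
        if (rr_table.rr[factor, :, c] == 1.0).all():
            continue  # factor not linked to this cancer
        pop.rr_shift[ch, c] += log_rr_delta(
            rr_table, dist, c, band, sex, v[changed], v2[changed]
        )
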