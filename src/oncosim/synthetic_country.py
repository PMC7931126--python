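"""Synthetic model inputs: a stylized country for the microsimulation.

Real analyses of this kind run on restricted national data (population
registers, burden-of-disease incidence and fatality tables, household
expenditure surveys).  This module generates inputs with the same
*statistical structure* — a population pyramid with vital rates, age-sex
risk-factor distributions cut into fixed quantiles, baseline cancer
incidence and 5-year case fatality, per-quantile relative risks, per-case
treatment costs, and alcohol price elasticities — so every downstream stage
of the model is fully exercisable and testable without any download.  No
fidelity to a specific real country is claimed.

All generators are deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AGE_BAND_EDGES,
    C_BREAST,
    C_COLORECTAL,
    C_LIVER,
    C_OESOPHAGEAL,
    CANCERS,
    F_ACTIVITY,
    F_ALCOHOL,
    F_BMI,
    F_SEDENTARY,
    FACTORS,
    FEMALE,
    MALE,
    N_AGES,
    N_BANDS,
    N_CANCERS,
    N_FACTORS,
)
from .rng import stream

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountryProfile:
    """Demography and macro parameters of the simulated country.

    Attributes
    ----------
    pyramid : (101, 2) array
        Head counts per (age, sex) at ``start_year``.
    fertility : (101,) array
        Births per woman-year by maternal age (zero outside 15-49).
    background_mortality : (101, 2) array
        Annual probability of death from causes *other than the modelled
        cancers*, by (age, sex).  Kept separate from cancer fatality to
        avoid double counting.
    net_migration : (101, 2) array
        Net annual migration as a fraction of the (age, sex) stratum;
        positive values add immigrants, negative values remove emigrants.
    ppp_factor : float
        Local currency per USD at purchasing power parity (metadata; all
        generated costs are already expressed in USD PPP).
    """

    name: str
    start_year: int
    pyramid: np.ndarray
    fertility: np.ndarray
    background_mortality: np.ndarray
    net_migration: np.ndarray
    ppp_factor: float

    def validate(self) -> None:
        if self.pyramid.shape != (N_AGES, 2):
            raise ValueError("pyramid must cover ages 0-100 for both sexes")
        if (self.pyramid < 0).any():
            raise ValueError("pyramid counts must be non-negative")
        q = self.background_mortality
        if q.shape != (N_AGES, 2) or (q < 0).any() or (q > 1).any():
            raise ValueError("background mortality must be probabilities on (age, sex)")
        if (self.fertility < 0).any():
            raise ValueError("fertility rates must be non-negative")
        if self.ppp_factor <= 0:
            raise ValueError("ppp_factor must be positive")

    @property
    def total_population(self) -> int:
        return int(self.pyramid.sum())


@dataclass
class RiskFactorDistribution:
    """Fixed-quantile representation of one continuous exposure.

    ``edges[band, sex]`` holds the ``n_quantiles + 1`` bin boundaries of the
    exposure distribution in that age-sex cell, and ``means[band, sex]`` the
    within-quantile means of the generating sample.  Individuals carry a
    lifelong quantile index plus a within-quantile rank fraction; their
    continuous exposure at any age is interpolated from the edges of their
    *current* age band, so exposure levels age realistically while the
    quantile allocation itself never changes.
    """

    factor: int
    n_quantiles: int
    edges: np.ndarray  # (N_BANDS, 2, Q+1)
    means: np.ndarray  # (N_BANDS, 2, Q)

    def validate(self) -> None:
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")
        if self.means.shape != (N_BANDS, 2, self.n_quantiles):
            raise ValueError("means shape mismatch")
        if not (np.diff(self.means, axis=-1) > 0).all():
            raise ValueError("quantile means must be strictly increasing")
        if (np.diff(self.edges, axis=-1) < 0).any():
            raise ValueError("quantile edges must be non-decreasing")

    def values_for(self, band, sex, quantile, frac) -> np.ndarray:
        """Continuous exposure for (band, sex, quantile) at rank fraction frac."""
        lo = self.edges[band, sex, quantile]
        hi = self.edges[band, sex, quantile + 1]
        return lo + np.asarray(frac) * (hi - lo)

    def bin_values(self, band, sex, values) -> np.ndarray:
        """Quantile index of arbitrary exposure values, by the cell's edges.

        Values below the lowest (above the highest) edge clamp into the
        bottom (top) quantile.  Consistent with :meth:`values_for`: a value
        generated from quantile q bins back to q.
        """
        band = np.asarray(band)
        sex = np.asarray(sex)
        values = np.asarray(values, dtype=float)
        out = np.zeros(values.shape, dtype=np.int16)
        for b in range(N_BANDS):
            for s in (MALE, FEMALE):
                m = (band == b) & (sex == s)
                if not m.any():
                    continue
                interior = self.edges[b, s, 1:-1]
                out[m] = np.searchsorted(interior, values[m], side="right")
        return np.clip(out, 0, self.n_quantiles - 1)


@dataclass
class DiseaseEpidemiology:
    """Baseline incidence and 5-year fatality of one cancer site.

    ``mortality_year_weights`` allocates predicted cancer deaths over the
    five years following diagnosis; the default is front-loaded (deaths are
    most likely in the first year after diagnosis and decline thereafter).
    """

    cancer: int
    baseline_incidence: np.ndarray  # (101, 2) cases per person-year
    p_death_5y: np.ndarray  # (N_BANDS, 2)
    mortality_year_weights: np.ndarray  # (5,)

    def validate(self) -> None:
        if (self.baseline_incidence < 0).any():
            raise ValueError("incidence rates must be non-negative")
        if ((self.p_death_5y < 0) | (self.p_death_5y > 1)).any():
            raise ValueError("p_death_5y must lie in [0, 1]")
        w = self.mortality_year_weights
        if w.shape != (5,) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mortality year weights must be a 5-vector summing to 1")
        if not (np.diff(w) < 0).all():
            raise ValueError("mortality year weights must be strictly decreasing")
        if self.cancer == C_BREAST and self.baseline_incidence[:, MALE].any():
            raise ValueError("male breast cancer incidence must be zero")


@dataclass
class RelativeRiskTable:
    """Relative risk per (factor, quantile, cancer, age band, sex).

    The bottom quantile is the reference (RR exactly 1).  Harmful exposures
    (BMI, sedentary time, alcohol) have RR non-decreasing in quantile;
    physical activity is protective, so RR is non-increasing.
    """

    rr: np.ndarray  # (N_FACTORS, Q, N_CANCERS, N_BANDS, 2)

    @property
    def n_quantiles(self) -> int:
        return self.rr.shape[1]

    def validate(self) -> None:
        if (self.rr < 0).any():
            raise ValueError("relative risks must be non-negative")
        if not np.allclose(self.rr[:, 0], 1.0):
            raise ValueError("reference quantile must have RR = 1")
        d = np.diff(self.rr, axis=1)
        for f in range(N_FACTORS):
            if f == F_ACTIVITY:
                if (d[f] > 1e-12).any():
                    raise ValueError("activity RR must be non-increasing in quantile")
            elif (d[f] < -1e-12).any():
                raise ValueError("harmful-exposure RR must be non-decreasing")


@dataclass
class CostProfile:
    """Per-case annual treatment costs and DALY disability weights.

    ``last_year_multiplier`` scales costs in the year of cancer death (care
    intensifies near death); ``multimorbidity_increment`` adds a fraction of
    total cost per additional concurrent cancer.
    """

    annual_cost: np.ndarray  # (N_CANCERS,) USD PPP per prevalent case-year
    last_year_multiplier: float
    multimorbidity_increment: float
    disability_weight: np.ndarray  # (N_CANCERS,) in [0, 1]

    def validate(self) -> None:
        if (self.annual_cost < 0).any():
            raise ValueError("costs must be non-negative")
        if self.last_year_multiplier < 1:
            raise ValueError("last_year_multiplier must be >= 1")
        if self.multimorbidity_increment < 0:
            raise ValueError("multimorbidity_increment must be non-negative")
        w = self.disability_weight
        if ((w < 0) | (w > 1)).any():
            raise ValueError("disability weights must lie in [0, 1]")


BEVERAGES = ("beer", "wine", "spirits")
DRINKER_AGE_BANDS = ("18-29", "30-49", "50+")
DRINKING_CATEGORIES = ("moderate", "heavy")
HEAVY_DRINKING_G_PER_DAY = 25.0  # category threshold on baseline intake


@dataclass
class ElasticityTable:
    """Own-price elasticities of alcohol demand plus the unit-price mix.

    Elasticities vary over beverage type, drinker age band, and drinking
    category (heavier drinkers respond less to price).  ``price_bins`` /
    ``price_shares`` describe the market-volume distribution over price per
    unit of alcohol, used by minimum-unit-pricing mechanics.
    """

    elasticity: np.ndarray  # (3 beverages, 3 age bands, 2 categories), <= 0
    beverage_shares: np.ndarray  # (3,) market volume shares, sum to 1
    price_bins: np.ndarray  # (B,) price per unit, ascending
    price_shares: np.ndarray  # (B,) volume share per bin, sum to 1

    def validate(self) -> None:
        if (self.elasticity > 0).any():
            raise ValueError("elasticities must be <= 0")
        if not np.isclose(self.price_shares.sum(), 1.0):
            raise ValueError("price-distribution shares must sum to 1")
        if not np.isclose(self.beverage_shares.sum(), 1.0):
            raise ValueError("beverage shares must sum to 1")
        if (np.diff(self.price_bins) <= 0).any():
            raise ValueError("price bins must be strictly increasing")


@dataclass
class World:
    """Bundle of all generated model inputs."""

    profile: CountryProfile
    distributions: list  # [RiskFactorDistribution] indexed by factor
    epidemiology: dict  # cancer index -> DiseaseEpidemiology
    rr: RelativeRiskTable
    costs: CostProfile
    elasticities: ElasticityTable
    n_quantiles: int = 5
    seed: int = 0

    def validate(self) -> None:
        self.profile.validate()
        for d in self.distributions:
            d.validate()
        for epi in self.epidemiology.values():
            epi.validate()
        self.rr.validate()
        self.costs.validate()
        self.elasticities.validate()


# ---------------------------------------------------------------------------
# Country profile
# ---------------------------------------------------------------------------

_GOMPERTZ_B = {MALE: 3.2e-5, FEMALE: 2.0e-5}
_GOMPERTZ_C = 0.088
_MAKEHAM_A = 4.0e-4
_TFR = 1.7
_MALE_BIRTH_SHARE = 0.512


def generate_country_profile(
    seed: int, scale: int, name: str = "Synthetica", start_year: int = 2019
) -> CountryProfile:
    """Generate a stylized stable-population country of ~``scale`` people.

    Mortality follows a Gompertz-Makeham schedule, fertility a bell over
    maternal ages 15-49 scaled to a total fertility rate near 1.7, and the
    pyramid is the stable-population shape implied by survivorship and a
    mild growth tilt, sampled multinomially so it sums to ``scale`` exactly.
    """
    if scale < 1000:
        raise ValueError("scale must be at least 1000")
    rng = stream(seed, "country_profile")
    ages = np.arange(N_AGES)

    q = np.empty((N_AGES, 2))
    for s in (MALE, FEMALE):
        jit = rng.uniform(0.92, 1.08)
        q[:, s] = np.minimum(
            0.95, _MAKEHAM_A + jit * _GOMPERTZ_B[s] * np.exp(_GOMPERTZ_C * ages)
        )

    tfr = _TFR * rng.uniform(0.92, 1.08)
    shape = np.exp(-0.5 * ((ages - 29.0) / 5.5) ** 2)
    shape[(ages < 15) | (ages > 49)] = 0.0
    fertility = tfr * shape / shape.sum()

    migration = np.zeros((N_AGES, 2))
    migration[(ages >= 20) & (ages < 40), :] = 0.002 * rng.uniform(0.5, 1.5)

    # Stable-population weights: survivorship x growth tilt, jittered.
    growth = 0.005
    weights = np.empty((N_AGES, 2))
    for s in (MALE, FEMALE):
        surv = np.concatenate([[1.0], np.cumprod(1.0 - q[:-1, s])])
        birth_share = _MALE_BIRTH_SHARE if s == MALE else 1 - _MALE_BIRTH_SHARE
        weights[:, s] = birth_share * surv * np.exp(-growth * ages)
    weights *= rng.uniform(0.97, 1.03, size=weights.shape)
    p = weights / weights.sum()
    pyramid = rng.multinomial(scale, p.ravel()).reshape(N_AGES, 2).astype(float)

    profile = CountryProfile(
        name=name,
        start_year=start_year,
        pyramid=pyramid,
        fertility=fertility,
        background_mortality=q,
        net_migration=migration,
        ppp_factor=float(rng.uniform(0.85, 1.25)),
    )
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# Risk-factor distributions
# ---------------------------------------------------------------------------

CELL_SAMPLE_SIZE = 4000
ALCOHOL_ABSTAINER_SHARE = 0.25

# Per-band parameters (band order: 0-19, 20-34, 35-49, 50-64, 65-79, 80+)
_BMI_MEAN = np.array([19.5, 25.0, 26.5, 27.5, 27.8, 26.8])
_BMI_SD = np.array([3.0, 4.0, 4.2, 4.4, 4.4, 4.2])
_ACTIVITY_MEAN = np.array([2800.0, 2600.0, 2300.0, 2000.0, 1500.0, 900.0])
_SEDENTARY_MEAN = np.array([420.0, 450.0, 470.0, 490.0, 540.0, 600.0])
_ALCOHOL_DRINKER_MEAN = np.array([1.0, 16.0, 18.0, 16.0, 12.0, 8.0])


def cell_sample(factor: int, band: int, sex: int, seed: int, n: int = CELL_SAMPLE_SIZE):
    """The generating sample of one (factor, age band, sex) cell.

    Exposed so tests can re-derive quantile cuts by brute-force re-binning.
    """
    rng = stream(seed, f"riskdist_{factor}_{band}_{sex}")
    if factor == F_BMI:
        mu = _BMI_MEAN[band] + (0.3 if sex == MALE else 0.0)
        x = rng.normal(mu, _BMI_SD[band], size=n)
        return np.maximum(x, 13.0)
    if factor == F_ACTIVITY:
        mean = _ACTIVITY_MEAN[band] * (1.1 if sex == MALE else 0.95)
        k = 1.6
        return rng.gamma(k, mean / k, size=n)
    if factor == F_SEDENTARY:
        x = rng.normal(_SEDENTARY_MEAN[band], 110.0, size=n)
        return np.maximum(x, 30.0)
    if factor == F_ALCOHOL:
        n_zero = int(round(ALCOHOL_ABSTAINER_SHARE * n))
        mean = _ALCOHOL_DRINKER_MEAN[band] * (1.3 if sex == MALE else 0.65)
        drinkers = rng.gamma(1.1, mean / 1.1, size=n - n_zero)
        return np.concatenate([np.zeros(n_zero), drinkers])
    raise ValueError(f"unknown factor {factor}")


def generate_risk_distributions(
    profile: CountryProfile, n_quantiles: int, seed: int
) -> list[RiskFactorDistribution]:
    """Cut each factor's per-cell generating sample into fixed quantiles.

    Quantile means are the empirical means of the generating draws within
    each equal-probability rank bin; edges are midpoints between adjacent
    order statistics (sample min/max at the extremes).  With the abstainer
    convention the bottom alcohol quantile is exactly zero at the default
    five quantiles.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    out = []
    for f in range(N_FACTORS):
        edges = np.empty((N_BANDS, 2, n_quantiles + 1))
        means = np.empty((N_BANDS, 2, n_quantiles))
        for b in range(N_BANDS):
            for s in (MALE, FEMALE):
                x = np.sort(cell_sample(f, b, s, seed))
                bins = np.array_split(x, n_quantiles)
                means[b, s] = [bin_.mean() for bin_ in bins]
                inner = [
                    0.5 * (bins[i][-1] + bins[i + 1][0]) for i in range(n_quantiles - 1)
                ]
                edges[b, s] = np.concatenate([[x[0]], inner, [x[-1]]])
        dist = RiskFactorDistribution(factor=f, n_quantiles=n_quantiles, edges=edges, means=means)
        dist.validate()
        out.append(dist)
    return out


# ---------------------------------------------------------------------------
# Disease epidemiology
# ---------------------------------------------------------------------------

DEFAULT_MORTALITY_YEAR_WEIGHTS = np.array([0.40, 0.25, 0.15, 0.12, 0.08])

# Logistic incidence-by-age parameters: (max male rate, max female rate,
# midpoint age, slope) per cancer.  Rates are cases per person-year.
_INCIDENCE_PARAMS = {
    C_BREAST: (0.0, 0.0028, 52.0, 8.0),
    C_COLORECTAL: (0.0030, 0.0022, 72.0, 9.0),
    C_OESOPHAGEAL: (0.0006, 0.00025, 70.0, 8.0),
    C_LIVER: (0.0005, 0.0002, 68.0, 8.0),
}
_FATALITY_BASE = {C_BREAST: 0.15, C_COLORECTAL: 0.35, C_OESOPHAGEAL: 0.70, C_LIVER: 0.75}
_FATALITY_AGE_GRADIENT = np.array([1.0, 0.85, 0.90, 1.00, 1.10, 1.25])


def generate_disease_epidemiology(
    profile: CountryProfile, seed: int
) -> dict[int, DiseaseEpidemiology]:
    """Baseline incidence and 5-year fatality per cancer, by age and sex."""
    rng = stream(seed, "epidemiology")
    ages = np.arange(N_AGES)
    out = {}
    for c in range(N_CANCERS):
        rmax_m, rmax_f, a0, slope = _INCIDENCE_PARAMS[c]
        curve = 1.0 / (1.0 + np.exp(-(ages - a0) / slope))
        curve[ages < 20] = 0.0
        inc = np.empty((N_AGES, 2))
        inc[:, MALE] = rmax_m * curve * rng.uniform(0.95, 1.05)
        inc[:, FEMALE] = rmax_f * curve * rng.uniform(0.95, 1.05)
        p5 = np.clip(
            _FATALITY_BASE[c]
            * _FATALITY_AGE_GRADIENT[:, None]
            * rng.uniform(0.95, 1.05, size=(N_BANDS, 2)),
            0.0,
            0.95,
        )
        epi = DiseaseEpidemiology(
            cancer=c,
            baseline_incidence=inc,
            p_death_5y=p5,
            mortality_year_weights=DEFAULT_MORTALITY_YEAR_WEIGHTS.copy(),
        )
        epi.validate()
        out[c] = epi
    return out


# ---------------------------------------------------------------------------
# Relative risks
# ---------------------------------------------------------------------------

# Top-quantile RR per (factor, cancer); 1.0 means no modelled link.
_RR_TOP = np.ones((N_FACTORS, N_CANCERS))
_RR_TOP[F_BMI] = [1.40, 1.50, 1.60, 1.50]
_RR_TOP[F_ACTIVITY] = [0.85, 0.75, 1.00, 1.00]
_RR_TOP[F_SEDENTARY] = [1.00, 1.25, 1.00, 1.00]
_RR_TOP[F_ALCOHOL] = [1.50, 1.40, 2.20, 1.80]


def generate_relative_risks(n_quantiles: int, seed: int) -> RelativeRiskTable:
    """Log-linear RR gradients across quantiles, reference = bottom quantile."""
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    rng = stream(seed, "relative_risks")
    grad = np.arange(n_quantiles) / (n_quantiles - 1)  # 0 .. 1
    rr = np.ones((N_FACTORS, n_quantiles, N_CANCERS, N_BANDS, 2))
    for f in range(N_FACTORS):
        for c in range(N_CANCERS):
            top = _RR_TOP[f, c]
            if top != 1.0:
                top = top ** rng.uniform(0.9, 1.1)
            rr[f, :, c, :, :] = (top ** grad)[:, None, None]
    table = RelativeRiskTable(rr=rr)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Costs and elasticities
# ---------------------------------------------------------------------------

_COST_BASE = np.array([32000.0, 38000.0, 45000.0, 50000.0])  # USD PPP, per cancer
_DISABILITY_BASE = np.array([0.11, 0.12, 0.25, 0.28])


def generate_cost_profile(seed: int) -> CostProfile:
    rng = stream(seed, "costs")
    costs = CostProfile(
        annual_cost=_COST_BASE * rng.uniform(0.9, 1.1, size=N_CANCERS),
        last_year_multiplier=float(rng.uniform(2.2, 2.8)),
        multimorbidity_increment=float(rng.uniform(0.2, 0.3)),
        disability_weight=np.clip(
            _DISABILITY_BASE * rng.uniform(0.9, 1.1, size=N_CANCERS), 0.0, 1.0
        ),
    )
    costs.validate()
    return costs


def generate_elasticities(seed: int) -> ElasticityTable:
    """Price elasticities calibrated to published intervention effect ranges.

    Cells are drawn so that a 10% across-the-board price rise cuts every
    (beverage, age, category) cell's consumption by 4-7%, with heavy
    drinkers systematically less price-responsive than moderate drinkers.
    The unit-price mix is chosen so a 0.65 USD/unit floor price binds on
    20% of market volume.
    """
    rng = stream(seed, "elasticities")
    elas = np.empty((len(BEVERAGES), len(DRINKER_AGE_BANDS), len(DRINKING_CATEGORIES)))
    elas[:, :, 0] = rng.uniform(-0.68, -0.52, size=(3, 3))  # moderate
    elas[:, :, 1] = rng.uniform(-0.55, -0.42, size=(3, 3))  # heavy
    table = ElasticityTable(
        elasticity=elas,
        beverage_shares=np.array([0.45, 0.30, 0.25]),
        price_bins=np.array([0.50, 0.60, 0.80, 1.00, 1.40]),
        price_shares=np.array([0.10, 0.10, 0.25, 0.30, 0.25]),
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# World
# ---------------------------------------------------------------------------


def generate_world(seed: int, scale: int = 20000, n_quantiles: int = 5) -> World:
    """Generate the complete, internally consistent set of model inputs."""
    profile = generate_country_profile(seed, scale)
    world = World(
        profile=profile,
        distributions=generate_risk_distributions(profile, n_quantiles, seed),
        epidemiology=generate_disease_epidemiology(profile, seed),
        rr=generate_relative_risks(n_quantiles, seed),
        costs=generate_cost_profile(seed),
        elasticities=generate_elasticities(seed),
        n_quantiles=n_quantiles,
        seed=seed,
    )
    world.validate()
    return world
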