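"""Risk-factor-driven cancer incidence, fatality, and remission.

Individual annual incidence is the age-sex baseline rate scaled by the
individual's relative risk and renormalized by the population-mean relative
risk, so that a no-intervention run reproduces the baseline rates in
expectation — the model's central calibration property.  Each new case is
assigned a 5-year fatality outcome up front; predicted deaths are spread
over years 0..4 after diagnosis by a front-loaded weight vector, and cases
alive five full years after diagnosis without a cancer death are considered
recovered (remission).
"""
from __future__ import annotations

import numpy as np

from .constants import MALE, FEMALE, N_BANDS, N_CANCERS, N_FACTORS, age_band
from .population import Population
from .rng import stream
from .synthetic_country import DiseaseEpidemiology, RelativeRiskTable


def individual_relative_risk(
    pop: Population,
    cancer: int,
    rr_table: RelativeRiskTable,
    rows: np.ndarray | None = None,
    effective: bool = True,
) -> np.ndarray:
    """Multiplicative RR across all four risk factors for one cancer.

    The base RR is the product of the table entries at the individual's
    lifelong quantiles.  ``effective=True`` additionally applies the
    current year's intervention shift — the exponentiated log-RR delta
    along the continuous RR gradient — while ``effective=False`` is the
    intervention-free calibration reference.
    """
    if rows is None:
        rows = np.arange(pop.n)
    rows = np.asarray(rows)
    q = pop.quantile[rows]
    if q.size and q.max() >= rr_table.n_quantiles:
        raise ValueError("quantile index outside relative-risk table")
    band = age_band(pop.ages()[rows])
    sex = pop.sex[rows]
    rr = np.ones(q.shape[0])
    for f in range(N_FACTORS):
        rr *= rr_table.rr[f, q[:, f], cancer, band, sex]
    if effective:
        shift = pop.rr_shift[rows, cancer]
        if np.any(shift):
            rr = rr * np.exp(shift)
    return rr


def mean_relative_risk(
    pop: Population, cancer: int, rr_table: RelativeRiskTable, mask: np.ndarray
) -> np.ndarray:
    """Mean baseline RR per (age band, sex) over the masked individuals.

    Always computed from *baseline* quantiles: the calibration denominator
    is the intervention-free exposure mix, so that interventions shift
    incidence rather than being normalized away.  Cells with no one at risk
    default to 1.
    """
    rows = np.flatnonzero(mask)
    rr = individual_relative_risk(pop, cancer, rr_table, rows, effective=False)
    band = age_band(pop.ages()[rows])
    sex = pop.sex[rows]
    total = np.zeros((N_BANDS, 2))
    count = np.zeros((N_BANDS, 2))
    np.add.at(total, (band, sex), rr)
    np.add.at(count, (band, sex), 1.0)
    out = np.ones((N_BANDS, 2))
    nz = count > 0
    out[nz] = total[nz] / count[nz]
    return out


def calibrated_hazard(baseline, rr, mean_rr):
    """Annual incidence probability: baseline x RR / mean RR, clipped to [0, 1]."""
    baseline = np.asarray(baseline, dtype=float)
    rr = np.asarray(rr, dtype=float)
    mean_rr = np.asarray(mean_rr, dtype=float)
    if (mean_rr <= 0).any():
        raise ValueError("mean relative risk must be positive")
    return np.clip(baseline * rr / mean_rr, 0.0, 1.0)


def at_risk_mask(pop: Population, cancer: int) -> np.ndarray:
    """Alive, in-country, and never diagnosed with this cancer.

    A remitted case keeps its diagnosis year, so remission excludes
    re-diagnosis of the same site (no second primaries); other cancers
    remain possible (multimorbidity).
    """
    return pop.present() & (pop.dx_year[:, cancer] < 0)


def sample_incident_cases(
    pop: Population,
    epi: DiseaseEpidemiology,
    rr_table: RelativeRiskTable,
    year: int,
    seed: int,
):
    """Bernoulli incidence draws at the calibrated hazard; attach diagnoses.

    Returns ``(new_case_rows, diagnostics)`` where diagnostics carries the
    expected case count (sum of baseline rates over the at-risk set, the
    calibration anchor) and the Poisson-binomial variance of the realized
    count, accumulated by the runner for model-consistency checks.
    """
    c = epi.cancer
    mask = at_risk_mask(pop, c)
    rows = np.flatnonzero(mask)
    ages = pop.ages()[rows]
    sex = pop.sex[rows]
    baseline = epi.baseline_incidence[np.clip(ages, 0, epi.baseline_incidence.shape[0] - 1), sex]
    rr = individual_relative_risk(pop, c, rr_table, rows, effective=True)
    mrr = mean_relative_risk(pop, c, rr_table, mask)
    h = calibrated_hazard(baseline, rr, mrr[age_band(ages), sex])
    u = stream(seed, f"incidence_{c}", year).random(pop.n)
    new = rows[u[rows] < h]
    pop.dx_year[new, c] = year
    diag = {
        "expected": {
            MALE: float(baseline[sex == MALE].sum()),
            FEMALE: float(baseline[sex == FEMALE].sum()),
        },
        "variance": {
            MALE: float((h * (1 - h))[sex == MALE].sum()),
            FEMALE: float((h * (1 - h))[sex == FEMALE].sum()),
        },
    }
    return new, diag


def assign_survival_outcome(
    pop: Population, rows: np.ndarray, epi: DiseaseEpidemiology, seed: int
) -> None:
    """Draw the 5-year fatality plan for freshly diagnosed cases.

    A case dies of its cancer within five years with probability
    ``p_death_5y`` for its (age band, sex) at diagnosis; if so, the death
    year is diagnosis year + k with k drawn from the mortality-year
    weights (k = 0..4).
    """
    if len(rows) == 0:
        return
    c = epi.cancer
    year = pop.current_year
    band = age_band(pop.ages()[rows])
    p = epi.p_death_5y[band, pop.sex[rows]]
    uf = stream(seed, f"fatality_{c}", year).random(pop.n)
    ut = stream(seed, f"death_timing_{c}", year).random(pop.n)
    fatal = uf[rows] < p
    k = np.searchsorted(np.cumsum(epi.mortality_year_weights), ut[rows], side="right")
    k = np.clip(k, 0, 4)
    pop.will_die[rows, c] = fatal
    pop.cancer_death_year[rows[fatal], c] = year + k[fatal]


def execute_cancer_deaths(pop: Population, year: int) -> np.ndarray:
    """Resolve planned cancer deaths falling due this year.

    Background mortality competes: a case already dead of other causes
    simply never reaches its planned cancer death.  If several cancers of
    one individual fall due the same year, the lowest cancer index is
    recorded as the cause.
    """
    due = (
        pop.will_die
        & (pop.cancer_death_year == year)
        & ~pop.remission
        & pop.present()[:, None]
    )
    rows = np.flatnonzero(due.any(axis=1))
    if len(rows):
        cause = due[rows].argmax(axis=1)
        pop.alive[rows] = False
        pop.death_year[rows] = year
        pop.death_cause[rows] = cause.astype(np.int8)
    return rows


def apply_remission(pop: Population, year: int) -> np.ndarray:
    """Mark survivors five full years past diagnosis as recovered.

    Returns the per-cancer count of new remissions.  Remission is absorbing
    for that cancer's mortality; remitted individuals still accrue all
    other risks.
    """
    newly = (
        pop.present()[:, None]
        & (pop.dx_year >= 0)
        & ~pop.remission
        & ~pop.will_die
        & (year - pop.dx_year >= 5)
    )
    pop.remission |= newly
    return newly.sum(axis=0)
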