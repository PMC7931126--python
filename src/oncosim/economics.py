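"""Healthcare expenditure, DALYs, and counterfactual scenario comparison.

Costs follow a per-case annual basis: each active (not yet remitted) cancer
accrues its annual treatment cost, scaled up in the year of cancer death
and by a multimorbidity surcharge per additional concurrent cancer.  DALYs
are years lived with disability (prevalent active case-years times the
disability weight) plus years of life lost (cancer deaths times residual
life expectancy from the synthetic life table), undiscounted by default.

Scenario outputs are differences against a business-as-usual run paired on
the same random seed; uncertainty comes from percentile intervals over
independent replicate seeds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    AGE_BAND_LABELS,
    CANCERS,
    N_AGES,
    N_BANDS,
    N_CANCERS,
    SEXES,
)
from .population import Population
from .synthetic_country import CostProfile, CountryProfile


# ---------------------------------------------------------------------------
# Per-case costing
# ---------------------------------------------------------------------------


def annual_cost(active_costs, costs: CostProfile, terminal_year: bool = False) -> float:
    """Cost of one individual-year given their active cancers' base costs.

    Sum over active cancers of base cost x terminal multiplier (if this is
    the year of the individual's cancer death) x multimorbidity factor
    ``1 + increment x (k - 1)`` where k is the number of concurrent active
    cancers.
    """
    active_costs = np.asarray(active_costs, dtype=float)
    k = active_costs.size
    if k == 0:
        return 0.0
    mm = 1.0 + costs.multimorbidity_increment * (k - 1)
    term = costs.last_year_multiplier if terminal_year else 1.0
    return float(active_costs.sum() * term * mm)


def annual_cost_components(pop: Population, costs: CostProfile, year: int):
    """Vectorized costing of every individual-year in ``year``.

    An individual accrues costs if in-country and alive during the year
    (including the year of death).  Returns ``(per_cancer_totals,
    per_individual_totals, active_matrix)``.
    """
    in_country = pop.migration_status != 2
    alive_during = pop.alive | (pop.death_year == year)
    active = (
        (pop.dx_year >= 0)
        & (pop.dx_year <= year)
        & ~pop.remission
        & (in_country & alive_during)[:, None]
    )
    k = active.sum(axis=1)
    mm = 1.0 + costs.multimorbidity_increment * np.maximum(k - 1, 0)
    terminal = (pop.death_cause >= 0) & (pop.death_cause < N_CANCERS) & (pop.death_year == year)
    term = np.where(terminal, costs.last_year_multiplier, 1.0)
    cost_matrix = active * costs.annual_cost[None, :] * (term * mm)[:, None]
    return cost_matrix.sum(axis=0), cost_matrix.sum(axis=1), active


# ---------------------------------------------------------------------------
# Life table and DALYs
# ---------------------------------------------------------------------------


def residual_life_expectancy(profile: CountryProfile) -> np.ndarray:
    """Remaining life expectancy by (age, sex) from background mortality.

    Curtate expectation plus half a year: e(a) = 0.5 + sum_t prod_{k<t}
    (1 - q(a+k)) over the remaining ages of the life table.
    """
    q = profile.background_mortality
    e = np.zeros_like(q)
    for s in range(q.shape[1]):
        surv = np.cumprod(1.0 - q[:, s])
        # survival from a to a+t is surv[a+t-1] / surv[a-1]
        padded = np.concatenate([[1.0], surv])
        for a in range(q.shape[0]):
            e[a, s] = 0.5 + (padded[a + 1 :] / padded[a]).sum()
    return e


def compute_dalys(
    events: pd.DataFrame,
    deaths_by_age: pd.DataFrame,
    disability_weight: np.ndarray,
    life_expectancy: np.ndarray,
) -> pd.DataFrame:
    """DALYs per (year, cancer): YLD from prevalence, YLL from deaths."""
    yld = (
        events.assign(yld=lambda d: d["prevalent"] * disability_weight[d["cancer"].map(
            {name: i for i, name in enumerate(CANCERS)}
        )])
        .groupby(["year", "cancer"], as_index=False)["yld"]
        .sum()
    )
    if len(deaths_by_age):
        d = deaths_by_age.copy()
        sex_idx = d["sex"].map({name: i for i, name in enumerate(SEXES)})
        ages = np.clip(d["age"].to_numpy(), 0, life_expectancy.shape[0] - 1)
        d["yll"] = d["count"].to_numpy() * life_expectancy[ages, sex_idx.to_numpy()]
        yll = d.groupby(["year", "cancer"], as_index=False)["yll"].sum()
    else:
        yll = pd.DataFrame(columns=["year", "cancer", "yll"])
    out = yld.merge(yll, on=["year", "cancer"], how="outer")
    out[["yld", "yll"]] = out[["yld", "yll"]].astype(float).fillna(0.0)
    out["daly"] = out["yld"] + out["yll"]
    return out.sort_values(["year", "cancer"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Run results and scenario comparison
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    """Yearly cross-sections and economic aggregates of one simulation run."""

    seed: int
    intervention: str | None
    years: np.ndarray
    events: pd.DataFrame  # year, cancer, age_band, sex, incident, deaths, prevalent, remissions
    deaths_by_age: pd.DataFrame  # year, cancer, age, sex, count
    expenditure: pd.DataFrame  # year, cancer, cost (USD PPP)
    person_years: pd.Series  # indexed by year
    dalys: pd.DataFrame  # year, cancer, yld, yll, daly
    accounting: pd.DataFrame  # yearly demographic ledger
    audit_individual_costs: pd.Series  # yearly sum of per-individual costs
    calibration: pd.DataFrame  # cancer, sex, observed, expected, variance

    @property
    def total_expenditure(self) -> float:
        return float(self.expenditure["cost"].sum())

    @property
    def total_incident(self) -> float:
        return float(self.events["incident"].sum())


@dataclass
class ScenarioComparison:
    """Differences of an intervention run against its paired counterfactual."""

    intervention: str
    seed: int
    years: np.ndarray
    cases_avoided: pd.DataFrame  # year, cancer, age_band, sex, avoided
    total_cases_avoided: float
    avoided_by_cancer: pd.Series
    expenditure_avoided: float
    savings_per_capita_per_year: float
    dalys_averted: float
    person_years: float


def compare_scenarios(
    baseline: RunResult, intervention: RunResult
) -> ScenarioComparison:
    """Difference two runs paired on seed (common random numbers).

    Cases avoided are counterfactual minus intervention incident counts per
    stratum; savings are the expenditure difference divided by baseline
    person-years, in USD PPP per capita per year.
    """
    if not np.array_equal(baseline.years, intervention.years):
        raise ValueError("runs must share the same horizon")
    if baseline.seed != intervention.seed:
        raise ValueError("runs must be paired on the same seed")
    keys = ["year", "cancer", "age_band", "sex"]
    merged = baseline.events[keys + ["incident"]].merge(
        intervention.events[keys + ["incident"]],
        on=keys,
        suffixes=("_base", "_int"),
    )
    merged["avoided"] = merged["incident_base"] - merged["incident_int"]
    avoided = merged[keys + ["avoided"]]
    py = float(baseline.person_years.sum())
    exp_avoided = baseline.total_expenditure - intervention.total_expenditure
    return ScenarioComparison(
        intervention=intervention.intervention or "",
        seed=baseline.seed,
        years=baseline.years,
        cases_avoided=avoided,
        total_cases_avoided=float(avoided["avoided"].sum()),
        avoided_by_cancer=avoided.groupby("cancer")["avoided"].sum(),
        expenditure_avoided=exp_avoided,
        savings_per_capita_per_year=exp_avoided / py,
        dalys_averted=float(baseline.dalys["daly"].sum() - intervention.dalys["daly"].sum()),
        person_years=py,
    )


def decade_shares(comparison: ScenarioComparison) -> pd.Series:
    """Share of cumulative cases avoided per decade of the horizon."""
    df = comparison.cases_avoided.copy()
    decade = (df["year"] // 10) * 10
    by_decade = df.groupby(decade)["avoided"].sum()
    total = by_decade.sum()
    if total == 0:
        return by_decade * 0.0
    return by_decade / total


def replicate_ci(values, level: float = 95.0):
    """Percentile interval and mean across replicate values.

    ``values`` is a sequence (replicates) of scalars or aligned arrays.
    Returns ``(point, low, high)`` with the point estimate the replicate
    mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 replicates for an interval")
    alpha = (100.0 - level) / 2.0
    point = arr.mean(axis=0)
    low = np.percentile(arr, alpha, axis=0)
    high = np.percentile(arr, 100.0 - alpha, axis=0)
    return point, low, high
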