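"""Orchestration: paired counterfactual/intervention runs over a config.

Policies are implemented in the profile's start year (2019 by default) and
outcomes reported over the following horizon (2020-2050).  Every replicate
runs one business-as-usual and one intervention simulation on the same
seed, so the random streams driving births, deaths, and incidence draws are
common to both; the difference between the pair isolates the intervention.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import (
    AGE_BAND_LABELS,
    CANCERS,
    N_BANDS,
    N_CANCERS,
    SEXES,
    age_band,
)
from .disease import (
    apply_remission,
    assign_survival_outcome,
    execute_cancer_deaths,
    sample_incident_cases,
)
from .economics import (
    RunResult,
    ScenarioComparison,
    annual_cost_components,
    compare_scenarios,
    compute_dalys,
    replicate_ci,
    residual_life_expectancy,
)
from .interventions import (
    InterventionSpec,
    apply_risk_factor_effect,
    build_intervention,
    select_exposed,
)
from .population import Population, initialize_population, step_demographics
from .synthetic_country import World, generate_world


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce one paired scenario end to end."""

    seed: int = 1
    scale: int = 20000
    n_quantiles: int = 5
    intervention: str = "alcohol_tax"
    implementation_year: int = 2019
    end_year: int = 2050
    replicates: int = 5
    outdir: str | None = None

    def __post_init__(self):
        if self.end_year <= self.implementation_year:
            raise ValueError("end_year must exceed implementation_year")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scale < 1000:
            raise ValueError("scale must be at least 1000")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def replicate_seeds(master_seed: int, replicates: int) -> np.ndarray:
    """Independent sub-seeds (< 2^31) derived deterministically."""
    state = np.random.SeedSequence(master_seed).generate_state(replicates, np.uint32)
    return (state % np.uint32(2**31)).astype(np.int64)


def simulate(
    world: World,
    seed: int,
    spec: InterventionSpec | None = None,
    end_year: int = 2050,
    return_population: bool = False,
):
    """Run one life-history simulation over the horizon.

    Yearly order of events: demographics (ageing, births, migration,
    background deaths), intervention exposure shift, cancer incidence and
    fatality assignment, planned cancer deaths, remission, then the yearly
    cross-section (counts, costs, person-years) is recorded.  Intervention
    effects are evaluated at mid-year offsets of the effect schedule.
    """
    profile = world.profile
    pop = initialize_population(profile, world.distributions, seed)
    if spec is not None:
        select_exposed(pop, spec, seed)

    years = np.arange(profile.start_year + 1, end_year + 1)
    ny = len(years)
    incident = np.zeros((ny, N_CANCERS, N_BANDS, 2))
    deaths = np.zeros((ny, N_CANCERS, N_BANDS, 2))
    prevalent = np.zeros((ny, N_CANCERS, N_BANDS, 2))
    remissions = np.zeros((ny, N_CANCERS))
    expenditure = np.zeros((ny, N_CANCERS))
    audit = np.zeros(ny)
    person_years = np.zeros(ny)
    death_age_rows = []
    accounting_rows = []
    observed_cal = np.zeros((N_CANCERS, 2))
    expected_cal = np.zeros((N_CANCERS, 2))
    variance_cal = np.zeros((N_CANCERS, 2))

    for yi, year in enumerate(years):
        acc = step_demographics(pop, profile)
        pop.reset_effective()
        if spec is not None:
            t = year - profile.start_year - 0.5
            apply_risk_factor_effect(
                pop, spec, t, world.distributions, world.rr, world.elasticities
            )

        for c in range(N_CANCERS):
            epi = world.epidemiology[c]
            new, diag = sample_incident_cases(pop, epi, world.rr, year, seed)
            assign_survival_outcome(pop, new, epi, seed)
            if len(new):
                b = age_band(pop.ages()[new])
                np.add.at(incident[yi, c], (b, pop.sex[new]), 1.0)
            for s in (0, 1):
                observed_cal[c, s] += float((pop.sex[new] == s).sum())
                expected_cal[c, s] += diag["expected"][s]
                variance_cal[c, s] += diag["variance"][s]

        died = execute_cancer_deaths(pop, year)
        if len(died):
            b = age_band(pop.ages()[died])
            cause = pop.death_cause[died]
            np.add.at(deaths[yi], (cause, b, pop.sex[died]), 1.0)
            for r, c_, b_, s_ in zip(died, cause, b, pop.sex[died]):
                death_age_rows.append(
                    (year, CANCERS[c_], int(pop.ages()[r]), SEXES[s_], 1)
                )
        remissions[yi] = apply_remission(pop, year)

        per_cancer, per_ind, active = annual_cost_components(pop, world.costs, year)
        expenditure[yi] = per_cancer
        audit[yi] = per_ind.sum()
        present = pop.present()
        person_years[yi] = int(present.sum())
        b_all = age_band(pop.ages())
        for c in range(N_CANCERS):
            rowsc = np.flatnonzero(active[:, c] & pop.alive & present)
            np.add.at(prevalent[yi, c], (b_all[rowsc], pop.sex[rowsc]), 1.0)

        acc["cancer_deaths"] = int(len(died))
        acc["end"] = int(present.sum())
        accounting_rows.append(acc)

    # Assemble tidy frames.
    idx = pd.MultiIndex.from_product(
        [years, CANCERS, AGE_BAND_LABELS, SEXES],
        names=["year", "cancer", "age_band", "sex"],
    )
    events = pd.DataFrame(
        {
            "incident": incident.ravel(),
            "deaths": deaths.ravel(),
            "prevalent": prevalent.ravel(),
        },
        index=idx,
    ).reset_index()
    rem = pd.DataFrame(
        {"year": np.repeat(years, N_CANCERS), "cancer": list(CANCERS) * ny,
         "remissions": remissions.ravel()}
    )
    events = events.merge(rem, on=["year", "cancer"], how="left")
    events["remissions"] = events["remissions"].where(
        (events["age_band"] == AGE_BAND_LABELS[0]) & (events["sex"] == SEXES[0]), 0.0
    )
    deaths_by_age = pd.DataFrame(
        death_age_rows, columns=["year", "cancer", "age", "sex", "count"]
    )
    exp_df = pd.DataFrame(
        {"year": np.repeat(years, N_CANCERS), "cancer": list(CANCERS) * ny,
         "cost": expenditure.ravel()}
    )
    life_exp = residual_life_expectancy(profile)
    dalys = compute_dalys(events, deaths_by_age, world.costs.disability_weight, life_exp)
    calibration = pd.DataFrame(
        [
            (CANCERS[c], SEXES[s], observed_cal[c, s], expected_cal[c, s], variance_cal[c, s])
            for c in range(N_CANCERS)
            for s in (0, 1)
        ],
        columns=["cancer", "sex", "observed", "expected", "variance"],
    )
    result = RunResult(
        seed=seed,
        intervention=spec.name if spec is not None else None,
        years=years,
        events=events,
        deaths_by_age=deaths_by_age,
        expenditure=exp_df,
        person_years=pd.Series(person_years, index=years, name="person_years"),
        dalys=dalys,
        accounting=pd.DataFrame(accounting_rows),
        audit_individual_costs=pd.Series(audit, index=years, name="audit"),
        calibration=calibration,
    )
    if return_population:
        return result, pop
    return result


def run_paired_scenario(config: ScenarioConfig, world: World | None = None) -> dict:
    """Run replicate paired scenarios and aggregate with percentile CIs.

    Returns a dict with per-replicate :class:`ScenarioComparison` objects
    and point/interval summaries; when ``config.outdir`` is set, writes
    ``summary.json``, ``cases_avoided.csv``, and ``run_metadata.json``.
    """
    spec = build_intervention(config.intervention)
    if world is None:
        world = generate_world(config.seed, config.scale, config.n_quantiles)
    seeds = replicate_seeds(config.seed, config.replicates)
    comparisons: list[ScenarioComparison] = []
    for rs in seeds:
        base = simulate(world, int(rs), None, config.end_year)
        intv = simulate(world, int(rs), spec, config.end_year)
        comparisons.append(compare_scenarios(base, intv))

    totals = [c.total_cases_avoided for c in comparisons]
    savings = [c.savings_per_capita_per_year for c in comparisons]
    dalys = [c.dalys_averted for c in comparisons]
    summary = {
        "intervention": config.intervention,
        "replicates": config.replicates,
        "scale": config.scale,
        "horizon": [config.implementation_year + 1, config.end_year],
        "cases_avoided": _point_ci(totals, config.replicates),
        "savings_per_capita_per_year_usd_ppp": _point_ci(savings, config.replicates),
        "dalys_averted": _point_ci(dalys, config.replicates),
    }
    by_cancer = pd.concat([c.avoided_by_cancer for c in comparisons], axis=1)
    summary["cases_avoided_by_cancer"] = {
        cancer: _point_ci(by_cancer.loc[cancer].to_numpy(), config.replicates)
        for cancer in by_cancer.index
    }

    result = {"config": config, "comparisons": comparisons, "summary": summary}
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        mean_avoided = (
            pd.concat([c.cases_avoided for c in comparisons])
            .groupby(["year", "cancer", "age_band", "sex"], as_index=False)["avoided"]
            .mean()
        )
        mean_avoided.to_csv(out / "cases_avoided.csv", index=False)
        meta = {
            "config": dataclasses.asdict(config),
            "config_digest": config.digest(),
            "replicate_seeds": [int(s) for s in seeds],
            "version": __version__,
        }
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
    return result


def _point_ci(values, replicates: int) -> dict:
    values = np.asarray(values, dtype=float)
    if replicates >= 2:
        point, low, high = replicate_ci(values)
        return {"point": float(point), "ci_low": float(low), "ci_high": float(high)}
    return {"point": float(values.mean()), "ci_low": None, "ci_high": None}


def run_battery(
    world: World,
    names,
    replicates: int,
    master_seed: int,
    end_year: int = 2050,
) -> dict:
    """Paired comparisons for several policies sharing baseline runs.

    The counterfactual run of each replicate seed is computed once and
    reused against every policy, which both saves time and makes policy
    rankings exact pairwise comparisons under common random numbers.
    """
    seeds = replicate_seeds(master_seed, replicates)
    out = {name: [] for name in names}
    for rs in seeds:
        base = simulate(world, int(rs), None, end_year)
        for name in names:
            spec = build_intervention(name)
            intv = simulate(world, int(rs), spec, end_year)
            out[name].append(compare_scenarios(base, intv))
    return out
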