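"""Delimited-text serialization of generated model inputs.

Every input structure round-trips through plain CSV with documented column
schemas, so a generated world can be inspected, edited, and reloaded.

Files written by :func:`save_world` into a directory:

``meta.csv``
    name, start_year, ppp_factor, n_quantiles, seed
``pyramid.csv``
    age, sex, count
``vital_rates.csv``
    age, sex, fertility, background_mortality, net_migration
``risk_distributions.csv``
    factor, age_band, sex, quantile, edge_low, edge_high, mean
``incidence.csv``
    cancer, age, sex, rate
``fatality.csv``
    cancer, age_band, sex, p_death_5y
``mortality_weights.csv``
    cancer, year_since_diagnosis, weight
``relative_risks.csv``
    factor, quantile, cancer, age_band, sex, rr
``costs.csv``
    cancer, annual_cost, disability_weight, last_year_multiplier,
    multimorbidity_increment
``elasticities.csv``
    beverage, age_band, category, elasticity
``price_distribution.csv``
    kind ("price_bin" rows), price, share  plus "beverage_share" rows
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    AGE_BAND_LABELS,
    CANCERS,
    FACTORS,
    N_AGES,
    N_BANDS,
    N_CANCERS,
    N_FACTORS,
    SEXES,
)
from .synthetic_country import (
    BEVERAGES,
    CostProfile,
    CountryProfile,
    DiseaseEpidemiology,
    DRINKER_AGE_BANDS,
    DRINKING_CATEGORIES,
    ElasticityTable,
    RelativeRiskTable,
    RiskFactorDistribution,
    World,
)

_FLOAT = "%.17g"


def _read(path):
    return pd.read_csv(path, float_precision="round_trip")


def save_world(world: World, directory) -> None:
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    p = world.profile

    pd.DataFrame(
        {
            "name": [p.name],
            "start_year": [p.start_year],
            "ppp_factor": [p.ppp_factor],
            "n_quantiles": [world.n_quantiles],
            "seed": [world.seed],
        }
    ).to_csv(out / "meta.csv", index=False, float_format=_FLOAT)

    age = np.repeat(np.arange(N_AGES), 2)
    sex = np.tile([0, 1], N_AGES)
    pd.DataFrame(
        {"age": age, "sex": np.array(SEXES)[sex], "count": p.pyramid.ravel()}
    ).to_csv(out / "pyramid.csv", index=False, float_format=_FLOAT)
    pd.DataFrame(
        {
            "age": age,
            "sex": np.array(SEXES)[sex],
            "fertility": np.repeat(p.fertility, 2),
            "background_mortality": p.background_mortality.ravel(),
            "net_migration": p.net_migration.ravel(),
        }
    ).to_csv(out / "vital_rates.csv", index=False, float_format=_FLOAT)

    rows = []
    for d in world.distributions:
        for b in range(N_BANDS):
            for s in range(2):
                for q in range(d.n_quantiles):
                    rows.append(
                        (
                            FACTORS[d.factor],
                            AGE_BAND_LABELS[b],
                            SEXES[s],
                            q,
                            d.edges[b, s, q],
                            d.edges[b, s, q + 1],
                            d.means[b, s, q],
                        )
                    )
    pd.DataFrame(
        rows,
        columns=["factor", "age_band", "sex", "quantile", "edge_low", "edge_high", "mean"],
    ).to_csv(out / "risk_distributions.csv", index=False, float_format=_FLOAT)

    inc_rows, fat_rows, w_rows = [], [], []
    for c, epi in world.epidemiology.items():
        for a in range(N_AGES):
            for s in range(2):
                inc_rows.append((CANCERS[c], a, SEXES[s], epi.baseline_incidence[a, s]))
        for b in range(N_BANDS):
            for s in range(2):
                fat_rows.append((CANCERS[c], AGE_BAND_LABELS[b], SEXES[s], epi.p_death_5y[b, s]))
        for k in range(5):
            w_rows.append((CANCERS[c], k, epi.mortality_year_weights[k]))
    pd.DataFrame(inc_rows, columns=["cancer", "age", "sex", "rate"]).to_csv(
        out / "incidence.csv", index=False, float_format=_FLOAT
    )
    pd.DataFrame(fat_rows, columns=["cancer", "age_band", "sex", "p_death_5y"]).to_csv(
        out / "fatality.csv", index=False, float_format=_FLOAT
    )
    pd.DataFrame(w_rows, columns=["cancer", "year_since_diagnosis", "weight"]).to_csv(
        out / "mortality_weights.csv", index=False, float_format=_FLOAT
    )

    rr = world.rr.rr
    f, q, c, b, s = np.meshgrid(
        np.arange(N_FACTORS),
        np.arange(rr.shape[1]),
        np.arange(N_CANCERS),
        np.arange(N_BANDS),
        np.arange(2),
        indexing="ij",
    )
    pd.DataFrame(
        {
            "factor": np.array(FACTORS)[f.ravel()],
            "quantile": q.ravel(),
            "cancer": np.array(CANCERS)[c.ravel()],
            "age_band": np.array(AGE_BAND_LABELS)[b.ravel()],
            "sex": np.array(SEXES)[s.ravel()],
            "rr": rr.ravel(),
        }
    ).to_csv(out / "relative_risks.csv", index=False, float_format=_FLOAT)

    pd.DataFrame(
        {
            "cancer": list(CANCERS),
            "annual_cost": world.costs.annual_cost,
            "disability_weight": world.costs.disability_weight,
            "last_year_multiplier": world.costs.last_year_multiplier,
            "multimorbidity_increment": world.costs.multimorbidity_increment,
        }
    ).to_csv(out / "costs.csv", index=False, float_format=_FLOAT)

    e = world.elasticities
    bv, ab, cat = np.meshgrid(
        np.arange(3), np.arange(3), np.arange(2), indexing="ij"
    )
    pd.DataFrame(
        {
            "beverage": np.array(BEVERAGES)[bv.ravel()],
            "age_band": np.array(DRINKER_AGE_BANDS)[ab.ravel()],
            "category": np.array(DRINKING_CATEGORIES)[cat.ravel()],
            "elasticity": e.elasticity.ravel(),
        }
    ).to_csv(out / "elasticities.csv", index=False, float_format=_FLOAT)
    price = pd.DataFrame(
        {"kind": "price_bin", "label": e.price_bins.astype(str), "value": e.price_shares}
    )
    bev = pd.DataFrame(
        {"kind": "beverage_share", "label": list(BEVERAGES), "value": e.beverage_shares}
    )
    pd.concat([price, bev]).to_csv(
        out / "price_distribution.csv", index=False, float_format=_FLOAT
    )


def load_world(directory) -> World:
    src = Path(directory)
    sex_idx = {name: i for i, name in enumerate(SEXES)}
    cancer_idx = {name: i for i, name in enumerate(CANCERS)}
    factor_idx = {name: i for i, name in enumerate(FACTORS)}
    band_idx = {name: i for i, name in enumerate(AGE_BAND_LABELS)}

    meta = _read(src / "meta.csv").iloc[0]
    pyr = _read(src / "pyramid.csv")
    pyramid = np.zeros((N_AGES, 2))
    pyramid[pyr["age"], pyr["sex"].map(sex_idx)] = pyr["count"]
    vr = _read(src / "vital_rates.csv")
    fertility = np.zeros(N_AGES)
    mortality = np.zeros((N_AGES, 2))
    migration = np.zeros((N_AGES, 2))
    si = vr["sex"].map(sex_idx)
    fertility[vr["age"]] = vr["fertility"]
    mortality[vr["age"], si] = vr["background_mortality"]
    migration[vr["age"], si] = vr["net_migration"]
    profile = CountryProfile(
        name=str(meta["name"]),
        start_year=int(meta["start_year"]),
        pyramid=pyramid,
        fertility=fertility,
        background_mortality=mortality,
        net_migration=migration,
        ppp_factor=float(meta["ppp_factor"]),
    )

    n_quantiles = int(meta["n_quantiles"])
    rd = _read(src / "risk_distributions.csv")
    distributions = []
    for fname in FACTORS:
        f = factor_idx[fname]
        edges = np.zeros((N_BANDS, 2, n_quantiles + 1))
        means = np.zeros((N_BANDS, 2, n_quantiles))
        sub = rd[rd["factor"] == fname]
        b = sub["age_band"].map(band_idx).to_numpy()
        s = sub["sex"].map(sex_idx).to_numpy()
        q = sub["quantile"].to_numpy()
        edges[b, s, q] = sub["edge_low"]
        edges[b, s, q + 1] = sub["edge_high"]
        means[b, s, q] = sub["mean"]
        distributions.append(
            RiskFactorDistribution(factor=f, n_quantiles=n_quantiles, edges=edges, means=means)
        )

    inc = _read(src / "incidence.csv")
    fat = _read(src / "fatality.csv")
    wts = _read(src / "mortality_weights.csv")
    epidemiology = {}
    for cname in CANCERS:
        c = cancer_idx[cname]
        baseline = np.zeros((N_AGES, 2))
        sub = inc[inc["cancer"] == cname]
        baseline[sub["age"], sub["sex"].map(sex_idx)] = sub["rate"]
        p5 = np.zeros((N_BANDS, 2))
        sub = fat[fat["cancer"] == cname]
        p5[sub["age_band"].map(band_idx), sub["sex"].map(sex_idx)] = sub["p_death_5y"]
        w = wts[wts["cancer"] == cname].sort_values("year_since_diagnosis")["weight"].to_numpy()
        epidemiology[c] = DiseaseEpidemiology(
            cancer=c, baseline_incidence=baseline, p_death_5y=p5, mortality_year_weights=w
        )

    rrd = _read(src / "relative_risks.csv")
    rr = np.ones((N_FACTORS, n_quantiles, N_CANCERS, N_BANDS, 2))
    rr[
        rrd["factor"].map(factor_idx),
        rrd["quantile"],
        rrd["cancer"].map(cancer_idx),
        rrd["age_band"].map(band_idx),
        rrd["sex"].map(sex_idx),
    ] = rrd["rr"]

    cdf = _read(src / "costs.csv").set_index("cancer").loc[list(CANCERS)]
    costs = CostProfile(
        annual_cost=cdf["annual_cost"].to_numpy(),
        last_year_multiplier=float(cdf["last_year_multiplier"].iloc[0]),
        multimorbidity_increment=float(cdf["multimorbidity_increment"].iloc[0]),
        disability_weight=cdf["disability_weight"].to_numpy(),
    )

    ed = _read(src / "elasticities.csv")
    elas = np.zeros((3, 3, 2))
    elas[
        ed["beverage"].map({n: i for i, n in enumerate(BEVERAGES)}),
        ed["age_band"].map({n: i for i, n in enumerate(DRINKER_AGE_BANDS)}),
        ed["category"].map({n: i for i, n in enumerate(DRINKING_CATEGORIES)}),
    ] = ed["elasticity"]
    pdist = _read(src / "price_distribution.csv")
    bins = pdist[pdist["kind"] == "price_bin"]
    bev = pdist[pdist["kind"] == "beverage_share"].set_index("label").loc[list(BEVERAGES)]
    elasticities = ElasticityTable(
        elasticity=elas,
        beverage_shares=bev["value"].to_numpy(),
        price_bins=bins["label"].astype(float).to_numpy(),
        price_shares=bins["value"].to_numpy(),
    )

    world = World(
        profile=profile,
        distributions=distributions,
        epidemiology=epidemiology,
        rr=RelativeRiskTable(rr=rr),
        costs=costs,
        elasticities=elasticities,
        n_quantiles=n_quantiles,
        seed=int(meta["seed"]),
    )
    world.validate()
    return world
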