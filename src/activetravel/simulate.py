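"""Synthetic multilevel travel datasets with known ground truth.

Real city-level mode-share data of this kind are proprietary, so every
downstream stage (model fitting, effect summaries, scenario sweeps) is
exercised against data drawn from the model's own assumed data-generating
process: cities nested in countries, correlated national covariates,
country-varying logit-scale slopes moderated by national income, and
beta-distributed walk/cycle shares.

The defaults below define the simulated study conditions: a walk share a
little over a tenth of non-transit km and a cycle share under one percent,
density the strongest city-level covariate, gasoline price the strongest
national one, and income moderating the density slope. Scales of the raw
covariates (density in persons/km², temperatures in °C, precipitation in
mm/year, GDP in USD) are set to resemble a global city sample.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .schema import (
    CITY_COVARIATES,
    COUNTRY_COVARIATES,
    CityRecord,
    CountryRecord,
    write_city_table,
    write_country_table,
)

logger = logging.getLogger(__name__)

OUTCOMES = ("walk", "cycle")

#: mean km per trip by mode, used to convert km volumes into trip counts.
#: Chosen so that pooled trip shares (walking several times cycling, both
#: far above their km shares) follow from the km shares: walking trips are
#: short, motorized trips long.
TRIP_LENGTH_KM = {"walk": 1.2, "cycle": 3.67, "car_moto": 9.5, "transit": 11.0}


def _outcome_map(walk: float, cycle: float) -> dict[str, float]:
    return {"walk": walk, "cycle": cycle}


def _per_covariate(walk: dict, cycle: dict) -> dict[str, dict[str, float]]:
    return {"walk": dict(walk), "cycle": dict(cycle)}


_DEFAULT_GAMMA0 = _per_covariate(
    walk={"ln_density": 0.16, "B": 0.08, "terrain": -0.02, "tmin": 0.05,
          "tmin2": -0.04, "tmax": -0.08, "precip": -0.01},
    cycle={"ln_density": 0.06, "B": 0.07, "terrain": -0.25, "tmin": 0.06,
           "tmin2": -0.05, "tmax": -0.01, "precip": -0.02},
)
_DEFAULT_GAMMA1 = _per_covariate(
    walk={"ln_density": 0.06, "B": -0.02, "terrain": 0.0, "tmin": 0.0,
          "tmin2": 0.0, "tmax": 0.0, "precip": 0.0},
    cycle={"ln_density": 0.03, "B": 0.02, "terrain": 0.0, "tmin": 0.0,
           "tmin2": 0.0, "tmax": 0.0, "precip": 0.0},
)
_DEFAULT_TAU = _per_covariate(
    walk={k: 0.06 for k in CITY_COVARIATES},
    cycle={k: 0.06 for k in CITY_COVARIATES},
)
_DEFAULT_DELTA = _per_covariate(
    walk={"gas_price": 0.12, "ln_gdp_pc": -0.05, "dependency_ratio": 0.03},
    cycle={"gas_price": 0.10, "ln_gdp_pc": 0.06, "dependency_ratio": 0.02},
)


@dataclass
class TruthConfig:
    """Ground-truth parameters and distributional settings for generation.

    Logit-scale coefficients are per standardized covariate; ``phi`` is the
    beta precision (larger = shares cluster tighter around the mean).
    """

    n_countries: int = 10
    cities_per_country: int = 20
    # logit-scale intercepts on the transit-excluded denominator: pooled km
    # shares near 2% walking and 0.9% cycling of all travel (walk ~2.6% and
    # cycle ~1.2% of non-transit km)
    hyper_intercepts: dict[str, float] = field(
        default_factory=lambda: _outcome_map(-3.6, -4.4))
    sigma_alpha: dict[str, float] = field(
        default_factory=lambda: _outcome_map(0.35, 0.35))
    gamma0: dict[str, dict[str, float]] = field(
        default_factory=lambda: {o: dict(_DEFAULT_GAMMA0[o]) for o in OUTCOMES})
    gamma1: dict[str, dict[str, float]] = field(
        default_factory=lambda: {o: dict(_DEFAULT_GAMMA1[o]) for o in OUTCOMES})
    tau: dict[str, dict[str, float]] = field(
        default_factory=lambda: {o: dict(_DEFAULT_TAU[o]) for o in OUTCOMES})
    delta: dict[str, dict[str, float]] = field(
        default_factory=lambda: {o: dict(_DEFAULT_DELTA[o]) for o in OUTCOMES})
    phi: dict[str, float] = field(default_factory=lambda: _outcome_map(90.0, 160.0))
    # raw covariate model
    mean_ln_density: float = 8.0      # ~3,000 persons/km²
    sd_ln_density: float = 0.9
    bikeway_zero_prob: float = 0.35   # cities with no bicycle facility at all
    bikeway_gamma_shape: float = 1.3
    bikeway_gamma_scale: float = 6.0  # B in km per 100 road-km, truncated to [0, 100]
    terrain_sd: float = 1.0           # half-normal ruggedness index
    tmin_mean: float = 5.0
    tmin_sd: float = 8.0
    temp_span_mean: float = 18.0      # tmax - tmin, clipped >= 0
    temp_span_sd: float = 4.0
    precip_shape: float = 2.0
    precip_scale: float = 500.0       # mm/year, mean ~1,000
    gas_price_mean: float = 1.2       # USD/liter
    gas_price_sd: float = 0.4
    mean_ln_gdp: float = 9.6          # ~15,000 USD per capita
    sd_ln_gdp: float = 1.0
    gas_gdp_corr: float = 0.4
    dependency_mean: float = 55.0     # per 100 working-age persons
    dependency_sd: float = 10.0
    # volume model
    mean_ln_population: float = 12.2  # ~200,000 persons
    sd_ln_population: float = 1.0
    km_per_capita_mean: float = 2200.0
    km_per_capita_sd: float = 400.0
    transit_share_a: float = 2.3      # Beta params for descriptive transit km share
    transit_share_b: float = 7.7      # mean 0.23: transit ~23% of km traveled
    road_km_per_1000: float = 8.0     # road-network km per 1,000 residents
    inout_fraction: float = 0.301     # probability a city reports in/out-bound trips
    seed: int = 0

    def validate(self) -> None:
        if self.n_countries < 1 or self.cities_per_country < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.inout_fraction <= 1.0):
            raise ValueError("inout_fraction must lie in [0, 1]")
        for o in OUTCOMES:
            if not self.phi[o] > 0:
                raise ValueError("phi must be > 0")
            if any(t < 0 for t in self.tau[o].values()):
                raise ValueError("tau must be >= 0")

    def replace(self, **kwargs) -> "TruthConfig":
        return dataclasses.replace(self, **kwargs)


def _rngs(cfg: TruthConfig, n: int) -> list[np.random.Generator]:
    """Independent substreams derived from the master seed, one per stage."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(n)]


def generate_countries(cfg: TruthConfig) -> list[CountryRecord]:
    """Draw national covariates (gasoline price correlated with income)."""
    cfg.validate()
    rng = _rngs(cfg, 3)[0]
    J = cfg.n_countries
    rho = cfg.gas_gdp_corr
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=J)
    gas = np.clip(cfg.gas_price_mean + cfg.gas_price_sd * z[:, 0], 0.05, None)
    gdp = np.exp(cfg.mean_ln_gdp + cfg.sd_ln_gdp * z[:, 1])
    dep = np.clip(rng.normal(cfg.dependency_mean, cfg.dependency_sd, size=J), 10.0, None)
    return [
        CountryRecord(country_id=f"C{j:03d}", gas_price=float(gas[j]),
                      gdp_pc=float(gdp[j]), dependency_ratio=float(dep[j]))
        for j in range(J)
    ]


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_cities(
    cfg: TruthConfig, countries: list[CountryRecord]
) -> tuple[list[CityRecord], dict]:
    """Draw cities from the hierarchical beta data-generating process.

    Returns the records plus a ground-truth dict holding every drawn
    parameter (country intercepts and slopes, hyper-coefficients,
    precision) and the standardization registry of the generated sample,
    so estimators can be checked against the truth.
    """
    cfg.validate()
    if not countries:
        raise ValueError("countries must be nonempty")
    _, rng_cov, rng_out = _rngs(cfg, 3)
    J = len(countries)
    n_per = cfg.cities_per_country
    n = J * n_per
    country_index = np.repeat(np.arange(J), n_per)

    # raw city covariates
    ln_density = rng_cov.normal(cfg.mean_ln_density, cfg.sd_ln_density, n)
    B = np.where(
        rng_cov.random(n) < cfg.bikeway_zero_prob,
        0.0,
        np.clip(rng_cov.gamma(cfg.bikeway_gamma_shape, cfg.bikeway_gamma_scale, n), None, 100.0),
    )
    terrain = np.abs(rng_cov.normal(0.0, cfg.terrain_sd, n))
    tmin = rng_cov.normal(cfg.tmin_mean, cfg.tmin_sd, n)
    tmax = tmin + np.clip(rng_cov.normal(cfg.temp_span_mean, cfg.temp_span_sd, n), 0.0, None)
    precip = rng_cov.gamma(cfg.precip_shape, cfg.precip_scale, n)

    raw_x = {"ln_density": ln_density, "B": B, "terrain": terrain, "tmin": tmin,
             "tmin2": tmin ** 2, "tmax": tmax, "precip": precip}
    X = np.column_stack([_standardize(raw_x[k]) for k in CITY_COVARIATES])
    registry = {k: (float(raw_x[k].mean()), float(raw_x[k].std()))
                for k in CITY_COVARIATES}

    raw_z = {
        "gas_price": np.array([c.gas_price for c in countries]),
        "ln_gdp_pc": np.log([c.gdp_pc for c in countries]),
        "dependency_ratio": np.array([c.dependency_ratio for c in countries]),
    }
    Z = np.column_stack([_standardize(raw_z[k]) for k in COUNTRY_COVARIATES])
    registry.update({k: (float(raw_z[k].mean()), float(raw_z[k].std()))
                     for k in COUNTRY_COVARIATES})
    z_gdp = Z[:, COUNTRY_COVARIATES.index("ln_gdp_pc")]

    # country-level parameters and city shares per outcome
    truth: dict = {"registry": registry, "config": dataclasses.asdict(cfg),
                   "country_ids": [c.country_id for c in countries]}
    mu = {}
    for o in OUTCOMES:
        alpha = cfg.hyper_intercepts[o] + cfg.sigma_alpha[o] * rng_out.standard_normal(J)
        beta = np.column_stack([
            cfg.gamma0[o][k] + cfg.gamma1[o][k] * z_gdp
            + cfg.tau[o][k] * rng_out.standard_normal(J)
            for k in CITY_COVARIATES
        ])
        delta = np.array([cfg.delta[o][k] for k in COUNTRY_COVARIATES])
        eta = (alpha[country_index]
               + np.einsum("ik,ik->i", X, beta[country_index])
               + Z[country_index] @ delta)
        mu[o] = expit(eta)
        truth[o] = {
            "a": cfg.hyper_intercepts[o],
            "sigma_alpha": cfg.sigma_alpha[o],
            "alpha": alpha.tolist(),
            "beta": beta.tolist(),
            "gamma0": dict(cfg.gamma0[o]),
            "gamma1": dict(cfg.gamma1[o]),
            "tau": dict(cfg.tau[o]),
            "delta": dict(cfg.delta[o]),
            "phi": cfg.phi[o],
        }

    # beta draws for the two outcomes, rejecting physically impossible pairs
    def draw(mu_o, phi):
        a = mu_o * phi
        b = (1.0 - mu_o) * phi
        return rng_out.beta(a, b)

    y_walk = draw(mu["walk"], cfg.phi["walk"])
    y_cycle = draw(mu["cycle"], cfg.phi["cycle"])
    rejections = 0
    bad = (y_walk + y_cycle) >= 1.0
    while bad.any():
        rejections += int(bad.sum())
        y_walk[bad] = draw(mu["walk"][bad], cfg.phi["walk"])
        y_cycle[bad] = draw(mu["cycle"][bad], cfg.phi["cycle"])
        bad = (y_walk + y_cycle) >= 1.0
    if rejections:
        logger.info("redrew %d share pair(s) with walk + cycle >= 1", rejections)
    truth["share_rejections"] = rejections

    # volumes: total effective km fixed by population, split across modes
    population = np.exp(rng_cov.normal(cfg.mean_ln_population, cfg.sd_ln_population, n))
    km_pc = np.clip(rng_cov.normal(cfg.km_per_capita_mean, cfg.km_per_capita_sd, n), 300.0, None)
    total_km = population * km_pc
    transit_frac = rng_cov.beta(cfg.transit_share_a, cfg.transit_share_b, n)
    nontransit = total_km * (1.0 - transit_frac)
    eff_km = {
        "walk": nontransit * y_walk,
        "cycle": nontransit * y_cycle,
        "car_moto": nontransit * (1.0 - y_walk - y_cycle),
        "transit": total_km * transit_frac,
    }
    eff_trips = {m: eff_km[m] / TRIP_LENGTH_KM[m] for m in eff_km}

    road_km = cfg.road_km_per_1000 * population / 1000.0
    bikeway_km = B / 100.0 * road_km

    reports_inout = rng_cov.random(n) < cfg.inout_fraction
    # fraction of effective km attributed to boundary-crossing travel;
    # within = (1-f)·eff and inout = 2f·eff so that within + inout/2 = eff.
    f_inout = rng_cov.uniform(0.05, 0.4, n)

    records = []
    for i in range(n):
        j = country_index[i]
        if reports_inout[i]:
            f = f_inout[i]
            km_within = {m: float((1 - f) * eff_km[m][i]) for m in eff_km}
            km_inout = {m: float(2 * f * eff_km[m][i]) for m in eff_km}
            tr_within = {m: float((1 - f) * eff_trips[m][i]) for m in eff_trips}
            tr_inout = {m: float(2 * f * eff_trips[m][i]) for m in eff_trips}
        else:
            km_within = {m: float(eff_km[m][i]) for m in eff_km}
            km_inout = None
            tr_within = {m: float(eff_trips[m][i]) for m in eff_trips}
            tr_inout = None
        records.append(CityRecord(
            city_id=f"{countries[j].country_id}-city{i % n_per:03d}",
            country_id=countries[j].country_id,
            population=float(population[i]),
            km_within=km_within, km_inout=km_inout,
            trips_within=tr_within, trips_inout=tr_inout,
            road_km=float(road_km[i]), bikeway_km=float(bikeway_km[i]),
            density=float(np.exp(ln_density[i])), terrain=float(terrain[i]),
            tmin=float(tmin[i]), tmax=float(tmax[i]), precip=float(precip[i]),
        ))
    truth["shares"] = {"walk": y_walk.tolist(), "cycle": y_cycle.tolist()}
    return records, truth


def generate_dataset(cfg: TruthConfig) -> tuple[list[CityRecord], list[CountryRecord], dict]:
    countries = generate_countries(cfg)
    cities, truth = generate_cities(cfg, countries)
    return cities, countries, truth


PRESETS = {
    "tiny": TruthConfig(n_countries=3, cities_per_country=5, seed=11),
    "small": TruthConfig(n_countries=10, cities_per_country=20, seed=12),
    "recovery": TruthConfig(n_countries=30, cities_per_country=40, seed=13),
}


def make_fixture(name: str, out_dir) -> dict[str, Path]:
    """Write a preset dataset (cities.csv, countries.csv, truth.json) to disk."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cities, countries, truth = generate_dataset(PRESETS[name])
    paths = {"cities": out / "cities.csv", "countries": out / "countries.csv",
             "truth": out / "truth.json"}
    write_city_table(cities, paths["cities"])
    write_country_table(countries, paths["countries"])
    paths["truth"].write_text(json.dumps(truth, sort_keys=True, indent=1))
    return paths
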