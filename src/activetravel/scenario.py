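"""Counterfactual bicycle-infrastructure scenarios with posterior uncertainty.

The policy question: if every city raised its bikeway provision
B (km of bicycle facility per 100 km of road) to at least a floor B*,
how much travel would shift to walking and cycling, how much motorized
travel would be displaced, what CO2 would be saved, and what would the
health benefit of the added physical activity be worth?

Mechanics, per posterior draw and per floor:

1. every city's B becomes max(B, B*) — cities already above the floor do
   not change;
2. the standardized B column is recomputed against the *factual*
   standardization registry (coefficients were estimated on that scale);
3. predicted walk and cycle shares are re-evaluated through the fitted
   country-specific coefficients, and the share changes are converted to
   km using each city's fixed baseline non-transit travel volume;
4. each added active km displaces ``d_walk``/``d_cycle`` km of motorized
   travel (central assumption 1:1), split across private vehicles and
   transit in proportion to their baseline km; only the private-vehicle
   portion generates CO2 savings;
5. health benefits apply a per-km dollar multiplier to added walking and
   cycling km.

Uncertainty intervals are equal-tailed 2.5/97.5% quantiles across
posterior draws (coefficient uncertainty only by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import PosteriorDraws
from .schema import CITY_COVARIATES, CityRecord, DesignMatrix, effective_km

logger = logging.getLogger(__name__)

COPENHAGEN_B = 44.3  # km of bicycle facility per 100 km of road


@dataclass
class ScenarioConfig:
    """Assumptions of the counterfactual engine.

    ``emission_factor_g_km`` is a single global g CO2 per private-vehicle
    km; the *percent* CO2 reduction is invariant to its value (it cancels),
    but absolute tonnage is not. The health multipliers are deliberately
    simple per-km dollar values and are placeholders to be set from a
    health-impact source appropriate to the study region; results scale
    linearly in them.
    """

    B_grid: tuple[float, ...] = tuple(float(b) for b in range(1, 51))
    d_walk: float = 1.0    # km motorized displaced per added walking km (range 1.0-3.1)
    d_cycle: float = 1.0   # km motorized displaced per added cycling km (range 0.8-2.1)
    emission_factor_g_km: float = 170.0
    health_usd_per_km_walk: float = 0.50
    health_usd_per_km_cycle: float = 0.25
    include_observation_noise: bool = False
    n_draws: int | None = None   # subsample of posterior draws (None = all)
    seed: int = 0

    def validate(self) -> None:
        if any(b < 0 for b in self.B_grid):
            raise ValueError("scenario floors must be >= 0")
        if self.d_walk < 0 or self.d_cycle < 0:
            raise ValueError("displacement ratios must be >= 0")
        if self.emission_factor_g_km < 0:
            raise ValueError("emission factor must be >= 0")


def apply_floor(B, B_star: float):
    """Counterfactual provision max(B, B*): the floor is a minimum, cities
    already above it are unchanged."""
    B = np.asarray(B, dtype=float)
    if np.any(B < 0) or B_star < 0:
        raise ValueError("bikeway provision must be >= 0")
    out = np.maximum(B, B_star)
    return float(out) if out.shape == () else out


def required_construction(cities: list[CityRecord], B_star: float) -> float:
    """Total km of new bicycle facility needed to reach the floor."""
    total = 0.0
    skipped = 0
    for c in cities:
        if c.road_km <= 0:
            skipped += 1
            continue
        total += max(0.0, B_star / 100.0 * c.road_km - c.bikeway_km)
    if skipped:
        logger.warning("required_construction: skipped %d city(ies) with road_km = 0",
                       skipped)
    return total


def _eta_factual(draws: PosteriorDraws, design: DesignMatrix) -> np.ndarray:
    """(D, n) logit-scale predictors of the fitted cities."""
    c = design.country_index
    X = design.X[:, [CITY_COVARIATES.index(k) for k in draws.city_covariates]]
    eta = draws.alpha[:, c] + draws.z_terms[:, c]
    # accumulate per covariate to avoid a (D, n, K) temporary
    for k in range(X.shape[1]):
        eta = eta + draws.beta[:, :, k][:, c] * X[:, k][None, :]
    return eta


def shift_shares(
    draws: PosteriorDraws, design: DesignMatrix, B_star: float,
) -> np.ndarray:
    """(D, n) predicted share changes for one outcome under floor ``B_star``.

    The counterfactual standardized B uses the original registry; cities
    at or above the floor have exactly zero change.
    """
    if "B" not in draws.city_covariates:
        raise ValueError("fitted model has no bikeway-provision covariate")
    kB = draws.city_covariates.index("B")
    c = design.country_index
    x_fact = design.standardize("B", design.B_raw)
    x_cf = design.standardize("B", apply_floor(design.B_raw, B_star))
    dx = x_cf - x_fact                                   # (n,), zero above the floor
    eta = _eta_factual(draws, design)
    beta_B = draws.beta[:, :, kB][:, c]                  # (D, n)
    mu_fact = expit(eta)
    mu_cf = expit(eta + beta_B * dx[None, :])
    delta = mu_cf - mu_fact
    delta[:, dx == 0.0] = 0.0   # exact zero where the floor is inactive
    return delta


@dataclass
class _Baseline:
    """Per-city baseline volumes aligned with the design rows."""

    nontransit_km: np.ndarray   # walk + cycle + car_moto effective km
    car_km: np.ndarray
    transit_km: np.ndarray


def _baseline_volumes(cities: list[CityRecord], design: DesignMatrix) -> _Baseline:
    by_id = {c.city_id: c for c in cities}
    missing = [cid for cid in design.city_ids if cid not in by_id]
    if missing:
        raise ValueError(f"cities absent from records: {missing[:5]}")
    recs = [by_id[cid] for cid in design.city_ids]
    km = {m: np.array([effective_km(r, m) for r in recs])
          for m in ("walk", "cycle", "car_moto", "transit")}
    return _Baseline(
        nontransit_km=km["walk"] + km["cycle"] + km["car_moto"],
        car_km=km["car_moto"],
        transit_km=km["transit"],
    )


def displace_and_account(
    delta_walk: np.ndarray, delta_cycle: np.ndarray,
    baseline: _Baseline, config: ScenarioConfig,
) -> dict[str, np.ndarray]:
    """Convert per-draw share changes into km, CO2 and dollar aggregates.

    Returns per-draw (D,) aggregates. Displaced km in a city is capped at
    its baseline motorized km; the cap count is logged.
    """
    config.validate()
    dkm_walk = delta_walk * baseline.nontransit_km[None, :]     # (D, n)
    dkm_cycle = delta_cycle * baseline.nontransit_km[None, :]
    displaced_from_walk = config.d_walk * dkm_walk
    displaced_from_cycle = config.d_cycle * dkm_cycle
    displaced = displaced_from_walk + displaced_from_cycle

    motorized = baseline.car_km + baseline.transit_km
    capped = np.minimum(displaced, motorized[None, :])
    n_capped = int(np.sum(displaced > motorized[None, :]))
    if n_capped:
        logger.warning("displaced km capped at baseline motorized km in %d "
                       "city-draw case(s)", n_capped)
    # attribute the (possibly capped) displacement back to walk vs cycle
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(displaced != 0.0, capped / displaced, 1.0)
        p_car = np.where(motorized > 0, baseline.car_km / np.where(motorized > 0, motorized, 1.0), 0.0)
    displaced_car = capped * p_car[None, :]
    displaced_transit = capped - displaced_car
    car_from_walk = displaced_from_walk * scale * p_car[None, :]
    car_from_cycle = displaced_from_cycle * scale * p_car[None, :]

    ef = config.emission_factor_g_km
    co2_saved_g = displaced_car * ef
    baseline_co2_g = float(np.sum(baseline.car_km)) * ef
    co2_pct = (100.0 * co2_saved_g.sum(axis=1) / baseline_co2_g
               if baseline_co2_g > 0 else np.zeros(delta_walk.shape[0]))

    health = (config.health_usd_per_km_walk * dkm_walk.sum(axis=1)
              + config.health_usd_per_km_cycle * dkm_cycle.sum(axis=1))

    walk_co2_share = np.divide(
        car_from_walk.sum(axis=1), displaced_car.sum(axis=1),
        out=np.full(delta_walk.shape[0], np.nan),
        where=displaced_car.sum(axis=1) != 0)

    return {
        "dkm_walk": dkm_walk.sum(axis=1),
        "dkm_cycle": dkm_cycle.sum(axis=1),
        "displaced_km": capped.sum(axis=1),
        "displaced_car_km": displaced_car.sum(axis=1),
        "displaced_transit_km": displaced_transit.sum(axis=1),
        "co2_tonnes": co2_saved_g.sum(axis=1) / 1e6,
        "co2_pct": co2_pct,
        "health_usd": health,
        "walk_co2_share": walk_co2_share,
        "n_capped": n_capped,
    }


def _summ(v: np.ndarray) -> tuple[float, float, float]:
    lo, hi = np.percentile(v, [2.5, 97.5])
    return float(v.mean()), float(lo), float(hi)


def sweep(
    draws_walk: PosteriorDraws, draws_cycle: PosteriorDraws,
    design: DesignMatrix, cities: list[CityRecord], config: ScenarioConfig,
) -> pd.DataFrame:
    """Run the floor grid; one result row per floor with 95% UIs.

    Columns: ``B_star``, mean/lo/hi for added walk and cycle km, displaced
    km, CO2 % reduction, health USD, the walk share of CO2 savings, and
    the (draw-independent) km of new bikeway construction.
    """
    config.validate()
    if draws_walk.n_draws == 0 or draws_cycle.n_draws == 0:
        raise ValueError("empty posterior draw set")
    D = min(draws_walk.n_draws, draws_cycle.n_draws)
    if config.n_draws is not None and config.n_draws < D:
        idx = np.random.default_rng(config.seed).choice(D, config.n_draws, replace=False)
    else:
        idx = np.arange(D)

    baseline = _baseline_volumes(cities, design)
    modeled = [c for c in cities if c.city_id in set(design.city_ids)]
    rows = []
    for B_star in config.B_grid:
        dw = shift_shares(draws_walk, design, B_star)[idx]
        dc = shift_shares(draws_cycle, design, B_star)[idx]
        acc = displace_and_account(dw, dc, baseline, config)
        row = {"B_star": B_star,
               "new_bikeway_km": required_construction(modeled, B_star)}
        for key in ("dkm_walk", "dkm_cycle", "displaced_km", "displaced_car_km",
                    "co2_tonnes", "co2_pct", "health_usd"):
            mean, lo, hi = _summ(acc[key])
            row[f"{key}_mean"], row[f"{key}_lo"], row[f"{key}_hi"] = mean, lo, hi
        finite = acc["walk_co2_share"][np.isfinite(acc["walk_co2_share"])]
        row["walk_co2_share_mean"] = float(finite.mean()) if finite.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def percentile95_floor(design: DesignMatrix) -> float:
    """The 95th percentile of observed bikeway provision — an alternative,
    less ambitious floor than the Copenhagen level."""
    return float(np.percentile(design.B_raw, 95))


def long_format(result: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready long table: one row per (floor, quantity, statistic)."""
    keep = [c for c in result.columns if c.endswith(("_mean", "_lo", "_hi"))]
    long = result.melt(id_vars=["B_star"], value_vars=keep,
                       var_name="key", value_name="value")
    long[["quantity", "stat"]] = long["key"].str.rsplit("_", n=1, expand=True)
    return long.drop(columns="key")
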