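"""City/country data model, mode-share arithmetic, and design matrices.

The unit of analysis is a city-year: annual km traveled and trips made by
four modes (walk, cycle, private motor vehicle, public transit), split into
within-boundary and optional in/out-bound components, plus infrastructure
and physical-geography covariates. Countries contribute national covariates
(gasoline price, GDP per capita, dependency ratio).

Two mode-share conventions coexist:

* the *regression* share excludes public transit from the denominator
  (walk + cycle + car/moto), because the substitution of interest is
  between active travel and private motor vehicles;
* the *descriptive* share includes transit, and is used for dataset-level
  summaries only.

In/out-bound travel (trips crossing the city boundary) is counted at 50%
of its distance, following greenhouse-gas reporting convention; cities
without in/out-bound data are a legal state, not an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("walk", "cycle", "car_moto", "transit")
ACTIVE_MODES = ("walk", "cycle")
REGRESSION_MODES = ("walk", "cycle", "car_moto")

CITY_COVARIATES = ("ln_density", "B", "terrain", "tmin", "tmin2", "tmax", "precip")
COUNTRY_COVARIATES = ("gas_price", "ln_gdp_pc", "dependency_ratio")

#: CSV column for each (mode, component) volume field.
_KM_COLS = {m: (f"km_{m.replace('car_moto', 'carmoto')}_within",
                f"km_{m.replace('car_moto', 'carmoto')}_inout") for m in MODES}
_TRIP_COLS = {m: (f"trips_{m.replace('car_moto', 'carmoto')}_within",
                  f"trips_{m.replace('car_moto', 'carmoto')}_inout") for m in MODES}

CITY_MANDATORY_COLUMNS = (
    ["city_id", "country_id", "population"]
    + [_KM_COLS[m][0] for m in MODES]
    + [_TRIP_COLS[m][0] for m in MODES]
    + ["road_km", "bikeway_km", "density", "terrain", "tmin_c", "tmax_c", "precip_mm"]
)
CITY_INOUT_COLUMNS = [_KM_COLS[m][1] for m in MODES] + [_TRIP_COLS[m][1] for m in MODES]
COUNTRY_COLUMNS = ["country_id", "gas_price_usd_l", "gdp_pc_usd", "dependency_ratio"]


class SchemaError(ValueError):
    """A table violates the documented column/record contract."""


@dataclass
class CityRecord:
    """One city's annual travel volumes and covariates.

    ``km_inout``/``trips_inout`` are ``None`` for cities reporting only
    within-boundary travel (``within_only`` is then True).
    """

    city_id: str
    country_id: str
    population: float
    km_within: dict[str, float]
    trips_within: dict[str, float]
    road_km: float
    bikeway_km: float
    density: float
    terrain: float
    tmin: float
    tmax: float
    precip: float
    km_inout: dict[str, float] | None = None
    trips_inout: dict[str, float] | None = None

    @property
    def within_only(self) -> bool:
        return self.km_inout is None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        for name in ("population", "road_km", "bikeway_km", "precip", "terrain"):
            if getattr(self, name) < 0:
                problems.append(f"{name} < 0")
        if not self.density > 0:
            problems.append("density must be > 0")
        if self.tmax < self.tmin:
            problems.append("tmax < tmin")
        for label, d in (("km_within", self.km_within), ("trips_within", self.trips_within),
                         ("km_inout", self.km_inout), ("trips_inout", self.trips_inout)):
            if d is None:
                continue
            for m in MODES:
                if m not in d:
                    problems.append(f"{label} missing mode {m!r}")
                elif d[m] < 0:
                    problems.append(f"{label}[{m}] < 0")
        if (self.km_inout is None) != (self.trips_inout is None):
            problems.append("km_inout and trips_inout must be present together")
        return problems


@dataclass
class CountryRecord:
    """National covariates attached to every city of the country."""

    country_id: str
    gas_price: float     # USD per liter
    gdp_pc: float        # USD per capita per year
    dependency_ratio: float  # dependents per 100 working-age persons

    def validate(self) -> list[str]:
        problems = []
        if self.gas_price < 0:
            problems.append("gas_price < 0")
        if not self.gdp_pc > 0:
            problems.append("gdp_pc must be > 0")
        if self.dependency_ratio < 0:
            problems.append("dependency_ratio < 0")
        return problems


def effective_km(rec: CityRecord, mode: str) -> float:
    """Annual km for ``mode``, counting in/out-bound travel at 50%."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    km = rec.km_within[mode]
    if rec.km_inout is not None:
        km += 0.5 * rec.km_inout[mode]
    return km


def effective_trips(rec: CityRecord, mode: str) -> float:
    """Annual trips for ``mode``, counting in/out-bound trips at 50%."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    t = rec.trips_within[mode]
    if rec.trips_inout is not None:
        t += 0.5 * rec.trips_inout[mode]
    return t


def mode_shares(rec: CityRecord, denominator: str = "regression") -> dict[str, float]:
    """Per-mode km shares of one city under either denominator convention.

    ``regression`` divides by walk + cycle + car/moto effective km (transit
    excluded); ``descriptive`` divides by all four modes. Returns shares for
    the denominator's modes; raises ValueError on an all-zero denominator.
    """
    if denominator == "regression":
        modes = REGRESSION_MODES
    elif denominator == "descriptive":
        modes = MODES
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    km = {m: effective_km(rec, m) for m in modes}
    total = sum(km.values())
    if total <= 0:
        raise ValueError(f"city {rec.city_id!r}: all-zero {denominator} denominator")
    return {m: km[m] / total for m in modes}


def trip_shares(rec: CityRecord, denominator: str = "descriptive") -> dict[str, float]:
    """Per-mode trip shares (analogue of :func:`mode_shares` for trip counts)."""
    modes = MODES if denominator == "descriptive" else REGRESSION_MODES
    trips = {m: effective_trips(rec, m) for m in modes}
    total = sum(trips.values())
    if total <= 0:
        raise ValueError(f"city {rec.city_id!r}: all-zero trip denominator")
    return {m: trips[m] / total for m in modes}


def bikeway_provision(rec: CityRecord) -> float:
    """B: km of bicycle facility per 100 km of road."""
    if rec.road_km <= 0:
        raise ValueError(f"city {rec.city_id!r}: road_km must be > 0 to define B")
    return 100.0 * rec.bikeway_km / rec.road_km


def shrink_boundary(y: np.ndarray, n: int) -> np.ndarray:
    """Pull shares at exactly 0 or 1 into the open interval.

    Applies the sample-size-aware compression y' = (y*(n-1) + 0.5)/n to
    boundary values only; interior values pass through untouched. The beta
    likelihood has open support, so exact 0/1 outcomes must be shrunk
    before fitting.
    """
    y = np.asarray(y, dtype=float)
    out = y.copy()
    at_bound = (y <= 0.0) | (y >= 1.0)
    out[at_bound] = (y[at_bound] * (n - 1) + 0.5) / n
    return out


# ---------------------------------------------------------------------------
# Table I/O


def _records_from_frame(df: pd.DataFrame) -> list[CityRecord]:
    has_inout = all(c in df.columns for c in CITY_INOUT_COLUMNS)
    some_inout = any(c in df.columns for c in CITY_INOUT_COLUMNS)
    if some_inout and not has_inout:
        raise SchemaError("in/out-bound columns must be present as a complete block or absent")

    missing = [c for c in CITY_MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cities table missing mandatory column(s): {missing}")

    dup = df["city_id"].astype(str).duplicated()
    if dup.any():
        raise SchemaError(f"duplicate city_id(s): {sorted(df.loc[dup, 'city_id'].unique())}")

    numeric_cols = [c for c in df.columns if c not in ("city_id", "country_id")]
    for c in numeric_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric value in column {c!r}: {exc}") from None

    records, errors = [], []
    for i, row in df.iterrows():
        km_inout = trips_inout = None
        if has_inout and not row[CITY_INOUT_COLUMNS].isna().any():
            km_inout = {m: float(row[_KM_COLS[m][1]]) for m in MODES}
            trips_inout = {m: float(row[_TRIP_COLS[m][1]]) for m in MODES}
        rec = CityRecord(
            city_id=str(row["city_id"]),
            country_id=str(row["country_id"]),
            population=float(row["population"]),
            km_within={m: float(row[_KM_COLS[m][0]]) for m in MODES},
            trips_within={m: float(row[_TRIP_COLS[m][0]]) for m in MODES},
            km_inout=km_inout,
            trips_inout=trips_inout,
            road_km=float(row["road_km"]),
            bikeway_km=float(row["bikeway_km"]),
            density=float(row["density"]),
            terrain=float(row["terrain"]),
            tmin=float(row["tmin_c"]),
            tmax=float(row["tmax_c"]),
            precip=float(row["precip_mm"]),
        )
        problems = rec.validate()
        if problems:
            errors.append(f"row {i} (city_id={rec.city_id!r}): " + "; ".join(problems))
        else:
            records.append(rec)
    if errors:
        raise SchemaError("invalid city record(s):\n" + "\n".join(errors))
    return records


def read_city_table(path) -> list[CityRecord]:
    """Read and validate a cities.csv file into :class:`CityRecord` objects."""
    return _records_from_frame(pd.read_csv(path, dtype={"city_id": str, "country_id": str}))


def read_country_table(path) -> list[CountryRecord]:
    """Read and validate a countries.csv file."""
    df = pd.read_csv(path, dtype={"country_id": str})
    missing = [c for c in COUNTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"countries table missing mandatory column(s): {missing}")
    dup = df["country_id"].duplicated()
    if dup.any():
        raise SchemaError(f"duplicate country_id(s): {sorted(df.loc[dup, 'country_id'].unique())}")
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            rec = CountryRecord(
                country_id=str(row["country_id"]),
                gas_price=float(row["gas_price_usd_l"]),
                gdp_pc=float(row["gdp_pc_usd"]),
                dependency_ratio=float(row["dependency_ratio"]),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"row {i}: non-numeric value: {exc}") from None
        problems = rec.validate()
        if problems:
            errors.append(f"row {i} (country_id={rec.country_id!r}): " + "; ".join(problems))
        else:
            records.append(rec)
    if errors:
        raise SchemaError("invalid country record(s):\n" + "\n".join(errors))
    return records


def write_city_table(records: list[CityRecord], path) -> None:
    """Write cities to the documented CSV dialect (inout block only if present)."""
    any_inout = any(not r.within_only for r in records)
    rows = []
    for r in records:
        row = {"city_id": r.city_id, "country_id": r.country_id, "population": r.population}
        for m in MODES:
            row[_KM_COLS[m][0]] = r.km_within[m]
        if any_inout:
            for m in MODES:
                row[_KM_COLS[m][1]] = "" if r.km_inout is None else r.km_inout[m]
        for m in MODES:
            row[_TRIP_COLS[m][0]] = r.trips_within[m]
        if any_inout:
            for m in MODES:
                row[_TRIP_COLS[m][1]] = "" if r.trips_inout is None else r.trips_inout[m]
        row.update(road_km=r.road_km, bikeway_km=r.bikeway_km, density=r.density,
                   terrain=r.terrain, tmin_c=r.tmin, tmax_c=r.tmax, precip_mm=r.precip)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_country_table(records: list[CountryRecord], path) -> None:
    pd.DataFrame(
        {"country_id": [r.country_id for r in records],
         "gas_price_usd_l": [r.gas_price for r in records],
         "gdp_pc_usd": [r.gdp_pc for r in records],
         "dependency_ratio": [r.dependency_ratio for r in records]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Design matrix


@dataclass
class DesignMatrix:
    """Standardized covariates for the hierarchical regression.

    ``X`` holds one row per modeled city over ``CITY_COVARIATES``; ``Z`` one
    row per country over ``COUNTRY_COVARIATES``. ``registry`` maps covariate
    name -> (mean, SD) used in standardization, so "one SD" effects can be
    converted back to raw units. City covariates are standardized against
    the pooled city sample; country covariates against the country sample
    (each country counted once). ``tmin2`` is raw tmin squared in °C²,
    standardized after squaring.
    """

    X: np.ndarray                 # (n_cities, 7) standardized
    Z: np.ndarray                 # (n_countries, 3) standardized
    city_ids: list[str]
    country_ids: list[str]        # order defines country index
    country_index: np.ndarray     # (n_cities,) int, row -> country
    registry: dict[str, tuple[float, float]]
    B_raw: np.ndarray             # (n_cities,) unstandardized bikeway provision
    excluded_city_ids: list[str] = field(default_factory=list)

    @property
    def n_cities(self) -> int:
        return self.X.shape[0]

    @property
    def n_countries(self) -> int:
        return self.Z.shape[0]

    def z_gdp(self) -> np.ndarray:
        """Standardized ln GDP per capita per country (the default moderator)."""
        return self.Z[:, COUNTRY_COVARIATES.index("ln_gdp_pc")]

    def unstandardize(self, covariate: str, x_std: np.ndarray) -> np.ndarray:
        mean, sd = self.registry[covariate]
        return np.asarray(x_std) * sd + mean

    def standardize(self, covariate: str, x_raw: np.ndarray) -> np.ndarray:
        mean, sd = self.registry[covariate]
        return (np.asarray(x_raw) - mean) / sd


def _standardize_columns(raw: dict[str, np.ndarray]) -> tuple[np.ndarray, dict]:
    cols, registry = [], {}
    for name, values in raw.items():
        mean = float(np.mean(values))
        sd = float(np.std(values))
        if not sd > 0:
            raise ValueError(f"covariate {name!r} has zero variance; cannot standardize")
        registry[name] = (mean, sd)
        cols.append((values - mean) / sd)
    return np.column_stack(cols), registry


def build_design(cities: list[CityRecord], countries: list[CountryRecord]) -> DesignMatrix:
    """Assemble the standardized design from validated records.

    Cities with road_km = 0 (B undefined) are excluded with a warning and
    listed in ``excluded_city_ids``. Raises on a city whose country_id has
    no matching CountryRecord.
    """
    country_by_id = {c.country_id: c for c in countries}
    orphans = sorted({c.country_id for c in cities} - set(country_by_id))
    if orphans:
        raise SchemaError(f"cities reference unknown country_id(s): {orphans}")

    kept, excluded = [], []
    for c in cities:
        if c.road_km <= 0:
            excluded.append(c.city_id)
        else:
            kept.append(c)
    if excluded:
        logger.warning("excluding %d city(ies) with road_km = 0: %s", len(excluded), excluded)
    if not kept:
        raise ValueError("no cities left after exclusions")

    country_ids = sorted({c.country_id for c in kept})
    cidx = {cid: i for i, cid in enumerate(country_ids)}

    tmin = np.array([c.tmin for c in kept])
    raw_city = {
        "ln_density": np.log([c.density for c in kept]),
        "B": np.array([bikeway_provision(c) for c in kept]),
        "terrain": np.array([c.terrain for c in kept]),
        "tmin": tmin,
        "tmin2": tmin ** 2,   # squared on the raw °C scale, standardized after
        "tmax": np.array([c.tmax for c in kept]),
        "precip": np.array([c.precip for c in kept]),
    }
    X, reg_city = _standardize_columns(raw_city)

    raw_country = {
        "gas_price": np.array([country_by_id[cid].gas_price for cid in country_ids]),
        "ln_gdp_pc": np.log([country_by_id[cid].gdp_pc for cid in country_ids]),
        "dependency_ratio": np.array([country_by_id[cid].dependency_ratio for cid in country_ids]),
    }
    Z, reg_country = _standardize_columns(raw_country)

    return DesignMatrix(
        X=X, Z=Z,
        city_ids=[c.city_id for c in kept],
        country_ids=country_ids,
        country_index=np.array([cidx[c.country_id] for c in kept]),
        registry={**reg_city, **reg_country},
        B_raw=raw_city["B"].copy(),
        excluded_city_ids=excluded,
    )


def regression_shares(cities: list[CityRecord]) -> pd.DataFrame:
    """Walk and cycle regression-denominator km shares, one row per city.

    Cities whose regression denominator is zero are dropped with a warning;
    the result is aligned with the cities that remain.
    """
    rows, dropped = [], []
    for c in cities:
        try:
            s = mode_shares(c, "regression")
        except ValueError:
            dropped.append(c.city_id)
            continue
        rows.append({"city_id": c.city_id, "walk": s["walk"], "cycle": s["cycle"]})
    if dropped:
        logger.warning("dropping %d city(ies) with all-zero regression denominator: %s",
                       len(dropped), dropped)
    if not rows:
        raise ValueError("no cities with a positive regression denominator")
    return pd.DataFrame(rows).set_index("city_id")


# ---------------------------------------------------------------------------
# Descriptive summaries


def aggregate_descriptives(cities: list[CityRecord]) -> dict:
    """Dataset-level pooled mode shares and walk:cycle ratios.

    Pooling sums effective km (and trips) across cities — i.e. city
    contributions are weighted by distance traveled, not averaged as
    shares. The descriptive denominator (transit included) is used.
    """
    if not cities:
        raise ValueError("aggregate_descriptives requires at least one city")
    km = {m: sum(effective_km(c, m) for c in cities) for m in MODES}
    trips = {m: sum(effective_trips(c, m) for c in cities) for m in MODES}
    km_total, trip_total = sum(km.values()), sum(trips.values())
    if km_total <= 0 or trip_total <= 0:
        raise ValueError("pooled denominators must be positive")
    return {
        "km_share": {m: km[m] / km_total for m in MODES},
        "trip_share": {m: trips[m] / trip_total for m in MODES},
        "walk_cycle_km_ratio": km["walk"] / km["cycle"] if km["cycle"] > 0 else math.inf,
        "walk_cycle_trip_ratio": trips["walk"] / trips["cycle"] if trips["cycle"] > 0 else math.inf,
        "total_km": km_total,
        "total_trips": trip_total,
    }


def prepare_model_inputs(
    cities: list[CityRecord], countries: list[CountryRecord]
) -> tuple[DesignMatrix, dict[str, np.ndarray], list[CityRecord]]:
    """Filter, standardize and align everything the model fit needs.

    Drops cities with road_km = 0 (bikeway provision undefined) or an
    all-zero regression denominator (beta likelihood undefined), builds
    the design on the remaining cities, computes walk and cycle regression
    shares row-aligned with it, and shrinks boundary shares away from 0/1.
    Returns (design, {"walk": y, "cycle": y}, modeled_cities).
    """
    modeled, dropped = [], []
    for c in cities:
        if c.road_km <= 0:
            dropped.append((c.city_id, "road_km = 0"))
            continue
        try:
            mode_shares(c, "regression")
        except ValueError:
            dropped.append((c.city_id, "all-zero regression denominator"))
            continue
        modeled.append(c)
    if dropped:
        logger.warning("excluding %d city(ies) from model fitting: %s",
                       len(dropped), dropped[:10])
    if not modeled:
        raise ValueError("no modelable cities")
    design = build_design(modeled, countries)
    n = len(modeled)
    shares = {}
    for outcome in ACTIVE_MODES:
        y = np.array([mode_shares(c, "regression")[outcome] for c in modeled])
        shares[outcome] = shrink_boundary(y, n)
    return design, shares, modeled


def urban_coverage(dataset_population: float, world_urban_population: float) -> float:
    """Percent of the world's urban population covered by the dataset."""
    if world_urban_population <= 0:
        raise ValueError("world_urban_population must be > 0")
    return 100.0 * dataset_population / world_urban_population
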