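import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from activetravel import schema
from activetravel.schema import (
    CityRecord,
    SchemaError,
    aggregate_descriptives,
    build_design,
    effective_km,
    mode_shares,
    read_city_table,
    read_country_table,
    shrink_boundary,
    urban_coverage,
    write_city_table,
    write_country_table,
)
from activetravel.simulate import PRESETS, generate_dataset


def make_city(city_id="x", country_id="AA", km=None, km_inout=None, **kw):
    km = km or {"walk": 10.0, "cycle": 5.0, "car_moto": 80.0, "transit": 20.0}
    trips = {m: v / 2.0 for m, v in km.items()}
    defaults = dict(population=1e5, road_km=200.0, bikeway_km=10.0, density=3000.0,
                    terrain=0.5, tmin=2.0, tmax=25.0, precip=900.0)
    defaults.update(kw)
    return CityRecord(
        city_id=city_id, country_id=country_id,
        km_within=km, trips_within=trips,
        km_inout=km_inout,
        trips_inout=None if km_inout is None else {m: v / 2.0 for m, v in km_inout.items()},
        **defaults,
    )


class TestEffectiveKm:
    def test_half_of_inout_is_counted(self):
        rec = make_city(km={"walk": 10, "cycle": 0, "car_moto": 0, "transit": 0},
                        km_inout={"walk": 4, "cycle": 0, "car_moto": 0, "transit": 0})
        assert effective_km(rec, "walk") == 12.0

    def test_within_only_record(self):
        rec = make_city(km={"walk": 10, "cycle": 0, "car_moto": 0, "transit": 0})
        assert effective_km(rec, "walk") == 10.0
        assert effective_km(rec, "cycle") == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            effective_km(make_city(), "teleport")

    @given(st.floats(0, 1e9), st.floats(0, 1e9), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_linearity_under_scaling(self, within, inout, c):
        km = {"walk": within, "cycle": 0.0, "car_moto": 0.0, "transit": 0.0}
        io = {"walk": inout, "cycle": 0.0, "car_moto": 0.0, "transit": 0.0}
        base = effective_km(make_city(km=km, km_inout=io), "walk")
        scaled = effective_km(
            make_city(km={m: c * v for m, v in km.items()},
                      km_inout={m: c * v for m, v in io.items()}), "walk")
        assert scaled == pytest.approx(c * base, rel=1e-12)


class TestModeShares:
    def test_regression_excludes_transit(self):
        rec = make_city(km={"walk": 2, "cycle": 1, "car_moto": 7, "transit": 10})
        s = mode_shares(rec, "regression")
        assert s["walk"] == pytest.approx(0.2)
        assert s["cycle"] == pytest.approx(0.1)

    def test_descriptive_includes_transit(self):
        rec = make_city(km={"walk": 2, "cycle": 1, "car_moto": 7, "transit": 10})
        s = mode_shares(rec, "descriptive")
        assert s["walk"] == pytest.approx(0.1)

    def test_zero_numerators(self):
        rec = make_city(km={"walk": 0, "cycle": 0, "car_moto": 5, "transit": 0})
        s = mode_shares(rec, "regression")
        assert s["walk"] == 0.0 and s["cycle"] == 0.0

    def test_all_zero_denominator_raises(self):
        rec = make_city(km={"walk": 0, "cycle": 0, "car_moto": 0, "transit": 10})
        with pytest.raises(ValueError, match="all-zero"):
            mode_shares(rec, "regression")

    @given(st.lists(st.floats(0.01, 1e6), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_shares_sum_to_one_and_transit_exclusion_never_decreases(self, kms):
        km = dict(zip(("walk", "cycle", "car_moto", "transit"), kms))
        rec = make_city(km=km)
        for denom, modes in (("regression", schema.REGRESSION_MODES),
                             ("descriptive", schema.MODES)):
            s = mode_shares(rec, denom)
            assert sum(s[m] for m in modes) == pytest.approx(1.0, abs=1e-9)
        reg, desc = mode_shares(rec, "regression"), mode_shares(rec, "descriptive")
        for m in ("walk", "cycle"):
            assert reg[m] >= desc[m]


class TestShrinkBoundary:
    def test_interior_untouched_boundary_compressed(self):
        y = shrink_boundary(np.array([0.0, 0.3, 1.0]), n=100)
        assert y[1] == 0.3
        assert y[0] == pytest.approx(0.5 / 100)
        assert y[2] == pytest.approx((99 + 0.5) / 100)
        assert np.all((y > 0) & (y < 1))


class TestTableIO:
    def test_round_trip(self, tmp_path, tiny_dataset):
        cities, countries, _ = tiny_dataset
        write_city_table(cities, tmp_path / "c.csv")
        write_country_table(countries, tmp_path / "n.csv")
        back = read_city_table(tmp_path / "c.csv")
        assert len(back) == len(cities)
        for a, b in zip(cities, back):
            assert a.city_id == b.city_id
            assert a.km_within["walk"] == pytest.approx(b.km_within["walk"])
            assert a.within_only == b.within_only
        nback = read_country_table(tmp_path / "n.csv")
        assert [c.country_id for c in nback] == [c.country_id for c in countries]

    def test_density_zero_names_row_and_field(self, tmp_path, tiny_dataset):
        cities, _, _ = tiny_dataset
        bad = [make_city("a"), make_city("b", density=0.0), make_city("c")]
        write_city_table(bad, tmp_path / "bad.csv")
        with pytest.raises(SchemaError, match=r"row 1.*density"):
            read_city_table(tmp_path / "bad.csv")

    def test_missing_inout_block_is_legal(self, tmp_path):
        write_city_table([make_city("a"), make_city("b")], tmp_path / "c.csv")
        recs = read_city_table(tmp_path / "c.csv")
        assert all(r.within_only for r in recs)

    def test_duplicate_city_id_rejected(self, tmp_path):
        write_city_table([make_city("a"), make_city("a")], tmp_path / "c.csv")
        with pytest.raises(SchemaError, match="duplicate"):
            read_city_table(tmp_path / "c.csv")

    def test_missing_mandatory_column(self, tmp_path):
        import pandas as pd
        write_city_table([make_city("a")], tmp_path / "c.csv")
        df = pd.read_csv(tmp_path / "c.csv").drop(columns=["density"])
        df.to_csv(tmp_path / "c2.csv", index=False)
        with pytest.raises(SchemaError, match="density"):
            read_city_table(tmp_path / "c2.csv")

    def test_non_numeric_cell_names_column(self, tmp_path):
        import pandas as pd
        write_city_table([make_city("a")], tmp_path / "c.csv")
        df = pd.read_csv(tmp_path / "c.csv")
        df.loc[0, "road_km"] = "many"
        df.to_csv(tmp_path / "c2.csv", index=False)
        with pytest.raises(SchemaError, match="road_km"):
            read_city_table(tmp_path / "c2.csv")


class TestBuildDesign:
    def _countries(self):
        from activetravel.schema import CountryRecord
        return [CountryRecord("AA", 1.0, 20000.0, 50.0),
                CountryRecord("BB", 1.5, 40000.0, 60.0)]

    def test_two_point_standardization_of_ln_density(self):
        cities = [make_city("a", "AA", density=math.e ** 1, bikeway_km=5.0,
                            terrain=0.1, tmin=1.0, tmax=20.0, precip=800.0),
                  make_city("b", "BB", density=math.e ** 3, bikeway_km=20.0,
                            terrain=0.9, tmin=4.0, tmax=30.0, precip=1200.0)]
        d = build_design(cities, self._countries())
        # ln-densities {1, 3}: mean 2, population SD 1 -> standardized -1, +1
        assert d.X[:, 0] == pytest.approx([-1.0, 1.0])

    def test_bikeway_provision_definition(self):
        rec = make_city(bikeway_km=10.0, road_km=200.0)
        assert schema.bikeway_provision(rec) == pytest.approx(5.0)

    def test_registry_round_trip(self, small_dataset):
        cities, countries, _ = small_dataset
        d = build_design(cities, countries)
        for i, k in enumerate(schema.CITY_COVARIATES):
            raw = d.unstandardize(k, d.X[:, i])
            assert np.allclose(d.standardize(k, raw), d.X[:, i], atol=1e-9)
        assert np.allclose(d.unstandardize("B", d.standardize("B", d.B_raw)), d.B_raw)

    def test_columns_standardized(self, small_dataset):
        cities, countries, _ = small_dataset
        d = build_design(cities, countries)
        assert np.allclose(d.X.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(d.X.std(axis=0), 1.0, atol=1e-8)
        assert np.allclose(d.Z.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(d.Z.std(axis=0), 1.0, atol=1e-8)

    def test_tmin2_is_square_of_raw_tmin(self, small_dataset):
        cities, countries, _ = small_dataset
        d = build_design(cities, countries)
        i, i2 = schema.CITY_COVARIATES.index("tmin"), schema.CITY_COVARIATES.index("tmin2")
        raw_t = d.unstandardize("tmin", d.X[:, i])
        raw_t2 = d.unstandardize("tmin2", d.X[:, i2])
        assert np.allclose(raw_t2, raw_t ** 2, rtol=1e-9)

    def test_orphan_country_rejected(self):
        with pytest.raises(SchemaError, match="unknown country_id"):
            build_design([make_city("a", "ZZ")], self._countries())

    def test_zero_road_km_excluded_with_warning(self):
        cities = [make_city("a", "AA", density=1000.0, bikeway_km=2.0, terrain=0.2,
                            tmin=0.0, tmax=18.0, precip=500.0),
                  make_city("b", "BB", road_km=0.0),
                  make_city("c", "BB", density=8000.0, bikeway_km=30.0, terrain=1.4,
                            tmin=6.0, tmax=33.0, precip=1500.0)]
        d = build_design(cities, self._countries())
        assert d.excluded_city_ids == ["b"]
        assert d.n_cities == 2


class TestAggregateDescriptives:
    def test_single_city_pooling_is_identity(self):
        rec = make_city()
        agg = aggregate_descriptives([rec])
        s = mode_shares(rec, "descriptive")
        for m in schema.MODES:
            assert agg["km_share"][m] == pytest.approx(s[m])

    def test_equal_denominator_pooling_averages(self):
        a = make_city("a", km={"walk": 10, "cycle": 10, "car_moto": 80, "transit": 0})
        b = make_city("b", km={"walk": 30, "cycle": 10, "car_moto": 60, "transit": 0})
        agg = aggregate_descriptives([a, b])
        assert agg["km_share"]["walk"] == pytest.approx(0.2)

    def test_constructed_km_ratio(self):
        rec = make_city(km={"walk": 2.3, "cycle": 1.0, "car_moto": 5.0, "transit": 1.0})
        assert aggregate_descriptives([rec])["walk_cycle_km_ratio"] == pytest.approx(2.3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_descriptives([])


class TestUrbanCoverage:
    def test_reported_dataset_coverage(self):
        assert round(urban_coverage(1.881e9, 4.60e9)) == 41

    def test_edge_cases(self):
        assert urban_coverage(5, 5) == 100.0
        assert urban_coverage(0, 5) == 0.0
        with pytest.raises(ValueError):
            urban_coverage(1, 0)
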