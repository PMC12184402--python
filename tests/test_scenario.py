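import numpy as np
import pytest
from scipy.special import expit

from activetravel.scenario import (
    COPENHAGEN_B,
    ScenarioConfig,
    _baseline_volumes,
    apply_floor,
    displace_and_account,
    percentile95_floor,
    required_construction,
    shift_shares,
    sweep,
)
from activetravel.schema import CITY_COVARIATES, prepare_model_inputs

from conftest import manual_draws
from test_schema import make_city


class TestApplyFloor:
    def test_city_above_floor_unchanged(self):
        assert apply_floor(50.0, COPENHAGEN_B) == 50.0

    def test_city_below_floor_raised(self):
        assert apply_floor(10.0, COPENHAGEN_B) == COPENHAGEN_B

    def test_boundary_and_idempotence(self):
        assert apply_floor(COPENHAGEN_B, COPENHAGEN_B) == COPENHAGEN_B
        once = apply_floor(np.array([5.0, 60.0]), 44.3)
        assert np.array_equal(apply_floor(once, 44.3), once)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            apply_floor(-1.0, 10.0)


class TestRequiredConstruction:
    def test_single_city_arithmetic(self):
        city = make_city(road_km=200.0, bikeway_km=10.0)
        assert required_construction([city], 44.3) == pytest.approx(0.443 * 200 - 10)

    def test_city_above_floor_contributes_zero(self):
        city = make_city(road_km=100.0, bikeway_km=60.0)
        assert required_construction([city], 44.3) == 0.0

    def test_zero_floor_costs_nothing(self):
        assert required_construction([make_city()], 0.0) == 0.0


def _scenario_inputs(small_fit):
    return (small_fit["draws"]["walk"], small_fit["draws"]["cycle"],
            small_fit["design"], small_fit["modeled"])


class TestShiftShares:
    def test_floor_below_minimum_provision_changes_nothing(self, small_fit):
        walk, _, design, _ = _scenario_inputs(small_fit)
        # a floor at or below every city's provision leaves every share alone
        floor = float(design.B_raw.min()) * 0.5
        delta = shift_shares(walk, design, floor)
        assert np.all(delta == 0.0)

    def test_zero_b_slope_gives_zero_delta(self, small_fit):
        design = small_fit["design"]
        beta = np.zeros((1, design.n_countries, 7))
        d = manual_draws(beta=beta)
        d.country_ids = list(design.country_ids)
        d.registry = dict(design.registry)
        assert np.all(shift_shares(d, design, 50.0) == 0.0)

    def test_single_city_hand_computed_delta(self, small_fit):
        design = small_fit["design"]
        kB = CITY_COVARIATES.index("B")
        beta = np.zeros((1, design.n_countries, 7))
        beta[0, :, kB] = 0.25
        d = manual_draws(beta=beta)
        d.country_ids = list(design.country_ids)
        d.registry = dict(design.registry)
        B_star = 30.0
        delta = shift_shares(d, design, B_star)
        i = int(np.argmin(design.B_raw))   # a city certainly below the floor
        mean_B, sd_B = design.registry["B"]
        x_f = (design.B_raw[i] - mean_B) / sd_B
        x_c = (max(design.B_raw[i], B_star) - mean_B) / sd_B
        # remaining covariates contribute 0 because all other slopes are zero
        expected = expit(0.25 * x_c) - expit(0.25 * x_f)
        assert delta[0, i] == pytest.approx(expected, abs=1e-12)

    def test_cities_at_or_above_floor_exactly_zero(self, small_fit):
        walk, _, design, _ = _scenario_inputs(small_fit)
        B_star = float(np.median(design.B_raw))
        delta = shift_shares(walk, design, B_star)
        above = design.B_raw >= B_star
        assert np.all(delta[:, above] == 0.0)
        assert np.any(delta[:, ~above] != 0.0)


class TestDisplaceAndAccount:
    def _baseline(self):
        from activetravel.scenario import _Baseline
        return _Baseline(nontransit_km=np.array([300.0]),
                         car_km=np.array([300.0]),
                         transit_km=np.array([100.0]))

    def test_proportional_split_across_motorized_modes(self):
        from activetravel.scenario import _Baseline
        base = _Baseline(nontransit_km=np.array([1000.0]),
                         car_km=np.array([300.0]), transit_km=np.array([100.0]))
        # added active travel 100 km: delta share 0.1 of 1000 km... use walk only
        acc = displace_and_account(np.array([[0.1]]), np.array([[0.0]]),
                                   base, ScenarioConfig(B_grid=(1.0,)))
        assert acc["displaced_km"][0] == pytest.approx(100.0)
        assert acc["displaced_car_km"][0] == pytest.approx(75.0)
        assert acc["displaced_transit_km"][0] == pytest.approx(25.0)

    def test_zero_health_multipliers(self):
        base = self._baseline()
        cfg = ScenarioConfig(B_grid=(1.0,), health_usd_per_km_walk=0.0,
                             health_usd_per_km_cycle=0.0)
        acc = displace_and_account(np.array([[0.05]]), np.array([[0.02]]), base, cfg)
        assert acc["health_usd"][0] == 0.0

    def test_all_car_city_closed_form_percent(self):
        # one-city world, all non-active travel by car: percent CO2 reduction
        # equals 100 * added_active_km / baseline_car_km
        from activetravel.scenario import _Baseline
        base = _Baseline(nontransit_km=np.array([500.0]),
                         car_km=np.array([480.0]), transit_km=np.array([0.0]))
        acc = displace_and_account(np.array([[0.1]]), np.array([[0.0]]),
                                   base, ScenarioConfig(B_grid=(1.0,)))
        assert acc["co2_pct"][0] == pytest.approx(100 * 50.0 / 480.0)

    def test_conservation_before_capping(self):
        rng = np.random.default_rng(0)
        from activetravel.scenario import _Baseline
        n = 20
        base = _Baseline(nontransit_km=rng.uniform(100, 1000, n),
                         car_km=rng.uniform(100, 800, n),
                         transit_km=rng.uniform(0, 300, n))
        dw, dc = rng.uniform(0, 0.01, (3, n)), rng.uniform(0, 0.005, (3, n))
        cfg = ScenarioConfig(B_grid=(1.0,), d_walk=1.7, d_cycle=0.8)
        acc = displace_and_account(dw, dc, base, cfg)
        expected = (cfg.d_walk * (dw * base.nontransit_km).sum(axis=1)
                    + cfg.d_cycle * (dc * base.nontransit_km).sum(axis=1))
        assert acc["n_capped"] == 0
        assert np.allclose(acc["displaced_km"], expected, rtol=1e-12)

    def test_capping_reduces_displacement(self):
        from activetravel.scenario import _Baseline
        base = _Baseline(nontransit_km=np.array([1000.0]),
                         car_km=np.array([10.0]), transit_km=np.array([0.0]))
        acc = displace_and_account(np.array([[0.5]]), np.array([[0.0]]),
                                   base, ScenarioConfig(B_grid=(1.0,)))
        assert acc["n_capped"] == 1
        assert acc["displaced_km"][0] == pytest.approx(10.0)

    def test_zero_emission_factor_zeroes_co2_not_health(self):
        base = self._baseline()
        cfg = ScenarioConfig(B_grid=(1.0,), emission_factor_g_km=0.0)
        acc = displace_and_account(np.array([[0.1]]), np.array([[0.0]]), base, cfg)
        assert acc["co2_tonnes"][0] == 0.0
        assert acc["health_usd"][0] > 0.0

    def test_zero_displacement_keeps_health(self):
        base = self._baseline()
        cfg = ScenarioConfig(B_grid=(1.0,), d_walk=0.0, d_cycle=0.0)
        acc = displace_and_account(np.array([[0.1]]), np.array([[0.0]]), base, cfg)
        assert acc["displaced_km"][0] == 0.0
        assert acc["co2_tonnes"][0] == 0.0
        assert acc["health_usd"][0] > 0.0


class TestSweep:
    def test_zero_floor_row_is_all_zero(self, small_fit):
        walk, cycle, design, modeled = _scenario_inputs(small_fit)
        res = sweep(walk, cycle, design, modeled, ScenarioConfig(B_grid=(0.0,)))
        assert res.loc[0, "dkm_walk_mean"] == 0.0
        assert res.loc[0, "co2_pct_mean"] == 0.0
        assert res.loc[0, "new_bikeway_km"] == 0.0

    def test_monotone_in_floor_with_positive_slopes(self, small_fit):
        """With uniformly positive bikeway slopes, every aggregate grows
        (weakly) along the floor grid."""
        design = small_fit["design"]
        rng = np.random.default_rng(5)
        kB = CITY_COVARIATES.index("B")
        def positive_draws(outcome):
            beta = np.zeros((40, design.n_countries, 7))
            beta[:, :, kB] = rng.uniform(0.05, 0.3, (40, design.n_countries))
            d = manual_draws(beta=beta, alpha=np.full((40, design.n_countries), -2.0),
                             outcome=outcome)
            d.country_ids = list(design.country_ids)
            d.registry = dict(design.registry)
            return d
        cfg = ScenarioConfig(B_grid=tuple(float(b) for b in range(1, 51)))
        res = sweep(positive_draws("walk"), positive_draws("cycle"),
                    design, small_fit["modeled"], cfg)
        for col in ("dkm_walk_mean", "dkm_cycle_mean", "co2_pct_mean",
                    "health_usd_mean", "new_bikeway_km"):
            assert np.all(np.diff(res[col]) >= -1e-9), col

    def test_single_draw_interval_collapses(self, small_fit):
        walk, cycle, design, modeled = _scenario_inputs(small_fit)
        cfg = ScenarioConfig(B_grid=(COPENHAGEN_B,), n_draws=1, seed=3)
        res = sweep(walk, cycle, design, modeled, cfg)
        assert res.loc[0, "co2_pct_lo"] == pytest.approx(res.loc[0, "co2_pct_mean"])
        assert res.loc[0, "co2_pct_hi"] == pytest.approx(res.loc[0, "co2_pct_mean"])

    def test_city_order_invariance(self, small_fit):
        walk, cycle, design, modeled = _scenario_inputs(small_fit)
        cfg = ScenarioConfig(B_grid=(20.0,))
        a = sweep(walk, cycle, design, modeled, cfg)
        b = sweep(walk, cycle, design, modeled[::-1], cfg)
        assert np.allclose(a["co2_pct_mean"], b["co2_pct_mean"])

    def test_uncertainty_interval_brackets_mean(self, small_fit):
        walk, cycle, design, modeled = _scenario_inputs(small_fit)
        res = sweep(walk, cycle, design, modeled,
                    ScenarioConfig(B_grid=(10.0, COPENHAGEN_B)))
        for q in ("dkm_walk", "dkm_cycle", "co2_pct", "health_usd"):
            assert np.all(res[f"{q}_lo"] <= res[f"{q}_mean"] + 1e-9)
            assert np.all(res[f"{q}_mean"] <= res[f"{q}_hi"] + 1e-9)

    def test_percentile95_floor_is_within_observed_range(self, small_fit):
        design = small_fit["design"]
        p95 = percentile95_floor(design)
        assert design.B_raw.min() <= p95 <= design.B_raw.max()
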