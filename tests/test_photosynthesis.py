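"""CO2–water coupling of the C3/C4 assimilation scheme."""

import numpy as np
import pytest

from veld import photosynthesis as ps


def brute_force_conductance(gcmax, supply, n=20_001):
    """Pure grid-scan inversion of the demand curve (no algebra).

    Coarse scan over [0, gcmax], then a rescan of the bracketing
    interval, giving ~1e-8 relative resolution.
    """
    grid = np.linspace(0.0, gcmax, n)
    i = np.argmin(np.abs(ps.transpiration_demand(grid) - supply))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n - 1)]
    fine = np.linspace(lo, hi, n)
    return fine[np.argmin(np.abs(ps.transpiration_demand(fine) - supply))]


class TestGrossAssimilation:
    def test_zero_light_zero_assimilation(self):
        for p in (ps.C3, ps.C4):
            assert ps.gross_assimilation(p, 25.0, 0.0, 360.0) == 0.0

    def test_zero_outside_temperature_range(self):
        assert ps.gross_assimilation(ps.C4, 0.0, 40.0, 360.0) == 0.0
        assert ps.gross_assimilation(ps.C3, 50.0, 40.0, 360.0) == 0.0

    def test_c3_strictly_increasing_in_co2(self):
        cas = np.arange(150.0, 401.0, 25.0)
        a = [ps.gross_assimilation(ps.C3, 25.0, 40.0, ca) for ca in cas]
        assert np.all(np.diff(a) > 0)

    def test_c4_less_co2_sensitive_than_c3(self):
        """Relative assimilation gain from 150->250 ppm is larger for C3."""
        gain = {}
        for p in (ps.C3, ps.C4):
            lo = ps.gross_assimilation(p, 25.0, 40.0, 150.0)
            hi = ps.gross_assimilation(p, 25.0, 40.0, 250.0)
            gain[p.pathway] = (hi - lo) / lo
        assert gain["C3"] > 2 * gain["C4"]

    def test_invalid_co2_rejected(self):
        with pytest.raises(ValueError):
            ps.gross_assimilation(ps.C3, 25.0, 40.0, 0.0)


class TestGcMax:
    def test_floor_at_minimum_conductance(self):
        assert ps.gc_max(0.0, 360.0, ps.C3) == pytest.approx(ps.C3.gmin)

    def test_strictly_decreasing_in_co2(self):
        g = [ps.gc_max(8.0, ca, ps.C3) for ca in (250.0, 300.0, 350.0)]
        assert g[0] > g[1] > g[2]

    def test_c4_needs_less_conductance_at_equal_assimilation(self):
        # 1 - lambda is larger for C4, so the same Amax costs less water
        assert ps.gc_max(8.0, 250.0, ps.C4) < ps.gc_max(8.0, 250.0, ps.C3)

    def test_lambda_validation(self):
        with pytest.raises(ValueError):
            ps.PathwayParams("C3", lambda_opt=1.0, b_resp=0.01, alpha=0.04,
                             vmax25=60.0, k_co2=450.0, t_low=4.0, t_high=36.0,
                             t_min_photo=-4.0, t_max_photo=45.0)


class TestWaterLimitedConductance:
    def test_unstressed_identity(self):
        gc, f = ps.water_limited_conductance(3.0, ps.transpiration_demand(3.0), 6.0)
        assert gc == pytest.approx(3.0) and f == pytest.approx(1.0)

    def test_zero_supply_closes_stomata(self):
        gc, f = ps.water_limited_conductance(3.0, 4.0, 0.0)
        assert gc == 0.0 and f == 0.0

    def test_continuity_at_stress_onset(self):
        gcmax = 4.0
        d = ps.transpiration_demand(gcmax)
        below = ps.water_limited_conductance(gcmax, d, d - 1e-9)[0]
        above = ps.water_limited_conductance(gcmax, d, d + 1e-9)[0]
        assert below == pytest.approx(above, abs=1e-5)

    def test_root_matches_brute_force_grid_search(self):
        """Closed-form inversion vs two-stage dense scan (independent oracle)."""
        for gcmax in (2.0, 5.0, 9.0):
            d_pot = ps.transpiration_demand(gcmax)
            s = d_pot / 2.0
            gc, _ = ps.water_limited_conductance(gcmax, d_pot, s)
            gc_scan = brute_force_conductance(gcmax, s)
            assert gc == pytest.approx(gc_scan, rel=1e-6)
            assert ps.transpiration_demand(gc) == pytest.approx(s, rel=1e-9)


class TestDailyGpp:
    def test_wet_soil_equals_unstressed(self):
        a = ps.gross_assimilation(ps.C4, 30.0, 40.0, 360.0)
        rd = ps.leaf_respiration(ps.C4, 30.0)
        assert ps.daily_gpp(ps.C4, 30.0, 40.0, 1.0, 360.0) == pytest.approx(a - rd)

    @pytest.mark.parametrize("p", [ps.C3, ps.C4], ids=["C3", "C4"])
    def test_fertilization_under_drought(self, p):
        assert ps.daily_gpp(p, 28.0, 40.0, 0.3, 250.0) > ps.daily_gpp(p, 28.0, 40.0, 0.3, 150.0)

    def test_c4_outyields_c3_at_30C_present_day(self):
        g4 = ps.daily_gpp(ps.C4, 30.0, 40.0, 1.0, 360.0)
        g3 = ps.daily_gpp(ps.C3, 30.0, 40.0, 1.0, 360.0)
        assert g4 / g3 > 1.0

    def test_non_negative_everywhere(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t, par, sf, ca = rng.uniform(-10, 50), rng.uniform(0, 60), rng.uniform(0, 1), rng.uniform(120, 900)
            for p in (ps.C3, ps.C4):
                assert ps.daily_gpp(p, t, par, sf, ca) >= 0.0


class TestCrossover:
    def test_present_day_wet_crossover_near_20C(self):
        assert ps.crossover_temperature(360.0, 1.0) == pytest.approx(20.0, abs=2.0)

    def test_strict_ordering_in_co2(self):
        t150 = ps.crossover_temperature(150.0, 1.0)
        t250 = ps.crossover_temperature(250.0, 1.0)
        t360 = ps.crossover_temperature(360.0, 1.0)
        assert t150 < t250 < t360

    def test_drying_lowers_crossover(self):
        assert ps.crossover_temperature(360.0, 0.3) < ps.crossover_temperature(360.0, 1.0)

    def test_c4_advantage_region_expands_with_drying(self):
        ts = [ps.crossover_temperature(360.0, sf) for sf in (1.0, 0.7, 0.4, 0.2)]
        assert np.all(np.diff(ts) <= 0)

    def test_co2_loss_asymmetry_over_warm_range(self):
        """Dropping 250->150 ppm costs C3 relatively more GPP than C4."""
        for t in np.arange(20.0, 35.1, 2.5):
            loss = {}
            for p in (ps.C3, ps.C4):
                hi = ps.daily_gpp(p, t, 40.0, 1.0, 250.0)
                lo = ps.daily_gpp(p, t, 40.0, 1.0, 150.0)
                loss[p.pathway] = (hi - lo) / hi
            assert loss["C3"] > loss["C4"]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ps.crossover_temperature(50.0, 1.0)
        with pytest.raises(ValueError):
            ps.crossover_temperature(360.0, 0.0)
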