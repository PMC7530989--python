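"""Factorial orchestration, spin-up behaviour and analysis products."""

import numpy as np
import pytest

from veld import vegetation as vg
from veld.experiments import (ExperimentConfig, c4_boundary, climate_space_binning,
                              difference_map, fire_sensitivity_stat, run_factorial,
                              run_single, spin_up, synthetic_cell)


class TestExperimentConfig:
    def test_default_factorial_size(self):
        assert sum(1 for _ in ExperimentConfig().labels()) == 16

    def test_single_member(self):
        cfg = ExperimentConfig(co2_levels=(250.0,), fire=(False,), variants=("A",))
        assert sum(1 for _ in cfg.labels()) == 1

    def test_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig(spinup_years=0)
        with pytest.raises(ValueError):
            ExperimentConfig(co2_levels=(50.0,))


class TestSpinUp:
    def test_wet_warm_cell_converges_quickly(self):
        grid = synthetic_cell(t_coldest=18.0, map_total=900.0)
        res = spin_up(grid, fire_on=False, co2=250.0)
        assert res.converged.all()
        assert res.years_run < 200

    def test_zero_precipitation_stays_bare(self):
        grid = synthetic_cell(t_coldest=18.0, map_total=0.0)
        res = spin_up(grid, fire_on=False, co2=250.0)
        assert res.state.established_fpc().max() == pytest.approx(0.0, abs=1e-9)

    def test_deterministic(self):
        grid = synthetic_cell(t_coldest=18.0, map_total=600.0)
        a = spin_up(grid, fire_on=True, co2=150.0).state
        b = spin_up(grid, fire_on=True, co2=150.0).state
        assert np.array_equal(a.biomass, b.biomass)

    def test_doubling_spinup_changes_little(self):
        """Desk-scale spin-up adequacy: equilibrium reached well within budget."""
        grid = synthetic_cell(t_coldest=18.0, map_total=700.0)
        f1 = spin_up(grid, False, 250.0, ExperimentConfig(spinup_years=200)).state.fpc
        f2 = spin_up(grid, False, 250.0, ExperimentConfig(spinup_years=400)).state.fpc
        assert np.abs(f1 - f2).max() < 0.01


class TestFactorial(object):
    def test_library_labels_and_shapes(self, coarse_factorial):
        cfg, runs = coarse_factorial
        assert len(runs) == 16
        for label, run in runs.items():
            assert run.label == label
            assert run.fpc.shape == (3, 5, 5)
            assert np.all((run.fpc >= 0) & (run.fpc <= 1))

    def test_missing_variant_grid_rejected(self, coarse_factorial):
        cfg, _ = coarse_factorial
        with pytest.raises(ValueError):
            run_factorial(cfg, grids={})

    def test_low_co2_expands_c4_in_warm_summer_cells(self, coarse_factorial):
        _, runs = coarse_factorial
        lo = runs["co2150_fireoff_A"]
        hi = runs["co2250_fireoff_A"]
        s = lo.summaries
        warm = (s.mat > 18) & np.isin(s.phase_month, (11, 12, 1, 2, 3))
        both = warm & ~np.isnan(lo.grass_share_c4) & ~np.isnan(hi.grass_share_c4)
        assert both.sum() >= 3
        assert np.all(lo.grass_share_c4[both] >= hi.grass_share_c4[both] - 1e-9)

    def test_c3_only_where_c4_filtered(self, coarse_factorial):
        _, runs = coarse_factorial
        for run in runs.values():
            cold = run.summaries.t_coldest < 15.5
            assert np.all(run.fpc[vg.C4G][cold] == 0.0)
            share = run.grass_share_c4[cold]
            grassy = ~np.isnan(share)
            if grassy.any():
                assert np.all(share[grassy] == pytest.approx(0.0, abs=1e-12))


class TestDifferenceMap:
    def test_self_difference_is_zero(self, coarse_factorial):
        _, runs = coarse_factorial
        r = runs["co2150_fireon_A"]
        diff, stats = difference_map(r, r)
        assert np.all(diff == 0.0)
        assert stats["C4_grass"]["mean"] == 0.0

    def test_antisymmetry(self, coarse_factorial):
        _, runs = coarse_factorial
        a, b = runs["co2150_fireon_A"], runs["co2250_fireon_A"]
        dab, _ = difference_map(a, b)
        dba, _ = difference_map(b, a)
        assert np.allclose(dab, -dba)

    def test_c4_gains_where_low_co2_removes_trees(self, coarse_factorial):
        """Low CO2 thins tree cover, and C4 grass takes the freed space."""
        _, runs = coarse_factorial
        a, b = runs["co2150_fireon_A"], runs["co2250_fireon_A"]
        diff, _ = difference_map(a, b)
        warm = a.summaries.mat > 18
        retreat = warm & (diff[vg.TREE] < -0.05)
        assert retreat.any()
        assert diff[vg.C4G][retreat].mean() > 0


class TestClimateSpaceBinning:
    def test_single_cell_bin_carries_its_value(self):
        grid = synthetic_cell(t_coldest=18.0, map_total=700.0)
        cfg = ExperimentConfig(spinup_years=120, run_years=10)
        run = run_single(grid, 150.0, False, "one", cfg)
        summary = climate_space_binning(run)
        assert len(summary.mat_map) == 1
        assert summary.mat_map["c4_fpc"].iloc[0] == pytest.approx(run.fpc[vg.C4G, 0, 0])
        assert summary.mat_map["n"].iloc[0] == 1

    def test_c4_dominated_cell_share_is_one(self):
        grid = synthetic_cell(t_coldest=18.0, map_total=700.0)
        cfg = ExperimentConfig(spinup_years=120, run_years=10)
        run = run_single(grid, 150.0, False, "one", cfg)
        assert run.grass_share_c4[0, 0] == pytest.approx(1.0)
        assert climate_space_binning(run).polar["c4_share"].iloc[0] == pytest.approx(1.0)

    def test_boundary_requires_valid_axis(self, coarse_factorial):
        _, runs = coarse_factorial
        with pytest.raises(ValueError):
            c4_boundary(list(runs.values()), "elevation")


class TestFireSensitivity:
    def test_identical_runs_give_zero(self, coarse_factorial):
        import dataclasses
        _, runs = coarse_factorial
        r_on = runs["co2150_fireon_A"]
        ghost_off = dataclasses.replace(r_on, fire_on=False)   # same fields, off label
        st = fire_sensitivity_stat({"a": r_on, "b": ghost_off})
        assert st["n_pairs"] == 1
        assert st["mean_abs_dtree_fpc"] == 0.0
        assert st["mean_abs_dc3_share"] == 0.0

    def test_unmatched_library_rejected(self, coarse_factorial):
        _, runs = coarse_factorial
        only_on = {k: v for k, v in runs.items() if v.fire_on}
        with pytest.raises(ValueError):
            fire_sensitivity_stat(only_on)


class TestSeasonalityAssociation:
    def test_winter_rain_cells_carry_more_c3_grass(self, coarse_factorial):
        """Winter-rainfall cells hold a higher C3 share than summer cells.

        In this reduced model the association runs through the coldest-
        month survival filter co-located with the winter-rain zone, as
        in the source vegetation model's own southern-African behaviour.
        """
        _, runs = coarse_factorial
        run = runs["co2250_fireon_B"]
        s = run.summaries
        share = run.grass_share_c4
        winter = np.isin(s.phase_month, (6, 7, 8)) & ~np.isnan(share)
        summer = np.isin(s.phase_month, (11, 12, 1, 2, 3)) & ~np.isnan(share) & (s.mat > 18)
        if winter.any() and summer.any():
            c3_winter = 1 - share[winter].mean()
            c3_summer = 1 - share[summer].mean()
            assert c3_winter > c3_summer
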