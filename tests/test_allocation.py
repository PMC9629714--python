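import numpy as np
import pandas as pd
import pytest

from conftest import make_messages
from darkgaps.allocation import (AllocationConfig, AllocationError,
                                 activity_hours, allocate_gaps,
                                 allocate_linear, allocate_probabilistic,
                                 fraction_obscured, hotspots,
                                 summarize_disabling)
from darkgaps.grid import GridSpec, Raster

GRID = GridSpec(-40, -30, -20, -10, 0.25)


class TestAllocateLinear:
    def test_stationary_gap_single_cell(self):
        out = allocate_linear(-35.1, -25.1, -35.1, -25.1, 24.0, GRID,
                              cap_h=None)
        r, c = GRID.cell_index(-35.1, -25.1)
        assert out[r, c] == 24.0
        assert out.sum() == 24.0

    def test_two_week_cap(self):
        out = allocate_linear(-35.1, -25.1, -34.0, -24.0, 400.0, GRID,
                              cap_h=336.0)
        assert out.sum() == pytest.approx(336.0)

    def test_equal_spans_split_evenly(self):
        # meridian segment crossing one cell boundary at lat -25.0 with
        # 0.2 degrees in each cell: 5 h + 5 h
        out = allocate_linear(-35.125, -25.2, -35.125, -24.8, 10.0, GRID,
                              cap_h=None, arc_step_deg=1e-4)
        r1, c1 = GRID.cell_index(-35.125, -25.1)
        r2, c2 = GRID.cell_index(-35.125, -24.9)
        assert out[r1, c1] == pytest.approx(5.0, rel=1e-3)
        assert out[r2, c2] == pytest.approx(5.0, rel=1e-3)
        assert out.sum() == pytest.approx(10.0)

    def test_matches_fine_step_brute_force(self):
        coarse = allocate_linear(-38.7, -28.3, -33.1, -22.9, 50.0, GRID,
                                 cap_h=None, arc_step_deg=0.01)
        fine = allocate_linear(-38.7, -28.3, -33.1, -22.9, 50.0, GRID,
                               cap_h=None, arc_step_deg=1e-4)
        assert np.abs(coarse - fine).max() < 0.1  # < 0.2% of the 50 h total

    def test_antipodal_falls_back_with_warning(self):
        g = GridSpec(-180, -90, 180, 90, 1.0)
        with pytest.warns(RuntimeWarning):
            out = allocate_linear(-90.0, 0.0, 90.0, 0.0, 24.0, g, cap_h=None)
        r, c = g.cell_index(-90.0, 0.0)
        assert out[r, c] == 24.0


class TestAllocateProbabilistic:
    def test_tiny_speed_degenerates_to_endpoint_cells(self):
        cfg = AllocationConfig(cap_h=None, max_speed_knots=1e-9)
        out = allocate_probabilistic(-35.1, -25.1, -34.9, -25.1, 24.0, GRID,
                                     cfg)
        r, c = GRID.cell_index(-35.1, -25.1)
        assert out[r, c] == 24.0

    def test_symmetric_about_track_axis(self):
        # meridian track: mirror cells east/west carry equal weight
        out = allocate_probabilistic(-30.125, -25.0, -30.125, -21.0, 48.0,
                                     GRID, AllocationConfig(cap_h=None))
        _, c0 = GRID.cell_index(-30.125, -23.0)
        for dc in (1, 3, 7):
            west = out[:, c0 - dc]
            east = out[:, c0 + dc]
            np.testing.assert_allclose(west, east, atol=1e-9)

    def test_prior_shifts_weight(self):
        prior_vals = np.zeros(GRID.shape)
        r, c = GRID.cell_index(-30.5, -23.0)
        prior_vals[r, c] = 100.0
        prior = Raster(GRID, prior_vals)
        out = allocate_probabilistic(-30.125, -25.0, -30.125, -21.0, 48.0,
                                     GRID, AllocationConfig(cap_h=None),
                                     prior=prior)
        uniform = allocate_probabilistic(-30.125, -25.0, -30.125, -21.0, 48.0,
                                         GRID, AllocationConfig(cap_h=None))
        assert out[r, c] > uniform[r, c]

    def test_geometry_mismatch_errors(self):
        other = GridSpec(-40, -30, -20, -10, 0.5)
        with pytest.raises(AllocationError):
            allocate_probabilistic(-35, -25, -34, -24, 24.0, GRID,
                                   AllocationConfig(),
                                   prior=Raster(other, np.zeros(other.shape)))


class TestConservation:
    def test_both_methods_conserve_capped_totals(self):
        rng = np.random.default_rng(7)
        expect = lin_tot = prob_tot = 0.0
        uncapped_lin = 0.0
        for _ in range(100):
            lon1 = rng.uniform(-38, -22)
            lat1 = rng.uniform(-28, -12)
            lon2, lat2 = lon1 + rng.uniform(-2, 2), lat1 + rng.uniform(-2, 2)
            dur = rng.uniform(12, 500)
            expect += min(dur, 336.0)
            lin = allocate_linear(lon1, lat1, lon2, lat2, dur, GRID, 336.0)
            prob = allocate_probabilistic(lon1, lat1, lon2, lat2, dur, GRID,
                                          AllocationConfig(cap_h=336.0))
            lin_tot += lin.sum()
            prob_tot += prob.sum()
            uncapped_lin += allocate_linear(lon1, lat1, lon2, lat2, dur,
                                            GRID, None).sum()
        assert lin_tot == pytest.approx(expect, rel=1e-6)
        assert prob_tot == pytest.approx(expect, rel=1e-6)
        assert lin_tot <= uncapped_lin + 1e-9


class TestActivityHours:
    def test_same_cell_interval(self):
        act = activity_hours(make_messages([0.0, 4.0]), GRID)
        r, c = GRID.cell_index(-35.1, -25.1)
        assert act.values[r, c] == 4.0

    def test_adjacent_cells_split_half_half(self):
        m = make_messages([0.0, 4.0], lons=[-35.1, -34.6],
                          lats=[-25.1, -25.1])
        act = activity_hours(m, GRID)
        r1, c1 = GRID.cell_index(-35.1, -25.1)
        r2, c2 = GRID.cell_index(-34.6, -25.1)
        assert act.values[r1, c1] == 2.0 and act.values[r2, c2] == 2.0

    def test_gap_candidate_interval_excluded(self):
        act = activity_hours(make_messages([0.0, 20.0]), GRID)
        assert act.values.sum() == 0.0

    def test_strata_partition_total(self):
        m = pd.concat([
            make_messages(np.arange(0, 48, 2.0), vessel_id="a",
                          gear="trawler"),
            make_messages(np.arange(0, 48, 3.0), vessel_id="b",
                          gear="squid_jigger", lons=None)])
        total = activity_hours(m, GRID)
        strata = activity_hours(m, GRID, stratum="gear")
        summed = sum(r.values for r in strata.values())
        np.testing.assert_allclose(summed, total.values, atol=1e-9)


class TestFractionObscured:
    def _raster(self, value):
        return Raster(GRID, np.full(GRID.shape, float(value)))

    def test_zero_disabling_zero_fraction(self):
        frac = fraction_obscured(self._raster(0), self._raster(5))
        assert (frac.values == 0).all()

    def test_hand_ratio(self):
        frac = fraction_obscured(self._raster(10), self._raster(90))
        assert frac.values[0, 0] == pytest.approx(0.10)

    def test_all_disabling_cell_is_one(self):
        frac = fraction_obscured(self._raster(7), self._raster(0))
        assert frac.values[0, 0] == 1.0

    def test_empty_cell_missing(self):
        frac = fraction_obscured(self._raster(0), self._raster(0))
        assert np.isnan(frac.values).all()

    def test_capped_bounds_order(self):
        rng = np.random.default_rng(2)
        gaps = pd.DataFrame({
            "start_lon": rng.uniform(-38, -22, 50),
            "start_lat": rng.uniform(-28, -12, 50),
            "duration_h": rng.uniform(12, 800, 50)})
        gaps["end_lon"] = gaps["start_lon"] + 0.5
        gaps["end_lat"] = gaps["start_lat"]
        capped = allocate_gaps(gaps, GRID, "linear", cap_h=336.0)
        uncapped = allocate_gaps(gaps, GRID, "linear", cap_h=None)
        assert capped.values.sum() <= uncapped.values.sum()
        assert (capped.values <= uncapped.values + 1e-9).all()


class TestHotspots:
    def test_zero_thresholds_select_everything(self):
        frac = Raster(GRID, np.full(GRID.shape, 0.5))
        act = Raster(GRID, np.full(GRID.shape, 10.0))
        hs = hotspots(frac, act, 0.0, 0.0)
        assert len(hs) == GRID.nrows * GRID.ncols

    def test_empty_selection_ok(self):
        frac = Raster(GRID, np.zeros(GRID.shape))
        act = Raster(GRID, np.zeros(GRID.shape))
        hs = hotspots(frac, act, 0.5, 1.0)
        assert len(hs) == 0

    def test_corner_touch_is_two_components(self):
        vals = np.zeros(GRID.shape)
        vals[10, 10] = vals[11, 11] = 1.0
        frac = Raster(GRID, vals)
        act = Raster(GRID, vals)
        hs = hotspots(frac, act, 0.5, 0.5)
        assert len(hs) == 2
        assert hs["component"].nunique() == 2


class TestSummary:
    def test_gear_summary_bounds(self):
        gaps = pd.DataFrame({
            "classification": ["suspected_disabling"] * 3,
            "gear": ["trawler", "trawler", "squid_jigger"],
            "start_lon": -35.0, "start_lat": -25.0,
            "end_lon": -35.0, "end_lat": -25.0,
            "duration_h": [100.0, 500.0, 24.0]})
        m = make_messages(np.arange(0, 24, 1.0), gear="trawler")
        table = summarize_disabling(gaps, m, GRID, by="gear")
        trawler = table[table["gear"] == "trawler"].iloc[0]
        assert trawler["events"] == 2
        assert trawler["hours_lost_lower"] == pytest.approx(100 + 336)
        assert trawler["hours_lost_upper"] == pytest.approx(600)
        assert trawler["fraction_lower"] <= trawler["fraction_upper"]
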