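"""Synthetic-generator contracts: determinism, behavioural structure,
GPS duty-cycle model and raster generation."""

import math

import numpy as np
import pytest

from fptseg.simulate import (COMMUTE, FORAGE, ROOST, LANDCOVER_CODES, PatchSpec,
                             SimConfig, UnreachablePatchError, generate_elevation,
                             generate_landcover, random_night_config, sample_gps,
                             schedule_seconds, simulate_night)

from .conftest import single_patch_config


def _excursions(states):
    """Count maximal non-ROOST runs (roost-to-roost trips)."""
    moving = states != ROOST
    return int(np.sum(moving[1:] & ~moving[:-1]) + moving[0])


class TestSimulateNight:
    def test_same_seed_is_bit_identical(self):
        cfg = single_patch_config(seed=11)
        a, b = simulate_night(cfg), simulate_night(cfg)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.truth.state, b.truth.state)
        assert np.array_equal(a.truth.trip, b.truth.trip)

    def test_path_starts_and_ends_at_roost(self):
        night = simulate_night(single_patch_config(seed=1))
        assert night.x[0] == 0.0 and night.y[0] == 0.0
        assert night.x[-1] == 0.0 and night.y[-1] == 0.0

    def test_commute_duration_matches_distance_over_speed(self):
        """15 km at ~7 m/s commuting: each leg should take ~2143 s."""
        cfg = single_patch_config(seed=2, distance=15000.0)
        night = simulate_night(cfg)
        st = night.truth.state
        first_commute = np.nonzero(st == COMMUTE)[0]
        first_forage = np.nonzero(st == FORAGE)[0][0]
        outbound_s = first_forage - first_commute[0]
        assert outbound_s == pytest.approx(15000.0 / 7.0, rel=0.12)

    @pytest.mark.parametrize("n_trips", [1, 2, 3])
    def test_ground_truth_has_configured_trip_count(self, n_trips):
        rng = np.random.default_rng(100 + n_trips)
        cfg = random_night_config(rng, n_trips=n_trips)
        night = simulate_night(cfg)
        assert _excursions(night.truth.state) == n_trips
        assert night.truth.trip.max() == n_trips

    def test_forage_steps_stay_inside_their_patch(self):
        cfg = single_patch_config(seed=3)
        night = simulate_night(cfg)
        in_forage = night.truth.state == FORAGE
        patch = cfg.patches[0]
        d = np.hypot(night.x[in_forage] - patch.center[0],
                     night.y[in_forage] - patch.center[1])
        assert np.all(d <= patch.radius + 1e-6)

    def test_mean_commute_speed_matches_configuration(self):
        """Monte-Carlo: per-night mean commute speed across seeds must sit
        within 2 SE of the configured 7 m/s."""
        means = []
        for seed in range(30):
            night = simulate_night(single_patch_config(seed=seed))
            sp = np.hypot(np.diff(night.x), np.diff(night.y))
            commute = night.truth.state[1:] == COMMUTE
            means.append(sp[commute].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / math.sqrt(means.size)
        # the approach-clamp at the target shaves a whisker off the last step
        assert abs(means.mean() - 7.0) <= max(2 * se, 0.02)

    def test_trip_path_distance_at_least_twice_straight_line(self):
        cfg = single_patch_config(seed=5, distance=18000.0)
        night = simulate_night(cfg)
        sp = np.hypot(np.diff(night.x), np.diff(night.y))
        in_trip = night.truth.trip[1:] == 1
        assert sp[in_trip].sum() >= 2 * 18000.0

    def test_unreachable_patch_raises_with_patch_named(self):
        cfg = single_patch_config(seed=6, distance=100_000.0)
        with pytest.raises(UnreachablePatchError, match="100.0 km"):
            simulate_night(cfg)


class TestSampleGps:
    def test_nine_hour_window_at_10min_has_55_slots(self):
        cfg = single_patch_config(seed=0)
        assert schedule_seconds(cfg).size == 55

    def test_no_dropout_no_error_fixes_lie_on_path(self):
        cfg = single_patch_config(seed=7, dropout_prob=0.0, position_error_sd=0.0)
        night = simulate_night(cfg)
        gps = sample_gps(night, cfg)
        valid = gps["fix-status"] == "valid"
        slots = schedule_seconds(cfg)[valid.to_numpy()]
        px, py = night.position_at(slots)
        from .conftest import TM
        rx, ry = TM.forward(*cfg.roost_lonlat)
        fx, fy = TM.forward(gps.loc[valid, "location-long"].to_numpy(),
                            gps.loc[valid, "location-lat"].to_numpy())
        np.testing.assert_allclose(fx - rx, px, atol=1e-3)
        np.testing.assert_allclose(fy - ry, py, atol=1e-3)

    def test_roost_slots_are_invalid_and_carry_no_coordinates(self):
        cfg = single_patch_config(seed=8, dropout_prob=0.0)
        night = simulate_night(cfg)
        gps = sample_gps(night, cfg)
        idx = np.clip(np.round(schedule_seconds(cfg)).astype(int), 0,
                      night.t.size - 1)
        roosting = night.truth.state[idx] == ROOST
        assert (gps.loc[roosting, "fix-status"] == "invalid").all()
        assert gps.loc[roosting, "location-long"].isna().all()

    def test_dropout_rate_emulates_the_campaign_failure_rate(self):
        """With p=0.47, valid fraction of airborne slots ~= 709/1343 ~= 0.53."""
        got = 0
        scheduled = 0
        for seed in range(40):
            cfg = single_patch_config(seed=seed, dropout_prob=0.47)
            night = simulate_night(cfg)
            gps = sample_gps(night, cfg)
            idx = np.clip(np.round(schedule_seconds(cfg)).astype(int), 0,
                          night.t.size - 1)
            airborne = night.truth.state[idx] != ROOST
            scheduled += int(airborne.sum())
            got += int((gps.loc[airborne, "fix-status"] == "valid").sum())
        assert got / scheduled == pytest.approx(709 / 1343, abs=0.02)

    def test_same_seed_same_fix_table(self):
        cfg = single_patch_config(seed=9)
        night = simulate_night(cfg)
        a = sample_gps(night, cfg)
        b = sample_gps(night, cfg)
        assert a.equals(b)


class TestRasters:
    def test_patch_cells_take_patch_class(self):
        patch = PatchSpec(center=(500.0, 500.0), radius=120.0, habitat="forest")
        ras = generate_landcover((0, 0, 1000, 1000), [patch],
                                 background_class="shrubland", cell_size=10.0)
        cx, cy = ras.cell_centers()
        inside = (cx - 500) ** 2 + (cy - 500) ** 2 <= 120**2
        assert np.all(ras.values[inside] == LANDCOVER_CODES["forest"])
        assert np.all(ras.values[~inside] == LANDCOVER_CODES["shrubland"])

    def test_empty_patch_list_is_uniform_background(self):
        ras = generate_landcover((0, 0, 500, 500), [], background_class="farmland",
                                 cell_size=50.0)
        assert np.all(ras.values == LANDCOVER_CODES["farmland"])

    def test_patch_cell_count_matches_circle_area(self):
        """pi * 400^2 / cell_area, within 2% (area-count comparison)."""
        patch = PatchSpec(center=(2000.0, 2000.0), radius=400.0, habitat="forest")
        ras = generate_landcover((0, 0, 4000, 4000), [patch],
                                 background_class="shrubland", cell_size=10.0)
        n = int(np.sum(ras.values == LANDCOVER_CODES["forest"]))
        assert n == pytest.approx(math.pi * 400**2 / 100, rel=0.02)

    def test_patch_outside_extent_raises(self):
        patch = PatchSpec(center=(5000.0, 0.0), radius=100.0, habitat="forest")
        with pytest.raises(ValueError, match="outside extent"):
            generate_landcover((0, 0, 1000, 1000), [patch])

    def test_bad_cell_size_raises(self):
        with pytest.raises(ValueError):
            generate_landcover((0, 0, 100, 100), [], cell_size=0.0)
        with pytest.raises(ValueError):
            generate_elevation((0, 0, 100, 100), cell_size=-5.0)

    def test_elevation_is_seeded_and_smooth(self):
        a = generate_elevation((0, 0, 5000, 5000), cell_size=100.0, seed=4)
        b = generate_elevation((0, 0, 5000, 5000), cell_size=100.0, seed=4)
        np.testing.assert_array_equal(a.values, b.values)
        # relief stays within base +- amplitude and varies gently cell-to-cell
        assert a.values.min() > 1950.0 - 130.0
        assert a.values.max() < 1950.0 + 130.0
        assert np.max(np.abs(np.diff(a.values, axis=1))) < 20.0


def test_config_validation():
    patch = PatchSpec(center=(1000.0, 0.0), radius=300.0, habitat="shrubland")
    with pytest.raises(ValueError):
        SimConfig(patches=())
    with pytest.raises(ValueError):
        SimConfig(patches=(patch,), commute_speed_mean=1.0, forage_speed_mean=2.0)
    with pytest.raises(ValueError):
        SimConfig(patches=(patch,), dropout_prob=1.0)
    with pytest.raises(ValueError):
        SimConfig(patches=(patch,), trip_itineraries=((3,),))
    with pytest.raises(ValueError):
        PatchSpec(center=(0.0, 0.0), radius=-1.0, habitat="shrubland")
    with pytest.raises(ValueError):
        PatchSpec(center=(0.0, 0.0), radius=10.0, habitat="swamp")
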