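"""Trip decomposition, foraging-area delineation and habitat summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from fptseg.fpt import passage_times
from fptseg.raster import Raster
from fptseg.segmentation import (CF, FF, Segment, build_segments, classify_modes,
                                 track_step_lengths)
from fptseg.simulate import LANDCOVER_CODES
from fptseg.trips import (ForagingArea, Trip, area_size, assign_habitat,
                          find_foraging_areas, habitat_tests, night_summary,
                          roost_distance, search_time, split_trips, trip_metrics)

from .conftest import planar_track


class TestSplitTrips:
    def test_regular_track_is_one_trip(self, projected_roost):
        track = planar_track(np.arange(6) * 1000.0, np.zeros(6),
                             np.arange(6) * 600.0)
        trips = split_trips(track, projected_roost)
        assert len(trips) == 1
        assert (trips[0].start, trips[0].end) == (0, 5)

    def test_near_roost_gap_splits(self, projected_roost):
        """45-min gap with both flanking fixes 2 km from the roost."""
        x = [0.0, 2000.0, 2000.0, 0.0]
        t = [0.0, 600.0, 600.0 + 45 * 60.0, 600.0 + 45 * 60.0 + 600.0]
        track = planar_track(x, np.zeros(4), t)
        trips = split_trips(track, projected_roost)
        assert len(trips) == 2
        assert [t.index for t in trips] == [1, 2]

    def test_far_gap_does_not_split(self, projected_roost):
        """A 40-min fix-failure run 15 km out cannot hide a roost visit."""
        x = [0.0, 8000.0, 15000.0, 15500.0, 8000.0, 0.0]
        t = [0.0, 1200.0, 2400.0, 2400.0 + 40 * 60.0, 6000.0, 7200.0]
        track = planar_track(x, np.zeros(6), t)
        assert len(split_trips(track, projected_roost)) == 1

    def test_long_gap_with_time_for_roost_return_splits(self, projected_roost):
        """Same distances, but a 2.5 h gap leaves >= 30 min of dwell."""
        x = [0.0, 8000.0, 8000.0, 0.0]
        t = [0.0, 1200.0, 1200.0 + 150 * 60.0, 1200.0 + 150 * 60.0 + 1200.0]
        track = planar_track(x, np.zeros(4), t)
        assert len(split_trips(track, projected_roost)) == 2


class TestTripMetrics:
    def test_out_and_back_distance(self, projected_roost):
        x = [0.0, 7500.0, 15000.0, 7500.0, 0.0]
        track = planar_track(x, np.zeros(5), np.arange(5) * 600.0)
        (trip,) = split_trips(track, projected_roost)
        assert trip.total_distance_km == pytest.approx(30.0)

    def test_mean_speed_arithmetic(self):
        # 36 km in 2.5 h -> 4 m/s
        track = planar_track([0.0, 18000.0, 36000.0], np.zeros(3),
                             [0.0, 4500.0, 9000.0])
        trip = trip_metrics(Trip(track_id="t", index=1, start=0, end=2),
                            track)
        assert trip.mean_speed_ms == pytest.approx(4.0)

    def test_single_fix_trip_flagged(self):
        track = planar_track([0.0, 1000.0], np.zeros(2), [0.0, 600.0])
        trip = trip_metrics(Trip(track_id="t", index=1, start=1, end=1),
                            track)
        assert trip.incomplete
        assert math.isnan(trip.total_distance_km)

    def test_trip_distances_plus_inter_trip_steps_conserve(self, projected_roost):
        x = [0.0, 2000.0, 2000.0, 0.0, 1000.0, 3000.0]
        t = [0.0, 600.0, 600.0 + 2700.0, 600.0 + 3300.0, 4800.0, 5400.0]
        track = planar_track(x, np.zeros(6), t)
        trips = split_trips(track, projected_roost)
        assert len(trips) == 2
        steps = track_step_lengths(track)
        inter = sum(steps[t0.end] for t0 in trips[:-1])
        total = sum(t0.total_distance_km for t0 in trips) * 1000.0 + inter
        assert total == pytest.approx(float(steps.sum()), abs=1e-9)


def _ff_segment(track, start, end):
    seg = Segment(track_id=track.individual_id, mode=FF, start=start, end=end,
                  start_time=track.fixes["timestamp"].iloc[start],
                  end_time=track.fixes["timestamp"].iloc[end])
    from fptseg.segmentation import segment_metrics
    return segment_metrics(seg, track)


class TestForagingAreas:
    def test_two_fix_thirty_minute_segment_qualifies(self):
        track = planar_track([0.0, 200.0, 5000.0], np.zeros(3),
                             [0.0, 1800.0, 3600.0])
        seg = _ff_segment(track, 0, 1)
        areas = find_foraging_areas([seg], track, r_star=300.0)
        assert len(areas) == 1
        assert areas[0].member_fixes == [0, 1]

    def test_single_fix_segment_rejected(self):
        track = planar_track([0.0, 200.0, 5000.0], np.zeros(3),
                             [0.0, 1800.0, 3600.0])
        seg = _ff_segment(track, 1, 1)
        assert find_foraging_areas([seg], track, r_star=300.0) == []

    def test_short_span_rejected(self):
        track = planar_track([0.0, 200.0, 5000.0], np.zeros(3),
                             [0.0, 900.0, 3600.0])
        seg = _ff_segment(track, 0, 1)     # 15-min span
        assert find_foraging_areas([seg], track, r_star=300.0) == []

    def test_cf_segments_ignored(self):
        track = planar_track([0.0, 200.0, 400.0], np.zeros(3),
                             [0.0, 1800.0, 3600.0])
        seg = _ff_segment(track, 0, 2)
        seg.mode = CF
        assert find_foraging_areas([seg], track, r_star=300.0) == []

    def test_revisited_patch_merges_into_one_area(self):
        # two FF bouts around the same spot, a commute in between
        x = [0.0, 100.0, 5000.0, 80.0, 150.0]
        t = [0.0, 1800.0, 3600.0, 5400.0, 7200.0]
        track = planar_track(x, np.zeros(5), t)
        segs = [_ff_segment(track, 0, 1), _ff_segment(track, 3, 4)]
        merged = find_foraging_areas(segs, track, r_star=300.0, merge=True)
        assert len(merged) == 1
        assert merged[0].n_segments == 2
        assert merged[0].search_time_h == pytest.approx(
            segs[0].duration_h + segs[1].duration_h)
        unmerged = find_foraging_areas(segs, track, r_star=300.0, merge=False)
        assert len(unmerged) == 2

    def test_area_size_values(self):
        assert area_size(300.0) == 0.28
        assert area_size(0.0) == 0.0
        assert area_size(339.0) == 0.36
        assert area_size(500.0) > area_size(400.0) > area_size(300.0)

    def test_roost_distance_and_search_time(self, projected_roost):
        area = ForagingArea(id="a", track_id="t", member_fixes=[0],
                            centroid=(projected_roost.x + 16410.0,
                                      projected_roost.y),
                            r_star=300.0, area_km2=0.28, search_time_h=1.5)
        assert roost_distance(area, projected_roost) == pytest.approx(16.41)
        assert search_time(area) == 1.5


class TestAssignHabitat:
    def _raster(self, codes):
        return Raster(values=np.array(codes, dtype=float), x0=0.0, y0=0.0,
                      cell=1000.0)

    def _area_track(self, xs, ys):
        track = planar_track(xs, ys, np.arange(len(xs)) * 600.0)
        # use raw grid coordinates: rebuild fixes with x/y directly
        track.fixes["x"] = xs
        track.fixes["y"] = ys
        area = ForagingArea(id="a", track_id="t",
                            member_fixes=list(range(len(xs))),
                            centroid=(float(np.mean(xs)), float(np.mean(ys))),
                            r_star=300.0, area_km2=0.28, search_time_h=1.0)
        return track, area

    def test_majority_vote(self):
        ras = self._raster([[LANDCOVER_CODES["forest"], LANDCOVER_CODES["farmland"]]])
        track, area = self._area_track([200.0, 300.0, 1200.0], [500.0] * 3)
        assert assign_habitat(area, ras, track) == "forest"

    def test_tie_breaks_by_priority(self):
        ras = self._raster([[LANDCOVER_CODES["forest"], LANDCOVER_CODES["shrubland"]]])
        track, area = self._area_track([200.0, 300.0, 1200.0, 1300.0], [500.0] * 4)
        assert assign_habitat(area, ras, track) == "shrubland"

    def test_fixes_outside_raster_excluded(self):
        ras = self._raster([[LANDCOVER_CODES["farmland"]]])
        track, area = self._area_track([500.0, 500000.0], [500.0, 500.0])
        assert assign_habitat(area, ras, track) == "farmland"

    def test_all_outside_is_unknown(self):
        ras = self._raster([[LANDCOVER_CODES["farmland"]]])
        track, area = self._area_track([500000.0, 600000.0], [500.0, 500.0])
        assert assign_habitat(area, ras, track) is None
        assert area.habitat is None


def _area(habitat, dist, size, time):
    return ForagingArea(id="x", track_id="t", member_fixes=[0], centroid=(0, 0),
                        r_star=300.0, area_km2=size, search_time_h=time,
                        roost_distance_km=dist, habitat=habitat)


class TestHabitatTests:
    def test_fractions_sum_to_one(self):
        areas = [_area("shrubland", 10, 0.3, 1.0), _area("forest", 12, 0.3, 1.0),
                 _area("forest", 15, 0.4, 2.0)]
        hs = habitat_tests(areas)
        assert sum(hs.fractions.values()) == pytest.approx(1.0)
        assert hs.counts == {"shrubland": 1, "forest": 2, "farmland": 0}

    def test_identical_groups_give_h_zero_p_one(self):
        areas = [_area(h, 10.0, 0.3, 1.0) for h in
                 ("shrubland", "forest", "farmland")]
        hs = habitat_tests(areas)
        row = hs.tests.set_index("variable").loc["roost_distance_km"]
        assert row["H"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_h_matches_hand_rank_formula(self):
        """Groups {1,2}, {3,4}, {5,6}: H = 12/(N(N+1)) * sum(R^2/n) - 3(N+1)
        = 12/42 * (9 + 49 + 121)/2 - 21 = 32/7 ~= 4.5714 (no ties, df 2)."""
        dists = {"shrubland": [1.0, 2.0], "forest": [3.0, 4.0],
                 "farmland": [5.0, 6.0]}
        areas = [_area(h, d, 0.3, 1.0) for h, ds in dists.items() for d in ds]
        hs = habitat_tests(areas)
        row = hs.tests.set_index("variable").loc["roost_distance_km"]
        rank_sums = [1 + 2, 3 + 4, 5 + 6]
        h_hand = 12 / (6 * 7) * sum(r**2 / 2 for r in rank_sums) - 3 * 7
        assert h_hand == pytest.approx(32 / 7)
        assert row["H"] == pytest.approx(h_hand, rel=1e-12)
        assert row["df"] == 2

    def test_single_group_omits_tests(self):
        areas = [_area("forest", 10, 0.3, 1.0), _area("forest", 12, 0.3, 1.0)]
        hs = habitat_tests(areas)
        assert hs.tests is None
        assert hs.counts["forest"] == 2


class TestNightSummary:
    def test_all_commute_night_has_zero_ff(self, projected_roost):
        track = planar_track(np.arange(5) * 2000.0, np.zeros(5),
                             np.arange(5) * 600.0)
        labels = np.array([CF] * 5)
        trips = split_trips(track, projected_roost)
        summ = night_summary(track, labels, trips, [])
        assert summ.ff_time_h == 0.0
        assert summ.ff_fraction_moving == 0.0
        assert summ.cf_time_h == pytest.approx(summ.moving_time_h)

    def test_cf_plus_ff_equals_moving_time(self, processed_night, projected_roost):
        _, cfg, track, _ = processed_night
        from fptseg.trackio import Roost
        from fptseg.projection import TransverseMercator
        tm = TransverseMercator.for_point(*cfg.roost_lonlat)
        roost = Roost(*cfg.roost_lonlat).projected(tm)
        labels = classify_modes(passage_times(track, 339.0))
        trips = split_trips(track, roost)
        summ = night_summary(track, labels, trips, [])
        assert summ.cf_time_h + summ.ff_time_h == pytest.approx(
            summ.moving_time_h, abs=1e-9)
        assert summ.moving_time_h <= summ.night_time_h

    def test_main_area_is_longest_search(self, projected_roost):
        track = planar_track(np.arange(3) * 1000.0, np.zeros(3),
                             np.arange(3) * 600.0)
        areas = [_area("forest", 5, 0.3, 0.8), _area("shrubland", 7, 0.3, 1.9)]
        summ = night_summary(track, np.array([CF] * 3),
                             split_trips(track, projected_roost), areas)
        assert summ.main_area_time_h == 1.9
        assert summ.n_areas == 2
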