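# fptseg

First-passage-time (FPT) segmentation of nightly GPS tracks from
central-place foragers — built around the movement ecology of lactating
nectar-feeding bats commuting between a maternity roost and nectar
patches, but applicable to any two-mode commute/forage tracker data.

The package is for movement ecologists who have Movebank-style fix
tables (timestamp, longitude, latitude, individual id, fix validity)
and want a reproducible pipeline from raw fixes to behavioural
segments, nightly round trips, and delineated foraging areas — plus a
fully seeded synthetic-data generator so every stage can be validated
against known ground truth without any field data.

## The method

For a relocation *i* on a planar track, the first passage time *t(r)*
is the time the path takes to traverse a circle of radius *r* centred
on that relocation — the forward crossing time plus the backward
crossing time, with the path between fixes taken as piecewise linear
at constant speed per step. Slow, tortuous area-restricted search (ARS)
inside a resource patch produces large *t(r)*; fast directed commuting
produces small *t(r)*.

The characteristic scale of ARS is selected per track as the peak of

&nbsp;&nbsp;&nbsp;&nbsp;*S(r)* = Var[log *t(r)*]

over a radius grid (default 300–500 m by 10 m). The mean of the
per-track optimal radii *r\** across the cohort is the single radius
used for a final FPT pass, and each fix is classified by its log
passage time (natural log, minutes):

&nbsp;&nbsp;&nbsp;&nbsp;log *t* < 2.7141 → commuting flight (CF),
log *t* > 2.7141 → foraging flight (FF).

Maximal same-mode runs become segments with length, duration, speed and
elevation; nights split into roost-to-roost trips at fix gaps long
enough to hide a roost visit; FF segments spanning ≥ 30 min and ≥ 2
relocations become foraging areas, each sized as π *r\**² from its
track's own *S(r)* peak, and assigned the majority land-cover class
under its relocations. Mann–Whitney U (CF vs FF, per-track means) and
Kruskal–Wallis (across habitats) tests summarise the cohort.

## Worked example

Simulate a small cohort and analyse it from the shell:

```sh
fptseg simulate --out demo --seed 7 --nights 5
fptseg analyze --tracks demo/sim/tracks.csv --out demo_analysis --seed 7
```

or equivalently from Python:

```python
from fptseg.pipeline import PipelineConfig, run

report = run(PipelineConfig(seed=7, output_dir="demo", n_nights=5))
print(report.to_text())
```

which prints (abridged):

```
-- per-stage counts --
tracks_read: 5
fixes_read: 257
fixes_valid: 85
tracks_analysed: 5
segments: 20
trips: 8
foraging_areas: 6

-- cohort statistics (mean +- sd unless noted) --
optimal_radius_m: 336.00 +- 45.06
total_distance_km: 62.57 +- 24.01
mean_speed_ms: 3.50 +- 0.73
trips_per_night: 1.60 +- 0.55
areas_per_night: 1.20 +- 0.84
cf_fraction_moving: 0.51 +- 0.11
n_foraging_areas: 6
area_km2: 0.38 +- 0.10
area_km2_min: 0.28
roost_distance_km: 24.77 +- 10.80
search_time_h: 1.75 +- 0.31
```

Reading: the five simulated bats flew 62.6 km per night on average,
made 1–2 round trips, and the scale-selection curve peaked at 336 ±
45 m — so the final classification ran FPT circles of that radius. Six
foraging areas qualified (≥ 30 min of FF), the smallest delineated at
0.28 km² (a 300 m radius, the bottom of the grid), at a mean 25 km from
the roost with ~1.8 h of nightly search effort each. About half the
moving time (51%) went to commuting.

Per-track tables (`per_track.csv`), segment/trip/area CSVs, S(r)
profiles, GeoJSON features and a plain-text report land in the output
directory; `fptseg summarize --in demo_analysis` aggregates several
runs.

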