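# Methods

This note documents the models, conventions and numerical choices
behind `fptseg`: what each stage computes, which parameters matter and
why their defaults are what they are, what the synthetic-data generator
does and does not emulate, and the known limitations.

## First passage time on a sparse track

The passage time at radius *r* for relocation *i* is the residence span
of the path in the circle of radius *r* centred on fix *i*: the elapsed
time from the fix until the path first crosses the circle forward,
plus the symmetric backward component toward the track start. The path
between fixes is piecewise linear at constant speed per step, so a
crossing is the outward root of a quadratic segment–circle
intersection, and the crossing instant interpolates linearly within the
step. Because a chord with both endpoints inside a circle cannot leave
it, the crossing segment is exactly the one ending at the first fix
beyond *r* — this is also why passage times are monotone non-decreasing
in *r*. Where the track ends (or starts) before crossing, the component
— and hence *t(r)* — is undefined for that fix; the first and last fix
are therefore always undefined. A step longer than *r* still yields a
defined (small) crossing within that step.

Conventions that make results bit-stable:

- time in **minutes**, logarithms **natural**;
- *S(r)* is the sample variance (n−1 denominator) of log *t(r)* over
  the fixes with defined *t*, computed listwise per radius; radii with
  fewer than two defined fixes have undefined *S*;
- the grid default is 300–500 m in 10 m steps; the argmax resolves
  ties toward the smallest radius;
- fix-failure gaps are bridged linearly at implied constant speed — no
  gap capping. This keeps the estimator simple and deterministic; very
  long gaps therefore contribute slow apparent movement, which is one
  reason sparse tracks drift toward small optimal radii.

The classification threshold 2.7141 log-minutes is carried over from
the FPT segmentation literature as an opaque constant (e^2.7141 ≈ 15.1
minutes, about one coarse fix interval); it is configurable. Equality
at the threshold is classed as commuting — the conservative choice.
Fixes with undefined *t* inherit the nearest preceding defined label
(or the nearest following one at the track start) so that trips and
distance budgets stay whole; dropping them instead would punch holes in
every night's first and last commute.

## Segments, trips, areas

**Segments.** Maximal same-mode runs. The step from fix *i* to *i+1*
belongs to the segment containing fix *i*, and a segment's duration
runs to the first fix of the next segment. These two conventions make
the decomposition exactly conservative: segment lengths sum to the
track length and segment durations to the track span (both asserted at
run time in the pipeline). Note that a segment spanning a roost dwell
inherits the dwell in its duration, which dilutes its mean speed; the
per-night time budget below avoids this by accounting within trips.

**Trips.** The tag records nothing inside the roost, so a roost visit
appears as a long fix gap. A gap splits two trips when the bat could
have flown from the last fix to the roost, dwelt at least `min_gap`
(default 30 min, the shortest inter-trip lag the emulated campaign
reports), and flown back out to the next fix — i.e. when
`gap − (d_a + d_b) / commute_speed ≥ min_gap`, with `commute_speed`
defaulting to 7.5 m/s (just above typical commuting flight) and
`d_a`, `d_b` the roost distances of the bracketing fixes. Gaps whose
bracketing fixes both sit within `roost_buffer` (default 5 km) split
unconditionally once they exceed `min_gap`. The travel-time term is
what rejects multi-fix failure runs in mid-commute or mid-patch: a
30–60 min blackout 15 km from the roost cannot hide a roost visit. A
plain "both fixes near the roost" rule was tried first and discarded —
under realistic fix failure the last valid fix before a roost entry is
frequently several kilometres out, so true boundaries are missed at a
high rate, while the reachability rule recovers the simulated trip
count essentially always (see the acceptance experiments).

**Foraging areas.** Every foraging-flight segment whose member fixes
span ≥ 30 min and number ≥ 2 becomes an area: centroid = mean of member
fix positions; characteristic radius = the track's own *S(r)*-peak
radius *r\** (deliberately not the cohort mean radius used for
thresholding — the two scales coexist); size = π *r\**² in km²,
reported to two decimals; search time = summed duration of the member
segments; roost distance measured to the centroid. Areas of one track
whose centroids fall within *r\** of each other are merged (a patch
revisited across the night is one area, not several); the merge is
configurable and off-by-default counts are one flag away.

**Habitat.** Majority land-cover class under the member fixes
(nearest-cell sampling, half-open cells `[x0, x0+w)`), ties broken by
the fixed priority shrubland > forest > farmland; fixes outside the
raster abstain, and an area with no votes is flagged unknown.

**Statistics.** Commuting vs foraging contrasts use per-track means of
per-segment values (the track, not the segment, is the unit of
analysis) under a two-sided Mann–Whitney U — exact enumeration when
both groups have n ≤ 12 and no ties, otherwise the normal approximation
with tie and continuity corrections, and the method used is reported.
The reported U is the smaller of the two group statistics. Habitat
contrasts use Kruskal–Wallis with tie correction and a χ² reference
(df = groups − 1); fully tied samples are reported as H = 0, p = 1.

**Per-night time budget.** Moving time is the elapsed time inside
trips; CF and FF times accumulate over in-trip steps (each step carries
its left fix's label), so CF + FF = moving time exactly. Because field
summaries differ on whether roost dwells belong in the denominator,
fractions are reported against both moving time and the full
first-to-last-fix night span.

## Geodesy and rasters

Metric quantities (radii, step lengths, distances) require a planar
frame: the UTM zone containing the roost (WGS84, transverse Mercator,
k₀ = 0.9996), implemented from the classical series expansions and
accurate to well under a millimetre within a zone; the declared CRS id
(e.g. `EPSG:32614`) travels with the config. Timestamps are UTC
internally; clock-time rules (fix schedules, the 20:00–21:30
activation-site exclusion) convert through a configured UTC offset
(default −6 h). The early-evening exclusion drops fixes inside the
window within 1 km (configurable) of the activation site, anchored at
the roost when known, else at the night's first valid fix — the roost
anchor also makes filtering idempotent. Rasters are single-band Esri
ASCII grids, georeferenced in the same planar frame; land-cover classes
are coded integers (shrubland 1, forest 2, farmland 3 over background
0) and elevation is metres.

## The synthetic generator

`simulate` produces one-night central-place-forager tracks at 1-s
resolution with per-second behavioural truth, emulating the GPS
campaign the pipeline is built around:

- **night**: 20:30–05:30 local (9 h), 1–3 round trips per night drawn
  with weights 10/21, 8/21, 3/21 (the observed trip-count mix), roost
  dwells uniform 30–90 min between trips;
- **patches**: radius uniform 300–500 m, placed 13–40 km from the roost
  in a northward fan, habitat drawn with weights 0.46 shrubland /
  0.27 forest / 0.27 farmland; itineraries are redrawn until the night
  physically accommodates the commuting they imply;
- **commuting**: target-directed walk, speed ~ Normal(7, 1) m/s
  truncated at 0.1 m/s (reject-and-redraw), heading re-aimed at the
  target each second with 0.1 rad wrapped-normal noise;
- **foraging**: a smoothly curving search walk, speed ~ Normal(1.5,
  0.5) m/s truncated likewise, heading a random walk with 0.2 rad/s
  increments, plus a weak Ornstein–Uhlenbeck pull toward the patch
  core whose rate is set so the stationary position sd is
  `forage_core_frac` (0.30) of the patch radius — nectar bats trapline
  around a flower cluster rather than diffusing freely — with
  reflection at the patch boundary as a hard backstop. Bout durations
  are uniform 60–150 min per patch visit; whatever night time remains
  after the last return becomes a final roost dwell;
- **GPS model**: one scheduled slot every `fix_interval` minutes
  (10 or 15 in the emulated campaign), endpoints inclusive; slots
  during roost dwells are invalid (the tag cannot see satellites
  indoors — this is what creates the inter-trip gaps); airborne slots
  fail independently with `dropout_prob` (0.47 emulates the campaign's
  709/1343 valid-fix rate *for airborne slots*; total validity is lower
  because roost slots always fail); valid fixes get isotropic Gaussian
  error (sd 15 m) and export to WGS84 Movebank CSV via the roost UTM
  zone.

Identical (config, seed) gives byte-identical tracks, truth and
rasters.

The persistence parameters (heading noise and core fraction) are not
observable in the emulated campaign's report, so they were calibrated
once against the package's own recovery requirements: with 0.2 rad/s
heading noise and a 0.30 core fraction, the within-patch walk mixes
fast enough that a night's realized search envelope is a stable
function of the patch radius, and the *S(r)* argmax recovers a 400 m
patch to ±50 m in >90% of controlled single-patch nights (one 7-h
bout, 5-min fixes, no dropout — the clean design isolates estimator
behaviour from sampling noise). A plain reflective random walk without
the core attraction was evaluated extensively first: its realized
search envelope varies so much between realizations that the argmax
spread never fell below ~±55 m however tortuosity, bout length and
sampling were chosen — consistent, incidentally, with the ±63 m spread
real campaigns report. Slower-mixing or unconfined foragers should
therefore be expected to yield noisier radii on real data than the
controlled experiment suggests.

What the generator does **not** emulate: nectar depletion and
energetics, multi-bat interaction, memory across nights, terrain
effects on flight, autocorrelated or non-isotropic GPS error, and
fix-quality covariates (altitude-dependent failure). Passing
recovery tests on these tracks shows the estimator chain is correct
and well-calibrated for two-mode central-place movement; it does not
certify performance on behaviours outside that model.

## Problem sizes and runtime

The test suite and the acceptance script size their simulations to
standard desk-scale runs: cohorts of 5–21 nights, recovery experiments
of 100 seeded nights, and 50 random tracks for the brute-force FPT
cross-check (1-s dense resampling with index-scan crossing detection —
an oracle sharing no algebra with the analytic implementation). A
9-hour night simulates in ~40 ms; the full acceptance script completes
in well under a minute of compute per experiment.

## Known limitations

- With 15-min schedules and heavy fix failure a night can retain too
  few defined passage times to select a scale; such tracks are dropped
  from the cohort with a logged warning (mirroring real campaigns'
  unusable tags).
- The linear-gap-bridging convention biases *t(r)* upward across long
  blackouts; an alternative gap-capping rule is deliberately not
  offered to keep the estimator single-behaviour.
- Mode comparison on segment speeds inherits dwell dilution for
  segments spanning roost visits (see Segments above); per-trip
  accounting is the supported remedy.
- The exact Mann–Whitney route refuses ties (scipy's exact method);
  tied per-track means fall back to the corrected normal
  approximation, which is noted in the output.
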