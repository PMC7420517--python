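# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind the package, and what the synthetic-data experiments do
and do not demonstrate.

## Geometry and time

All distances are great-circle (haversine) on a sphere of radius
6,371,000 m (mean Earth radius). At the scale the pipeline operates on —
stops metres to a few kilometres apart — the spherical error relative to an
ellipsoidal geodesic is below 0.5 %, far under the 150 m thresholds that
drive every decision, so ellipsoidal math is deliberately out of scope.
Planar computations (convex-hull area) use an equirectangular projection
about a local origin, which preserves distances to better than 1 % within
~10 km at mid-latitudes; the hull area is computed by shapely on the
projected points.

Stop centroids are arithmetic means of degrees, valid at stop scale; point
sets straddling the antimeridian are rejected with an explicit error rather
than handled, since the study setting is a single urban region.

Timestamps are timezone-aware everywhere. File readers localise naive
timestamps to a configurable zone (default `America/Toronto`, the study
region); comparisons happen on the absolute timeline.

## Stop detection

Thresholds (all strict `<` on the join conditions, `>=` on the dwell
filter):

| parameter       | default | meaning                                             |
|-----------------|---------|-----------------------------------------------------|
| `gap_t_s`       | 180 s   | max gap between fixes of one cluster; min gap that opens a no-signal candidate |
| `min_dwell_s`   | 180 s   | minimum dwell for a cluster to become a stop        |
| `delta_d_m`     | 150 m   | max hop between fixes of one cluster; merge radius (typical urban block) |
| `delta_v_mps`   | 2 m/s   | max in-cluster speed (above older adults' usual walking speed of 0.9–1.3 m/s, with margin for device speed error) |
| `max_gap_jump_m`| 150 m   | max displacement across a signal gap for a no-signal stop |

The time threshold plays two roles (in-cluster gap and minimum dwell); they
default to the same 3 minutes but are independently configurable. A record
that breaks a cluster seeds the next one and is not double-counted. A record
with *absent* speed passes the speed test by default (`strict_speed`
reverses this): speed is a soft criterion — it is ignored entirely for
no-signal stops, whose bracketing fixes may belong to the adjacent trips —
and some devices omit speed on the first fix after standby.

The dwell filter is applied both when clusters close and again after
merging; merged stops inherit the guarantee from their parts. Merged
centroids are member-count weighted (a no-signal stop counts its two fixes),
which approximates the centroid of all underlying fixes and keeps merging
effectively associative. A full-signal cluster and a no-signal stop may
merge; the result is kind `merged`.

A consequence of clustering against the *previous record* (not the cluster
centroid): the last approach fix of a trip, if it lands within 150 m of the
venue at low speed, joins the dwell cluster and shifts the centroid by up to
`delta_d / member_count` — about 2–5 m for typical dwells. Tests account for
this rather than pretending centroids are exact.

## Home inference

DBSCAN over stop centroids (one point per stop, not raw fixes) with
MinPts = 4, the classic recommendation for 2-D data, and k = MinPts for the
k-distance curve. Eps is the value at the geometric knee — the point of
maximum perpendicular distance to the chord joining the curve's endpoints —
chosen for determinism over visual inspection; first index wins ties; a flat
curve returns its common value with a warning. Border points belong to the
first cluster that claims them in seed-scan order, which equals the cluster
whose minimal core index is smallest; this makes the partition fully
deterministic and is what the naive reference oracle in the tests
recomputes.

Cluster selection is by member-stop count, then total dwell, then earliest
first visit (the natural reading of "most visited", with dwell separating a
nightly home from an equally-frequent café). The home coordinate is the
unweighted centroid of member stops.

Known limitation: on short collections (a week) or stop sets whose sorted
4-NN curve has a concave tail, the knee can land on the scattered-stop
plateau, giving an Eps of hundreds of metres and a contaminated home
cluster. This is a property of the knee rule itself; with full 28-day months
the transition dominates and the chosen Eps is tens of metres. The
`eps_override` parameter exists for exactly these cases, and the acceptance
aggregates (median home error) are robust to the occasional bad knee.

## Activity inference

Home assignment precedes POI lookup and uses the DBSCAN Eps as the home
radius (fallback 150 m when Eps is unavailable or degenerate); a stop inside
it is Home unconditionally. Otherwise the POIs strictly within 150 m
(distance ties broken by id) are filtered to those whose opening hours
overlap the stop interval on any day it touches (absent hours = always
open, an empty weekday list = closed that day), mapped to one of eight
out-of-home categories by a fixed place-type dictionary (unknown types fall
through to Other; two Ontario medical-laboratory brand names are matched on
the POI *name*), and scored by the gravity law

    w(POI) = 1 / (d + ε)^γ,    category mass = Σ w over its open POIs,

with exponent γ = 2 (classic inverse-square) and softening ε = 1 m so a POI
coinciding with the stop centroid cannot divide by zero. Summing over POIs
(rather than taking the per-category maximum) makes prevalence count: a stop
surrounded by three cafés and one clinic leans Food even if the clinic is
slightly nearer. Argmax ties are broken by the fixed category order (Food
first). Both γ and ε are configuration, since the functional form is a
modelling choice rather than a law of nature.

## Evaluation

Matching requires temporal overlap (closed intervals touching counts) and
distance < 150 m, one-to-one, greedy in ascending distance; multiplicity is
otherwise unspecified in diary studies, and greedy-nearest is deterministic
and symmetric enough for scoring. True negatives are ill-posed on continuous
time ("no stop extracted or recorded" has no natural unit); they never enter
precision/recall/F1 and are reported as 0 with a pass-through hook. Any
undefined ratio (no predicted or no actual positives) is `None`, never a
silent 0. Global activity F1 is the micro-average over matched stops, which
for single-label stops equals the fraction classified correctly. Walk Score
values are an external input, looked up by nearest tabulated coordinate
within 150 m; the five buckets are the standard published ranges.

## Synthetic worlds

The generator emulates the study conditions: a 28-day collection, 3–6
out-of-home visits per day (uniform), visit durations 30–90 min, nightly
home dwells of at least 8 h, travel in a straight line at 8 m/s (urban
driving; a 1.2 m/s walking speed is available so that the speed gate sees
both sides of δ_v), and a device that samples once per 60 s in motion,
jitters every fix by isotropic Gaussian noise of σ = 10 m (real devices
scatter up to ~15 m), and per dwell enters standby with probability 0.15,
emitting only the two bracketing fixes. Venue choice is uniform over POIs
open at the planned time (rejection sampling), never repeating the previous
venue. POI opening hours are random day-by-day windows (~07–09 h to
17–22 h), 10 % of POIs always open, 10 % of weekdays closed.

The *sparse* layout keeps venues > 320 m apart and > 400 m from home, so
each stop has one unambiguous candidate and the inference ceiling is
F1 = 1.0; the *dense* layout packs ~5 venues per plaza within ~45 m, which
both merges consecutive same-plaza visits into one stop and puts competing
categories inside every search radius. The paired sparse-vs-dense comparison
over identical seeds reproduces the qualitative finding that denser
amenities degrade activity inference; with the defaults the gap is about
0.03 F1.

What passing these experiments does **not** show: robustness to real urban
noise (multipath canyons, forgotten devices, diary omissions), realistic
road networks or transit, multi-purpose venues (the shop under the
apartment, the cinema inside the mall — Home and the gravity argmax win by
construction), or second homes. The generator's diaries are complete and
exact by design, so recall against them is an upper bound on field
performance.

## Problem sizes

The test suite and the acceptance script use 20 seeded months per density
profile at the full 28-day length (~30,000 fixes, ~160 stops per month),
which keeps every oracle comparison exact and the whole run in seconds while
exercising the same regime as a real deployment month.
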