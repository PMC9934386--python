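# Methods

This note documents the models, conventions and numerical choices behind
`gulltrack`, and what the synthetic validation does and does not show.

## Data model and filtering

A fix is one GPS record (bird id, tz-aware timestamp, lat/lon in decimal
degrees, optional altitude in m a.s.l. and battery voltage). Filtering
removes *failed attempts* — rows with latitude and longitude both exactly
zero, the standard failure sentinel of the tag firmware — and *duplicates*,
defined as two rows of the same bird with the same timestamp (the typical
re-upload artifact; identical coordinates at different times are genuine
stationarity and are kept; the first occurrence wins). Filtering is
idempotent and its report satisfies `kept + failed + duplicates = input`.

All calendar bookkeeping uses UTC+9, the local time of the wintering range
where tags were programmed. The monitored span is `(last date − first
date)` in days — the exclusive-end convention; it is the one that
reproduces the printed per-bird day counts of the packaged deployment
table from their start/end dates (e.g. 25 Feb → 26 Oct 2015 prints as
243 days). Birds under 100 days of monitoring are excluded from analyses.
Printed integer means round half away from zero (3357.75 → 3358).

Tag fate at end of monitoring follows a criteria tree: terminal
stationarity (all fixes in the final 5 days within 500 m of their mean —
the radius is a tag-accuracy-scale default, configurable) ⇒ dead or tag
lost; fixes ≤ 80% of the duty-cycle expectation and/or last voltage
≤ 3.9 V ⇒ technical failure; still transmitting at the study end ⇒
censored alive; otherwise unknown.

The per-bird "longest great-circle distance" is the maximum distance
between any summer-band fix and any winter-band fix, by exhaustive chunked
scan.

## Geometry

Distances use the spherical Vincenty (atan2) great-circle formula on the
IUGG mean radius 6371.0088 km; track distances at km precision are
insensitive to the sphere/ellipsoid choice. Mean positions are normalized
3-D unit-vector means. All longitude arithmetic goes through 3-D vectors
or wrapped deltas because the eastern-Siberian corridor approaches the
antimeridian.

Track regularization resamples to exact interval multiples from the first
fix, interpolating linearly in time along the great-circle segment between
bracketing fixes (slerp), never extrapolating; segments spanning more than
7 days are interpolated but flagged so downstream analyses can drop
gap-bridging points.

The Lambert azimuthal equal-area projection is the spherical closed form,
centred by default on the spherical mean of the input fixes. Round-trip
error is well under 1 m within 6000 km of the centre, and planar distances
match great-circle distances to < 1% for separations ≤ 500 km, which is
what the DTW point metric and kernel densities rely on.

## Solar geometry and diel classes

Solar elevation uses the NOAA solar-calculator equation set (Julian
centuries → mean longitude/anomaly, equation of time, declination, hour
angle) plus the standard NOAA refraction correction; it agrees with the
published SPA benchmark case to < 0.01° and with an independently coded
low-precision Astronomical-Almanac algorithm to < 0.05°.

A bout is *night* when the apparent elevation at **both** endpoints (each
at its own place and instant, since the bird moves) is below the
threshold, *day* when both are at or above it, *twilight* when they
disagree. The threshold is signed and defaults to −6°: "below 6 degrees"
with civil twilight intended can only mean the civil-twilight limit, which
is 6° *below* the horizon; a +6° reading would misname civil twilight.
Evaluating both endpoints is forced by the twilight definition itself.

## Bouts

Consecutive-fix legs of 2 h duty-cycle birds are retained if their
duration lies in [1.9, 2.1] h; a bout is a migration bout if it covers
strictly more than 5 km. Bout altitude is the endpoint mean after flooring
negatives at zero; bouts missing an endpoint altitude stay in rate/diel
analyses but not altitude analyses. Months are assigned from the start fix
in UTC+9. Diel compositions are pooled across birds by default (per-bird
weighting available via groupby on the bout table).

Mann–Whitney U and Wilcoxon signed-rank wrappers report a tie- and
continuity-corrected normal z alongside p. Small samples switch to exact
enumeration (tie-safe): all C(n₁+n₂, n₁) rank splits when both groups are
≤ 8; all 2ⁿ sign assignments when the signed-rank n ≤ 15, a cutoff chosen
so the 13-pair paired-season design is always exact. Zero differences are
dropped (Wilcoxon's original treatment).

## Phenology

The daily series assigns each consecutive-fix step to the UTC+9 date of
its start fix and takes the spherical-mean latitude of the day's fixes.
Days with a single fix have zero distance and cannot be active; days
without fixes are absent, not zero-filled. A day is an active migration
day when distance > 60 km (strict) and the daily mean latitude lies in
[40.9, 64.9]°N.

Active days before 7 Jun belong to spring; active days from 1 Jul onward
belong to autumn. The pivot sits inside the observed early-summer
occupancy gap (last spring arrivals in early June, earliest autumn
departures from the breeding range in late July), so the assignment is
unambiguous; the short 7–30 Jun dead zone maps to neither season.

A migratory window spans first to last active day (inclusive duration);
`prop_active` divides the active-day count by that duration, and a
gap-corrected variant divides by days-with-data instead, reported
alongside. The route fraction on active days is the distance summed over
active days divided by the distance over all days in the window.

Season bands — winter 18 Dec–12 Apr, spring 13 Apr–6 Jun, summer
7 Jun–31 Aug, autumn 1 Sep–17 Dec — partition the year; December winter
days carry the following year's winter label.

## Repeatability (DTW) and inference

Daily-normalized positions are cut per bird × season × year and projected
into one shared LAEA plane. DTW is the classic unconstrained recursion
with Euclidean point costs in km, boundary-matched, no warping window, raw
(unnormalized) cumulative cost by default; a path-length-normalized
variant and a great-circle point cost are options. Planar-km costs are
scale-meaningful and antimeridian-safe; the projection choice matters
little at corridor scale.

The within- vs between-individual contrast uses a two-sided permutation
test on the difference of group means with the add-one estimator
`p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1)` (default 10,000
permutations), which cannot return zero and is reproducible by seed; the
pooled values are sorted before permuting so the p-value depends only on
the value multisets, not input order. Timing consistency reports absolute
day-of-year shifts of window endpoints between years, with day-of-year
evaluated on a fixed non-leap calendar so identical calendar dates count
as zero shift across leap years.

## Connectivity

Each bird contributes a breeding centroid (spherical mean of summer-band
fixes) and a wintering centroid (winter-band fixes). Mantel r is the
Pearson correlation of the strictly-lower triangles of the two pairwise
great-circle distance matrices. The 95% CI is a percentile bootstrap over
birds (rows and columns resampled jointly, both matrices rebuilt;
degenerate resamples with fewer than 3 unique birds or zero triangle
variance are redrawn), 1,000 resamples by default.

## Kernel utilization distributions

The UD is an isotropic Gaussian kernel density on the LAEA plane with the
smoothing factor interpreted as the kernel standard deviation (100 km
default, the home-range convention for continental-scale kernels; the
kernel form itself is a design choice documented here). The grid pads the
data extent by 3.5 bandwidths (> 99.7% of each kernel's mass on-grid) and
renormalizes to integrate to exactly 1; isopleths take cells in
decreasing-density order until the requested mass is reached. Daily
positions are restricted upstream to each bird's first tracked year so
individuals weigh equally.

## Synthetic cohorts

Each simulated bird-year is a scripted annual cycle: winter residence →
spring migration along a coastal corridor of waypoints → summer residence
→ autumn migration → winter. Defaults encode the study conditions the
generator emulates: spring departures ~24 Apr (sd 6 d), autumn departures
~25 Aug (sd 15 d), travel-day speeds ~N(300, 50) km/day floored at 120 and
rescaled to the route length, Poisson(1) stopovers of ~3 d in spring
versus Poisson(4) of ~6 d in autumn, 90% of travel days moving in
day/twilight hours (08–20 KST; the rest in evening/night hours), migration
altitudes ~300 m with rare (0.4%) 1000–3500 m excursions over a ~10 m
near-sea-level baseline that can dip negative, 1% failed and 0.5%
duplicate fixes. Birds keep a persistent corridor offset (50 km scale)
across years on top of 10 km yearly waypoint noise — this is what makes
within-individual DTW smaller than between. Fixes are sampled at the duty
cycle anchored at local midnight, so daily sums from fixes equal scripted
daily path lengths up to corner-cutting at waypoint crossings (≲ 2%,
negligible against the 60 km/day classifier margin).

"Positional noise" acts on the track — waypoint jitter and daily stopover
wander — plus a realistic ~30 m per-fix GPS error. Kilometre-scale white
noise on every fix would be unphysical: at a 2 h duty cycle it inflates
daily path sums by hundreds of km and no displacement-threshold method
could recover timing through it.

The generator records its own ground truth (per-day true distance and
mean latitude, derived active-day windows, travel-day diel intent,
injected artifact counts). What passing tests show: the pipeline recovers
scripted timing exactly without noise and to ±1 day under route-scale
noise, recovers artifact counts exactly, and detects individual route
fidelity. What they do not show: robustness to coastline-following
geometry, wind drift, tag clock drift, irregular duty cycles, or
behaviours the script does not generate (nomadism, failed breeding
wanderings).

## Problem sizes and runtime choices

The shipped test suite and analysis scripts use 3–10 birds over 1–2 years
at a 2 h duty cycle (~4,400 fixes per bird-year), 200–1,000 replicates for
calibration checks, 499–999 permutations inside replicated tests and
10,000 for single analyses, 1,000 bootstrap resamples, and 40 replicate
cohorts for the DTW-separation power check — sizes chosen to keep a full
validation run in tens of seconds on one core while leaving every
statistical conclusion comfortably away from its decision boundary.

## Known limitations

- Spherical (not ellipsoidal) geometry throughout; adequate at km
  precision.
- The daily latitude gate uses the day's spherical-mean latitude; birds
  straddling a band edge within one day are assigned by the mean.
- Fate classification is heuristic and threshold-based; it mirrors the
  criteria tree but cannot distinguish death from harness loss.
- The packaged deployment table carries one internal inconsistency of its
  printed source (a text range of 6,531–51,010 km for total distance
  versus a per-row minimum of 1,860 km); per-row values are authoritative
  and the discrepancy is preserved, not resolved.
- Mantel r on a handful of birds has wide bootstrap intervals; the CI, not
  the point estimate, is the deliverable at these sample sizes.
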