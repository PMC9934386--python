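# gulltrack

Analysis pipeline for multi-year GPS telemetry of long-distance migrant
gulls — built around the annual cycle of an Arctic-breeding gull that
travels 4,000–5,500 km between Siberian breeding grounds and wintering
areas at Korea/Japan latitudes.

The package takes raw fix tables (bird id, timestamp, latitude, longitude,
altitude, voltage) and runs the full chain a movement ecologist needs:

- **Filtering** — failed (0/0) location attempts, duplicate uploads, a
  100-day inclusion rule, tag-fate classification, and per-bird /
  cohort track summaries (total km, km/day, longest summer–winter
  great-circle distance).
- **Phenology** — daily displacement series; an *active migration day* is
  a UTC+9 calendar day with > 60 km travelled while the bird's daily mean
  latitude lies between 40.9°N (northern limit of the wintering range) and
  64.9°N (southern limit of the breeding sites); migratory windows span the
  first to last active day per season, individually or population-wide.
- **Bouts** — standardized 2 h legs (1.9–2.1 h retained) with rates of
  travel, flight altitudes (negatives floored at 0, endpoint mean), and a
  day/twilight/night class from apparent solar elevation against the civil
  twilight threshold (−6°); migration bouts cover > 5 km.
- **Repeatability** — tracks normalized to daily positions, cut into four
  season bands, projected to a shared Lambert azimuthal equal-area plane,
  and compared with Dynamic Time Warping
  `D(i,j) = d(a_i, b_j) + min[D(i−1,j), D(i,j−1), D(i−1,j−1)]`;
  within- vs between-individual DTW distributions are tested with
  10,000-permutation randomization of group labels.
- **Connectivity** — Mantel correlation r between the pairwise
  great-circle distance matrices of breeding and wintering centroids, with
  a 1,000-resample bird-level bootstrap CI.
- **Kernel UDs** — seasonal Gaussian kernel utilization distributions
  (100 km smoothing) with smallest-area isopleths.
- **Synthetic cohorts** — a seeded generator that scripts every bird-year
  (departure dates, travel-day speeds, stopovers, diel scheduling,
  altitudes, injected fix artifacts) and records its own ground truth, so
  every stage is validated end to end without field data.

A verbatim transcription of the published 28-bird deployment table ships
with the package (`gulltrack.table1`) and anchors the summary arithmetic.

## Worked example

The numbered scripts under `analysis/` form the narrative pipeline; each
prints what it found and writes tables under `results/` (bulk row-level
intermediates go to `scratch/`). Running them in order:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_filter_summarize.py
python analysis/03_phenology_windows.py
python analysis/04_bouts_diel.py
python analysis/05_repeatability_dtw.py
python analysis/06_connectivity_ud.py
```

prints, among other lines:

```
filtering: 458 failed, 207 duplicate fixes removed; 10 birds kept, 0 under 100 days
published 28-bird table recomputed: 94017 fixes / 10736 days, 48.8 km/day grand mean,
  mean longest distance 3709 (SD 940) km
individual windows: spring median 12 d vs autumn 32 d (paired Wilcoxon z=-2.37, p=0.0117, n=9)
42999 retained 2 h bouts, 1660 migration bouts (5% of migration bouts at night)
rates of travel: migration median 24.3 km/h vs other 0.3 km/h (z=69.2, p=0)
winter : within       686 vs between     57274 (n=18/135, permutation p=0.0001)
migratory connectivity: Mantel r = 0.256 (95% CI 0.08 to 0.76, 10 birds, 1000 bootstraps)
```

Reading these: the filter recovered exactly the injected artifact counts;
the packaged deployment table's printed totals and means are reproduced
from its per-row cells; on the simulated cohort spring migration is
concentrated (fewer stopovers) while autumn stretches roughly twice as
long; migration bouts are far faster and higher than foraging bouts and
happen mostly in daylight; same-bird winters in different years are far
more similar (lower DTW) than winters of different birds.

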