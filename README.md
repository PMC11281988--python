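# lifespace

Tools for GPS-based life-space mobility analysis in cohort studies: daily
out-of-home mobility indicators from raw GPS fixes, home-centered
environmental exposure metrics from vector map layers, and day-level Poisson
mixed models with person random intercepts — plus seeded synthetic-data
generators so the whole pipeline can be exercised against known ground truth.

## What it computes

**Daily mobility indicators** (per person, per mobility day — a day runs
from 03:00 to 02:59 so late-evening activity counts toward the preceding
day; a day is valid with ≥ 8 hours of GPS recording):

- *Time out of home (TOH)*: cumulative minutes spent beyond a 50 m home
  buffer, summing inter-fix intervals whose both endpoints are out of home
  and that do not exceed a gap cap (default 10 min).
- *Convex-hull area*: km² of the convex hull of all of the day's fixes,
  measured in a local azimuthal equal-area projection.
- A reconstructed stop/trip classifier segments each day into dwell and
  movement periods.

**Environmental exposures** around each home: walkable-intersection density
(≥ 3 approaches, 1500 m radius), green-area share of a 500 m disc, and
counts of transit stops / health facilities within a 15-minute walking
radius; questionnaire-derived scores (service utilization, subjective
accessibility, sidewalk quality) coded 0–3.

**Model**: a log-link Poisson GLMM with one random intercept per person,
fitted by Laplace-approximated maximum likelihood (implemented here and
cross-validated against `lme4::glmer`), with Wald inference, ICC and
Nakagawa marginal/conditional R² from the lognormal distribution-specific
variance. Continuous predictors are grand-mean centered; binaries stay 0/1.

## Command line

```sh
# generate a synthetic study (cohort, homes, environment layers, GPS traces)
lifespace simulate --out study/ --seed 1 --n-persons 20

# daily TOH / convex-hull indicators
lifespace metrics --gps study/gps.csv --homes study/homes.csv --out study/

# home-centered exposure profiles
lifespace environment --env study/environment.geojson --homes study/homes.csv \
    --covariates study/cohort.csv --out study/

# Poisson mixed models for both responses + coefficient reports
lifespace fit --covariates study/cohort.csv --out study/

# cohort descriptives table
lifespace report --covariates study/cohort.csv --out study/
```

Inputs are plain CSV (GPS fixes: `person_id,timestamp,lat,lon`; homes:
`person_id,lat,lon[,buffer_m]`), GPX 1.1 tracks, and GeoJSON feature
collections (LineStrings with a `walkable` property, Polygons with
`green_category`, Points with `category`). Every run writes a JSON manifest
with parameters, seed and row counts; reruns with identical inputs are
byte-identical.

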