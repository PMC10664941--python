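# serprisk

Multi-cluster snakebite risk modelling on a synthetic mini-country.

The package builds the full analysis chain used in enumeration-area (EA)
level snakebite risk mapping:

- **`synthetic_landscape`** — seeded generator for a complete test country:
  elevation/landcover/road rasters, ~400 tiled EAs with four planted
  archetypes (urban, peri-urban, commercial/protected, rural-poor),
  per-species habitat-suitability surfaces with occurrence points,
  treating-facility locations, and a case registry whose per-EA counts
  follow a Poisson log-linear model with a planted elevation effect
  (3.8% fewer cases per 100 m by default).
- **`species_richness`** — stepwise VIF pruning of covariates, maxSSS
  (maximum sensitivity + specificity) thresholding of suitability
  surfaces, presence–absence stacking into a richness layer, zonal means.
- **`risk_indices`** — the four composite indices (hazard, exposure,
  susceptibility, resource scarcity): z-transform, hypothetical worst-case
  reference, cosine similarity, rank 1..N, normalization to [0, 1];
  plus landcover fragmentation metrics (edge density, Shannon diversity).
- **`healthcare_access`** — friction surface from landcover/roads/slope
  and exact multi-source Dijkstra travel time to the nearest treating
  facility, aggregated per EA.
- **`risk_clustering`** — seeded, fully deterministic k-medoids profiling
  of the index scores (seeds are the top-ranked EA per index), scored by
  the Calinski–Harabasz pseudo-F with per-variable R².
- **`epi_stats`** — registry validation, tabulations, annual averages,
  relative risk with 95% CI, chi-squared + Cramér's V, and a Poisson
  IRLS log-linear elevation–incidence fit with a population offset.

## CLI

Every stage is exposed under the `serprisk` entry point and reads/writes
plain-text artifacts (ESRI ASCII grids, CSV, GeoJSON):

```sh
serprisk simulate --out run/landscape --seed 1          # synthetic country
serprisk richness --data run/landscape --out run/rich
serprisk access   --data run/landscape --out run/access
serprisk indices  --data run/landscape \
    --richness-csv run/rich/zonal_richness.csv \
    --travel-csv run/access/zonal_travel_time.csv --out run/idx
serprisk cluster  --indices-csv run/idx/risk_indices.csv --out run/clu --k 4
serprisk epi      --registry run/landscape/cases.csv --out run/epi
```

or everything at once:

```sh
serprisk pipeline --out run --seed 1
```

A YAML config file (`--config cfg.yaml`) can override any
`LandscapeConfig` field (grid size, EA count, archetype mix, baseline
case rate, attribute distributions, ...).

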