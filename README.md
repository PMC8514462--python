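# cropdiv

Tested, reusable pipeline for national-scale crop diversity change analysis
from area-harvested production tables:

- **data_ingest** — FAOSTAT-dialect CSV reading, crop-group harmonization
  (cotton merge, palm-kernel rename, five exclusions), country filtering.
- **diversity_metrics** — per-country-year richness (S), Shannon diversity
  (H, nats) and Pielou evenness (J) from harvested-area proportions.
- **segmented_model** — two-breakpoint piecewise-linear trend fits via
  iterative breakpoint relinearization with an SSE-descent safeguard and a
  deterministic local polish, plus an exhaustive integer-grid oracle for
  independent verification.
- **indicators** — onset (first breakpoint), duration (between-breakpoint
  span) and rate (mid-segment slope) per country, with normal-vs-lognormal
  AIC-chosen mean±sd / median±mad summaries (raw m.a.d., no 1.4826 factor).
- **composition_analysis** — Bray-Curtis distances (condensed storage),
  non-metric MDS (Kruskal stress-1, classical-MDS + seeded random starts),
  and sequential PERMANOVA (year as a 1-df numeric covariate, country,
  year×country) with count-based permutation p-values.
- **gradient_models** — quadratic latitudinal richness regressions, peak
  latitude, and indicator-vs-country-area diagnostic regressions.
- **socio_models** — REML mixed models (indicator ~ HDI with region nested
  in continent as random intercepts) and variance partitioning into fixed /
  continent / region / unexplained proportions.
- **synthetic_data** — seeded generators with known ground truth for every
  stage (piecewise richness paths, geometric rank-abundance evenness
  schedules, quadratic latitude gradients, nested socio-economic designs).
- **pipeline / cli** — configuration-driven orchestration with a manifest
  (config hash, seed, row counts, non-converged countries) and deterministic
  reruns.

## CLI

```bash
cropdiv simulate --config config.yaml            # synthetic dataset + truth tables
cropdiv run --config config.yaml --seed 7        # full pipeline -> stage CSVs + manifest
cropdiv fit-country --diversity out/diversity.csv --country Country001 --response S
cropdiv permanova --records out/records.csv --n-perm 99 --seed 0
cropdiv report --outdir out
```

Example config:

```yaml
outdir: out
seed: 7
synthetic:            # or: input: {production_csv: ..., country_meta: ...}
  n_countries: 30
  year_start: 1961
  year_end: 2017
  psi1: 1980.0
  psi2: 1995.0
  richness_sigma: 0.5
init_psi1: 1975.0
init_psi2: 2000.0
overrides: {}         # per-country [psi1, psi2] initials
n_perm: 99
nmds_starts: 4
```

Real-data mode expects a FAOSTAT bulk-download style CSV (columns Area,
Item, Element, Year, Unit, Value; mapping configurable) and a country
metadata CSV with columns `country, latitude_abs, continent, region, hdi`
(optionally `total_area, cultivated_area`).

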