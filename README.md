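# carnivisit

Analysis of community-reported visits of large carnivores — brown bears
(*Ursus arctos*) and grey wolves (*Canis lupus*) — to built-up areas in a
rural mountain landscape, for wildlife managers and quantitative
ecologists working on human–wildlife conflict.

Verified community reports (species, time, location, behavioural event
type, nearby food attractants, foraging outcome) are turned into
evidence about *where* conflicts concentrate and *whether past visits
predict future ones* — the spatial signature of food conditioning:

1. **Ingestion & deduplication** — repeated observations of the same
   individual within 100 m and 6 h are collapsed into a single *visit*;
   exact duplicates are removed first.
2. **Descriptive statistics** — distances to the nearest building and
   forest edge, buildings within 100 m, day/night classification from
   per-day sunrise/sunset, human presence, foraging success, attractant
   and event-type breakdowns per species.
3. **Gridding** — the study area is tiled with 0.01° (~1 km) cells on
   the global lattice; cells with < 75% of their area inside the
   boundary are excluded; visit counts, building counts and forest area
   are computed per cell.
4. **Spatial autocorrelation** — Moran's *I* on per-cell counts with
   row-standardized queen-contiguity weights, randomisation variance,
   one-sided test.
5. **Count regression** — per-species GLMs (log link) of visit counts in
   occupied cells on forest cover, building count and event-type
   indicators; quasi-Poisson scaling when the Pearson dispersion
   indicates overdispersion; backward selection at α = 0.05.
6. **Recurrence models** — counts are aggregated into consecutive 30-day
   windows per cell; three binomial models per species ask whether the
   number of previous reports (all / feeding / damage) predicts at
   least one report in the next window:

   logit P(y<sub>ct</sub> = 1) = β₀ + β₁·k<sub>ct</sub> + b<sub>c</sub>,
   with b ~ N(0, λ·Matérn<sub>ν</sub>(ρ·d))

   a spatially correlated random intercept over cell centroids (ν = 0.5,
   the exponential kernel), fitted by Laplace approximation with
   REML-type estimation of (ρ, λ), and compared by AICc.

A synthetic-data module generates the whole study from scratch — a
valley-village landscape with a target forest fraction and a
self-exciting visitation process in which successful feeding raises the
local visit rate for the next 30 days — so every stage is testable with
known ground truth.

## Worked example

The analysis is organised as numbered scripts over the library:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_descriptive.py
python analysis/03_count_models.py
python analysis/04_recurrence.py
```

which prints (abridged):

```
landscape: 364 buildings in 6 villages, forest fraction 0.57 (target 0.56)
stream: 546 reports over 2023-07-01..2024-06-30 (277 bear, 269 wolf)
546 reports -> 529 unique visits (17 repeated observations removed by the 100 m / 6 h rule)
bear: 97 occupied cells, 2.79 visits per occupied cell
  Moran's I = 0.0025, standard deviate 0.48, one-sided p = 0.317
  dispersion 1.72 -> family quasipoisson; eliminated: ['flag_beehive_damage', 'forest_area_km2', 'building_count']
  final terms: ['intercept', 'flag_anthropogenic_feeding', 'flag_depredation_domestic']
bear: window table with 1067 rows (97 occupied cells)
  all     : slope +0.432 (SE 0.118, p = 0.000251); ...
  feeding : slope +0.963 (SE 0.210, p = 4.51e-06); ...
  damage  : slope +0.833 (SE 0.336, p = 0.0131); rho 73.3, lambda 0.082, AICc 991.6
```

Reading this: per-cell bear counts are overdispersed (Pearson dispersion
1.72), so inference is quasi-Poisson; backward selection keeps the
anthropogenic-feeding and depredation indicators. In the recurrence
stage every extra *successful feeding* event in a 30-day window raises
the log-odds of a report in the next window by ≈ 0.96 — the food
conditioning built into the generator is recovered as the strongest
predictor, with the all-reports and damage slopes positive but smaller.
The fitted probability curves (P of a next-window report vs. number of
previous reports) are written as CSV and PNG under `results/`.

The same pipeline runs from a single YAML config via the CLI
(`carnivisit simulate | ingest | analyze | all`); real data enter as a
reports CSV/GeoJSON plus building, forest and boundary GeoJSON layers.

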