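# Methods

## Problem setting

Community members in a mountainous rural region report sightings of
brown bears and grey wolves in and around built-up areas. Each verified
report carries a species, a timestamp, WGS84 coordinates, one of six
exclusive behavioural event types (depredation on domestic animals,
beehive damage, property damage, foraging on anthropogenic food,
foraging on natural food, other), the set of potential attractants
recorded within 100 m (livestock, beehives, fruit trees/shrubs, wild
ungulates, dogs, waste), whether a foraging attempt succeeded, and
whether a person was present outdoors. The package answers three
questions: what characterises these visits, where do they concentrate
relative to landscape structure, and does the recent history of visits
in a place predict further visits — the operational signature of food
conditioning.

## Visit deduplication

Repeated observations of (presumably) the same individual within 100 m
and 6 h count as one visit. Exact duplicates (same species, location,
timestamp) are dropped first. Clustering is greedy in time order: a
record joins an open visit if it lies within the radius of the visit's
*first* record and within the time window of its *most recent* record;
otherwise it opens a new visit. Anchoring distance to the first record
bounds a visit's spatial extent; anchoring time to the latest record
lets a lingering animal extend its visit. The earliest record represents
the visit. The operation is idempotent and stable under input
reordering, which also makes the pipeline indifferent to whether an
incoming dataset was already deduplicated.

## Geometry and units

All point distances are great-circle distances on the mean-radius
sphere (R = 6 371 008.8 m); point-to-polygon distances and areas use a
local equirectangular projection centred on the geometry. At the scales
involved (100 m buffers, ~1 km cells, study areas of tens of km) the
error relative to the full ellipsoid is far below a metre and immaterial.
The analysis grid is anchored at integer multiples of 0.01° in both
axes, so the tiling is reproducible regardless of the data extent.
Cell area fractions inside the boundary are computed in degree space —
over a single ~1 km cell the metric distortion is constant and cancels
in the ratio.

Day/night classification uses the NOAA solar-position equations with
the conventional rise/set zenith of 90.833° (sun centre at −0.833°,
accounting for refraction and the solar radius). An instant is "day" iff
it falls inside a daylight interval [sunrise, sunset); near the
antimeridian the interval of an adjacent UTC date may apply, so all
three candidate dates are tested. Under polar day/night the sign of the
solar elevation decides. The implementation agrees with an independent
low-precision ephemeris (Astronomical Almanac formulas) to better than
0.5° of elevation, i.e. ~2 min at the boundary.

## Moran's I

Spatial autocorrelation of per-cell counts is tested with Moran's I on
binary queen-contiguity weights (lattice cells adjacent by edge or
corner), row-standardized. The variance is the Cliff–Ord randomisation
form, and the test is one-sided (greater), reported as the standard
deviate (I − E[I]) / √Var[I] with E[I] = −1/(n−1). By default the test
runs on occupied cells only (the analysis set of the count models); an
all-cells mode scores unoccupied cells as zero for sensitivity checks.
Isolated cells are allowed but flagged; a 2×2 lattice is a complete
graph on which I is identically −1/3 and the variance is exactly zero —
the deviate is then undefined and reported as NaN.

## Count GLMs

Per-species visit counts in occupied cells (counts ≥ 1, modelled as
plain counts without zero truncation) are regressed on forest area per
cell (km²), building count, and binary event-type indicators
(anthropogenic feeding, depredation on domestic animals, plus beehive
damage for bears and wild-ungulate killing for wolves). "Killing wild
ungulates" has no dedicated event category; it is operationalised as a
natural-food foraging event with wild ungulates among the attractants.
Fitting is IRLS (via statsmodels) with a log link. The Pearson
dispersion (χ²/df) chooses the family when unspecified: quasi-Poisson
above 1.5 (SEs scaled by √dispersion, t statistics on n − p df),
Poisson otherwise (z statistics). Pairwise covariate correlations are
reported before modelling. Backward selection repeatedly drops the
highest-p covariate above α = 0.05 and refits; ties within 1e−12 drop
the later covariate in declared order, the intercept is never dropped,
and full elimination returns a flagged intercept-only fit.

## Recurrence model

Visits are aggregated into consecutive, non-overlapping 30-day windows
anchored at the study start; the final partial window is dropped. For
each occupied cell and window t = 1..T−1 the table records the number
of reports in t (all; feeding = depredation, beehive damage or foraging
with successful food access, where depredation and beehive damage imply
success by definition; damage = depredation, beehive damage or property
damage) and whether any report occurred in window t+1. The event-class
map is configurable.

The model is a logistic regression with a spatially correlated random
intercept over cell centroids:

    logit P(y_ct = 1) = beta0 + beta1 * k_ct + b_c
    (b_1..b_q) ~ N(0, lambda * C),   C_ij = Matern_nu(rho * d_ij)

with d the Euclidean distance between centroids in decimal degrees
(rho is therefore an inverse range in 1/degree), nu fixed at 0.5 (the
exponential kernel) by default. The marginal likelihood is approximated
by Laplace: for candidate parameters the random-effect mode is found by
damped Newton iteration (the Hessian is diagonal-plus-Σ⁻¹, solved by
dense factorisation) and the Gaussian curvature correction applied.

Estimation is multi-start (three starts over log ρ, log λ) bounded
L-BFGS-B. By default the covariance parameters maximise a REML-type
restricted objective — the Laplace marginal log-likelihood minus half
the log-determinant of the fixed-effect information — after which β is
re-estimated from the unrestricted objective at the fitted (ρ, λ).
Pilot simulations at the package's canonical recovery conditions showed
the plain ML variance component biased low by roughly 40%, which
deflates the intercept's standard error; the restricted objective
removes this bias (mean λ̂ ≈ 0.30 at truth 0.3). `method="ML"` is
available for comparison. AICc is computed from the unrestricted
marginal log-likelihood with p = (fixed effects) + 2 covariance
parameters.

Standard errors: fixed effects use the Schur complement of the joint
Hessian at the mode (equivalently the GLS information, which includes
the field's contribution), replaced by the full 4×4 numeric-Hessian
version when it is positive definite so that covariance-parameter
uncertainty propagates into β; log ρ and log λ get delta-method SEs
from the same Hessian. λ estimated at its lower bound (1e−8) means "no
spatial effect" and is flagged, as is ρ pinned at a box bound
([0.5, 1e4] per degree — below 0.5/degree the field is effectively
constant and confounded with the intercept). Flagged covariance
parameters should not be interpreted.

Predicted recurrence probabilities are fixed-effects-only:
inverse-logit(β₀ + β₁k), the random effect at its zero mean.

### Parameter recovery

The canonical self-check simulates directly from the model — 200 cells
on a 20×10 lattice, 11 windows per cell, β₀ = −1.4, β₁ = 0.3, λ = 0.3,
ρ = 25, ν = 0.5, previous-report counts Poisson(1) — and refits. The
lattice spacing is 0.02°, chosen so the correlation range 1/ρ = 0.04°
spans two lattice steps and the extent about ten ranges, a design in
which (ρ, λ) are identifiable. Coverage of ±2 estimated SEs (log scale
for ρ and λ) is required to reach 90% per parameter across 50 seeded
replicates in the acceptance suite.

## Synthetic data generator

The generator emulates the study system — a ~10 × 10 km mountain
municipality observed for 12 months (July–June) — with no claim that
its parameters are estimates of anything; no quantitative visitation
model exists to calibrate against, so all values below are free design
choices, fixed once.

*Landscape.* Buildings are Gaussian scatters (σ = 0.004°) around 6
village centres with Poisson(60) buildings each, inside an extent of
0.14° × 0.09°. Forest is a union of random circular patches grown until
the realized fraction reaches the target (default 0.56, matching a
heavily forested mountain region); the overshoot is at most one patch
(~4%).

*Attractants* are static per-cell site properties drawn once: waste,
dogs, livestock and beehives are concentrated in built-up cells
(presence probabilities 0.50/0.45/0.30/0.12 vs 0.05/0.05/0.05/0.02
in unbuilt cells); fruit trees and wild ungulates are widespread
(0.35/0.20 and 0.25/0.40).

*Visitation process.* Time is discretised daily. The expected number of
visits in cell c on day d is

    baseline * exp(sum of attractant effects in c)
             * exp(gain * min(S_cd, cap))

where S counts successful feeding events in c in the preceding 30 days
(hard memory window, matching the 30-day analysis windows). Defaults:
baseline 0.003 visits/cell/day, conditioning gain 0.8, cap 3. The cap
reflects saturating conditioning and keeps the self-exciting process
subcritical — without it the feedback explodes. With gain 0 and no
attractants the process is exactly Poisson, which anchors the analytic
tests. Each visit gets an event type and outcome from its cell's
attractants (depredation and beehive damage occur only as successes;
foraging succeeds with probability 0.55 for bears, 0.50 for wolves), a
timestamp drawn day/night with species day fractions 0.69 (bear) and
0.52 (wolf) and uniformly within the chosen period using the actual
sunrise/sunset at the location, and uniform coordinates within its
cell. Conditioning runs on all true visits; each visit is then
*reported* with detection probability 0.8, and with rate 0.03 a second
witness files a near-duplicate report (≤ ~50 m jitter, within 2 h),
giving the deduplication stage realistic work.

*What the generator does not emulate*, hence what passing tests do not
show about field data: within-cell placement is uniform rather than
building-biased, so distance-to-building statistics are much larger
than in real report streams whose very definition is proximity to
buildings; reporting probability is spatially homogeneous (no
municipality effects, media attention or observer heterogeneity);
species are independent; there is no animal movement, home-range or
pack structure, and no seasonality in the baseline rate.

## Numerical choices

- IRLS convergence 1e−10 (statsmodels default iterations capped at 100);
  backward-selection ties broken deterministically.
- Laplace inner Newton: step damped to max-norm 5, convergence 1e−9,
  60 iterations; covariance jitter 1e−10 on the diagonal.
- Outer L-BFGS-B: ftol 1e−10, numeric gradient step 1e−5, bounds
  log λ ∈ [log 1e−8, log 1e3], log ρ ∈ [log 0.5, log 1e4]; numeric
  Hessian step 1e−3.
- Moran variance can be numerically non-positive for extreme kurtosis at
  tiny n; the deviate is then NaN rather than a spurious number.
- Grid fraction threshold applies with a 1e−12 tolerance so that an
  exactly-half cell is retained at min_fraction 0.5.

## Problem sizes

Default test and acceptance runs use a 126-cell landscape over 12
months (~550 reports), 50-replicate simulation studies for power and
coverage, and the 200-cell × 11-window recovery design; these sizes
were chosen to make the Monte-Carlo error small relative to the margins
they are tested against while keeping a full run of the suite in the
low minutes on a single core.

## Known limitations

- The Laplace approximation for binary data with few observations per
  cell can bias variance components; REML-type estimation mitigates but
  does not remove this, and λ/ρ from sparse tables (many cells with all
  zeroes) frequently land on a flagged boundary.
- The Matérn field uses degree-space distances; at mid-latitudes a
  degree of longitude is ~35% shorter than a degree of latitude, so ρ
  mixes the two axes. A metric-projection option would remove this
  anisotropy.
- GeoPackage input is not supported (GeoJSON only), and no raster
  land-cover handling exists.
- Backward selection inherits all the usual caveats of stepwise
  inference; the reported p-values of the final model are conditional
  on the selection path.
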