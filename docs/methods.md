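# Methods

This note documents the models, defaults and design choices behind
`seasonniche`, in the order the pipeline runs them.

## Data model and conventions

All analyses live on a single geographic lon/lat grid; reprojection is out
of scope. Row 0 is the northernmost row and cells are half-open, so a point
on a shared edge belongs deterministically to the cell to its south-east —
a convention that matters only for records digitized exactly on cell
boundaries, and which is therefore stated once here and enforced in
`GridSpec.cell_of`. Rasters are read and written as ESRI ASCII grids or
single-band GeoTIFFs; GeoTIFF georeferencing uses the
ModelPixelScale/ModelTiepoint tags and the GDAL nodata tag via `tifffile`.

Records carry a month and a season label. The default month→season map is:
May–July breeding, December–February winter, April and September–November
migratory, March and August excluded (transitional months that cannot be
assigned with confidence). The breeding *model* is fitted on May–June
layers only — the months of peak breeding suitability — while July records
keep the breeding label; whether late-summer records should enter the model
is genuinely ambiguous in field datasets, and the map is a plain
configuration dict for that reason. Deduplication keeps at most one record
per (cell, season), retaining the earliest in input order; records outside
the grid are dropped with a warning rather than an error because curated
datasets routinely contain strays. Multi-month climate extraction uses the
arithmetic mean over the season's months (configurable to per-month
extraction).

## Synthetic study system

The generator emulates a mid-latitude monthly climate and a migratory
grassland bird sampled over it.

Climate: `tmax(m, row, col) = base + gradient·row + A·cos(2π(m−7)/12) +
smooth noise`, with the noise field drawn once per variable and held fixed
across months (season means then inherit one spatial texture).
Precipitation has its own latitudinal and longitudinal gradients, seasonal
amplitude and phase, and is clipped at zero (clips are logged). tmin is
tmax minus a diurnal range that itself has a longitudinal gradient and
smooth texture. Two of these choices deserve emphasis because simpler
alternatives fail structurally:

* With latitude as the only spatial gradient, the set of realized
  (tmax, tmin, prec) combinations in any one month is a one-dimensional
  curve, and the breeding-season and winter-season curves are *parallel,
  non-intersecting* lines — summer is warmer and wetter while south is
  warmer and drier, so no climate combination exists in both seasons and a
  "niche follower" would be unrealizable by construction. The
  longitudinal precipitation gradient widens the realized climate to a
  2-D sheet whose seasonal copies genuinely intersect.
* A constant diurnal offset makes tmax and tmin exactly collinear, which
  collapses the three-variable polar projection (below) onto a line and
  gives every hull zero area. The spatially varying diurnal range breaks
  the collinearity the way real climatologies do.

Default parameter values (10 °C base with 0.25 °C/row, 8 °C seasonal
amplitude, 140 mm base precipitation with −0.8 mm/row and +1.2 mm/col,
10 mm seasonal amplitude, ~10 °C diurnal range, smooth noise of 1 °C / 4 mm
with 6-cell correlation length) were chosen once as plausible mid-latitude
magnitudes whose latitudinal span dominates the seasonal cycle, so that
both seasons realize a shared climate volume on the default 120 × 120 grid.

Occurrences are drawn without replacement, cell by cell, with probability
proportional to a diagonal-Gaussian suitability in climate space
(`spread` defaults: 1.5 °C, 1.5 °C, 6 mm) — drawing without replacement
mirrors the dedup rule, so generated data are already spatially unique.
Record counts default to 246 breeding, 83 winter and 28/20/33/15 for
April/September/October/November — the scale of a curated occurrence set
for a grassland migrant of conservation concern.

Scenarios: *follower* gives both seasons one centroid; *switcher* places
the centroids `delta` Mahalanobis units apart. The centroid anchor is the
midpoint of the two seasons' realized climate intersection, snapped to
actually realized cell climates, and the switcher offset runs along the
realized climate-gradient direction — an offset split evenly across
variables (the obvious alternative) points off the realized climate sheet,
so requested separations would be unattainable and centroid recovery
biased. Migratory records sit at the midpoint between the two seasonal
centroids, i.e. `delta/2` units from each.

What the generator does **not** emulate: coastlines and topography,
spatial autocorrelation beyond smooth noise, observation bias toward
roads/settlements, temporal trends, and interannual variability. Passing
tests therefore demonstrate that the pipeline recovers known structure
under clean sampling — not that any particular field dataset would behave
as cleanly.

## Rule-set niche models

The per-season model is an ordered rule list — climatic range boxes,
negated boxes and logistic rules, each predicting presence or absence; the
first matching rule wins and the default class is absence. Rules are
evolved by a genetic algorithm (population 40, ≤ 25 generations, elite
fraction 0.25, point mutation of bounds/coefficients, per-variable
crossover, constraint insertion/deletion, stop on 5 stagnant generations).
This is a from-scratch implementation in the spirit of classic genetic
rule-set algorithms; no attempt is made to be bit-compatible with any
historical tool, and all downstream claims about it are property-based.

Two details control the commission bias such models are prone to:

* **Balanced fitness.** Rule fitness is the z-score of the rule's accuracy
  gain over prior prevalence on an internal held-out split in which
  presence and background are balanced ~1:1. At raw prevalence (a few
  percent presence) the z-score grows with matched count almost regardless
  of accuracy, and indiscriminately wide rules win.
* **Forward selection.** The final rule set is assembled in fitness order,
  admitting a rule only if the evaluation points it newly claims improve
  held-out balanced accuracy. Without this, low-fitness broad presence
  rules (logistic half-spaces especially) enter late, claim every cell no
  earlier rule matched, and the model over-extrapolates grotesquely under
  transfer.

The calibration **background** defaults to 10 000 cells sampled from the
whole accessible landscape (all valid cells of the season's layers).
Restricting background to the records' bounding box leaves rule bounds
unconstrained outside it; the models then extrapolate freely when
projected, which defeats the transferability analyses. **Commission** for
best-subsets selection is still measured over the tighter modeling region —
a bounding box around the season's records buffered by 10 % of its span —
since commission is meant to describe over-prediction *within* the area the
species could plausibly reach.

Best subsets: of 100 seeded replicates, keep those with training omission
≤ 0.10, then the 10 whose commission is closest to the survivors' median
(ties: lower omission, then replicate index). Agreement (0–10 votes) is the
suitability surface; the binary map thresholds agreement at the majority
(⌈k/2⌉, configurable) — some consensus rule is needed and majority is the
least surprising. An 80/20 calibration/evaluation split (seeded,
`round(0.8·n)`) precedes fitting.

## Partial ROC

The curve plots sensitivity (1 − omission on test records) against the
proportion of region cells predicted present, one point per distinct
agreement value, restricted to sensitivity ≥ 1 − E. E defaults to 0.05 and
is logged in every result. The AUC ratio divides the trapezoid area under
the restricted curve by the area under the 1:1 chance line over the same
interval (boundary crossing linearly interpolated), giving values in
[0, 2] with 1 = chance; the statistic depends only on the ordering of
agreement values, hence is invariant under monotone transforms. The
bootstrap resamples 50 % of test points with replacement 1000 times;
p = fraction of bootstrap ratios ≤ 1. Degenerate inputs: a region with a
single agreement value *is* the chance line and scores exactly 1; the
ratio errors only when the restricted interval has zero chance area (e.g.
E = 0 with all test points at the region minimum), where it is genuinely
undefined.

## Niche structure

Climate over the predicted-presence cells is standardized per variable
(sample, n−1 convention, recorded in the output); the centroid is then the
zero vector, and DC is the Euclidean norm of the standardized row. The
square root is applied to the sum of squares deliberately: only the metric
version supports the monotonicity properties the zone classification
relies on. Zones use contiguous bins [0, b₁], (b₁, b₂], (b₂, ∞) with
defaults b₁ = 1.515, b₂ = 2.95 — breakpoints of this kind are data-derived
in any particular study, so they are plain parameters, and an `"auto"` mode
splits the observed DC range into three equal-width bins. Values beyond
any nominal upper band still classify as marginal so classification is
total. Records are classified with their own month's climate by default
(season-mean optional) against the *season's* standardization; records
outside the modeled climate envelope simply receive large DC.

## Polar-coordinate breadth

Variables are min–max scaled over the union of the stages being compared
(shared scaling is what makes two stages comparable; raw units would let
precipitation dominate), then projected as force vectors at fixed angles —
evenly spaced in the order tmax, tmin, prec by default; breadth is
invariant to a global rotation of the angle map, and the default is
recorded in every output. The occupied area is the alpha-shape (union of
Delaunay triangles with circumradius ≤ alpha), which converges to the
convex hull as alpha → ∞. Alpha defaults to 6× the median nearest-neighbor
distance of the cloud: small multipliers (≈ 2×) fragment realistic clouds
into near-zero-area dust, while the area curve is flat between roughly 6×
and the convex hull, so 6× captures genuine concavity without
fragmentation. Overlap rasterizes both hulls on a shared lattice (default
100 × 100 over the joint bounding box, cell counted if its center is
inside) and reports directional percentages plus occupied-cell counts
("pixels").

## PCA-env similarity

The comparison space is a two-axis PCA of the pooled, standardized
backgrounds of both groups (axis signs fixed so each axis's
largest-magnitude loading is positive, for cross-run determinism), with a
100 × 100 score lattice covering all background scores plus a 5 % margin.
Occupancy is the Gaussian-KDE occurrence density divided by the
availability density (occurrence densities must be read against how much
of each climate exists), zeroed where availability is below 10⁻⁶ of its
peak, and rescaled to sum to one. The occurrence bandwidth defaults to
Silverman's rule; the availability surface is always smoothed with its own
Silverman bandwidth, because sharing a narrow occurrence bandwidth punches
holes in the availability surface and the ratio explodes in them.
Availability backgrounds larger than 4000 points are deterministically
subsampled for the KDE (cost is linear in support size; the density
estimate is insensitive at that count).

Schoener's D = 1 − ½ Σ|z₁ − z₂| ∈ [0, 1]. The similarity test replaces the
focal group's records with an equal-size draw from the pooled records of
both groups (records, not grid cells — the null randomizes identity, not
climate), recomputes D against the other group's fixed occupancy 100
times, and reports p = (1 + #{D_null ≥ D_obs})/(n + 1) — the add-one
convention keeps p > 0 at finite replicates. Small p therefore means "more
similar than random relabelling", matching the similarity (not
equivalency) reading of the test; for identical niches the null is
centered at or above the observed D and the test essentially never
rejects, which is exactly the calibration property the acceptance suite
checks. Both directions are runnable; D itself is symmetric, only the null
differs.

## Pipeline and determinism

`run_pipeline` executes: season assignment → dedup → per-season 80/20
split, 100 GA replicates, best-10 selection, prediction, partial ROC →
inter-season and migratory-month projections with directional overlap
tables (a projection predicting no area prints NA) → niche structure and
record zone classification → polar breadth and hull overlap → PCA-env
similarity in both directions → monthly climate profiles (five-number
summaries per variable). One global seed derives per-stage seeds by
hashing the stage name (all below 2³¹), so stages are independently
reproducible; reruns of one config produce byte-identical summary JSON.
Floats in the summary are rounded to 9 decimals purely for stable
serialization.

The reference analyses (acceptance script and heavyweight tests) use the
default conditions — 120 × 120 grid, default record counts, 100 replicates,
1000 bootstrap and 100 randomization replicates; the determinism check uses
a 70-cell grid with 30 replicates, which exercises the identical code path.

## Known limitations

* The GA is a documented approximation of genetic rule-set modeling, not a
  reimplementation of any specific historical tool; absolute suitability
  maps differ from other implementations even where the property-level
  behavior matches.
* Breadth and overlap numbers depend on the angle assignment, scaling and
  alpha; they are comparable within one configuration, not across
  packages.
* The similarity null resamples records only; a cell-based null would
  answer a different question.
* `prec ≥ 0` clipping can create a zero plateau under extreme generator
  settings, which weakens the climate-manifold geometry the scenarios rely
  on; defaults keep precipitation strictly positive.
* Only two PCA axes and 2-D breadth are supported; volume-based (d > 2)
  measures are out of scope.
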