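# Methods

## The scientific problem

*Lobelia inflata* flowers can complete self-fertilization inside the fused
anther tube; an exserted style/stigma is required for outcross pollination.
Community-science photographs allow the presence and count of
style-exserted flowers to be scored on individual plants across whole
species ranges. The pipeline models (i) the probability that a plant shows
any exserted style as a function of geography and phenology, and (ii) the
number of exserted flowers among outcrossing-capable plants, and compares
exsertion frequency among five congeneric species. The package operates on
already-scored records; photograph interpretation, occurrence-database
retrieval, and elevation-raster lookup are out of scope (elevation is an
input column).

## Record model and inclusion cascade

A record is one scored plant: species, WGS84 decimal-degree coordinates,
date, exsertion score (`present` / `possible` / `absent` / `unscorable`),
counts of clearly visible and style-exserted flowers, fruit presence
(`yes` / `no` / `unscorable`), sex, and optional GPS accuracy and elevation.
Structural invariants (coordinate bounds, exserted ≤ visible, `present` ⟺
exserted ≥ 1 where both are recorded, `unscorable` ⟹ zero visible flowers)
are enforced at parse time; invalid rows become named diagnostics, never
silent drops. A `present` record with an unrecorded exserted count is kept
for the binary model and excluded from the count model, preserving maximal
n for each.

The inclusion cascade removes, in a fixed order, records with missing
coordinates; female or unknown-sex records of the two gynodioecious
species (*L. siphilitica*, *L. spicata* — females show exserted styles by
construction and are uninformative about hermaphrodite outcrossing);
`possible` and `unscorable` scores; unscorable fruit; zero visible flowers;
and (optionally) missing elevation. The count model additionally requires
`present`. Each record is charged to the first failing rule, so the audit
report closes exactly (n_input = n_retained + Σ removals) and the cascade
is idempotent. The published analysis does not state a removal order; the
fixed order here is a reproducibility choice and only affects how
multiply-ineligible records are attributed, not the retained set. The
published single-species binary and count sample sizes are not fully
derivable from the printed per-category counts; this cascade is a
documented reconstruction.

GPS accuracy is carried but never filtered on. Observations containing
several distinct plants can be split into per-plant records sharing
coordinates and source id.

Descriptive summaries report per-species score counts; the presence
fraction is present / (present + absent), excluding the uncertain
categories, and the obstructed fraction is unscorable / total.

## Range marginality

A species' range is summarized from **all** coordinate-bearing records of
the species (before trait filters): the center is the arithmetic mean of
longitudes and latitudes, and the margin is the convex hull of the raw
coordinate pairs. For a point *p*,

r = d_center / (d_center + d_margin),

with d_center the haversine distance to the center and d_margin the
minimum great-circle distance to the hull boundary. r is exactly 0 at the
center and exactly 1 at hull vertices, and lies in [0, 1] everywhere
because both distances are non-negative.

Numerical choices:

- **Hybrid planar/geodesic geometry.** The hull is computed planar on raw
  (longitude, latitude) pairs while distances are geodesic on a sphere of
  radius 6 378 137 m (configurable). This mirrors the standard geospatial
  toolchain for this statistic (planar `chull`-style hulls combined with
  geodesic distance-to-polyline kernels) rather than a fully spherical
  hull.
- **Edge kernel.** Distance from a point to a hull edge is the cross-track
  distance (via 3-D unit-vector projection) when the perpendicular foot
  lies within the arc, otherwise the distance to the nearer endpoint;
  endpoint distances are always candidates, which makes the vertex case
  exactly zero in floating point. Distance to the boundary is unsigned:
  interior and exterior points are treated alike.
- **Degenerate input.** Fewer than three distinct non-collinear points, or
  a longitude span above 180° (antimeridian wrap), is an error; the five
  species' ranges are continental and do not wrap.

## Covariates and standardization

Numeric predictors are z-scored with the sample (n−1) standard deviation
so fitted effects are comparable per-SD. Standardization parameters are
always estimated on the model's own fitting subset (the binary and count
subsets are standardized separately, as they are separate models) and are
serializable so prediction grids reuse fitting-time parameters exactly.
Day of year is 1-based (up to 366 in leap years) and, in multi-species
models, z-scored within species (group-centered) to absorb between-species
differences in flowering season; in single-species models group-centering
reduces to the plain z-score. The fruiting flag stays a raw 0/1 indicator.
Species enter via indicator coding with *L. inflata* as the reference
level — a presentation choice only, since marginal means are
level-symmetric.

The four designs are:

| model | response | predictors |
|---|---|---|
| geo_binary | 1{exsertion present} | z_latitude, z_marginality, z_longitude, z_elevation, z_day_of_year, fruit |
| geo_count | n exserted (present records) | geo_binary set + z_total_visible_flowers |
| species_binary | 1{exsertion present} | species indicators, group-centered z_day_of_year, fruit |
| species_count | n exserted (present records) | species_binary set + z_total_visible_flowers |

## Inference

GLMs (binomial-logit, Poisson-log) are fitted by iteratively reweighted
least squares (50-iteration cap, deviance tolerance 1e-10) with covariance
from the inverse Fisher information; dispersion is fixed at 1 for both
families, with the Pearson χ²/df reported as an overdispersion diagnostic
but not modeled. The count model is an ordinary Poisson fit on the
present-only (response ≥ 1) subset — a faithful-replication choice rather
than a truncated likelihood, so its intercept absorbs the truncation.
Quasi-separation (any fitted |η| > 30) and rank-deficient designs are
errors with guidance rather than silently unstable fits.

Inference is Wald-type: z = β/SE against the standard normal. All
intervals are 95%. Prediction surfaces and estimated marginal means are
computed on the link scale — η with SE(η) = √(xᵀΣx) — then inverse-linked,
giving intervals that are asymmetric on the response scale and always
admissible. Non-focal numeric predictors are held at their fitting-subset
means (z = 0) and the fruiting indicator at the pooled fruiting
proportion; grid values outside the fitted range are predicted but flagged
as extrapolation.

Pairwise species contrasts are differences of marginal means on the link
scale. Multiplicity adjustment is the single-step multivariate-normal
method (the GLM analogue of the Tukey HSD): the adjusted p of contrast j
is P(max_k |Z_k| ≥ |z_j|) under the contrasts' estimated correlation
matrix, computed by Monte Carlo with 100 000 draws and a fixed seed
(20231127) so adjusted p values are reproducible; sampling uses an
eigendecomposition because the contrast space has rank k−1 and the
correlation matrix is singular for k ≥ 3. Adjusted p values are clamped to
be ≥ raw p. Bonferroni is available as a deterministic fallback.

## Synthetic generator

The generator emulates the data-generating structure the models assume,
with known parameters, per species: locations uniform in a range polygon
(rejection sampling; >99% rejection is an error); dates uniform in a
species season window; elevation linear in latitude plus Gaussian noise;
fruiting Bernoulli with logit linear in standardized day of year; visible
flowers V = 1 + Poisson(λ_V); presence Bernoulli with logit η = β·x where
x is built exactly as the design builder standardizes covariates
(marginality is computed by the package's own geometry on the realized
cloud); and, given presence, an exserted count min(V, zero-truncated
Poisson(exp(γ₀ + γ₁ z_V))). Contamination is applied last: records become
`possible` (count withheld) or `unscorable` (all flowers obstructed, V set
to 0) with configured probabilities, and gynodioecious species get females
(forced `present`) at a configured rate. Generation is deterministic given
the seed, with fixed per-species substreams.

Defaults are chosen to mirror the real study's conditions: the presence
coefficients default to the fitted binary-model values of the real
analysis (−1.448, −0.644, −0.222, 0.286, 0.010, −0.168, 0.256) and the
count slope to 0.326; per-species sample sizes follow the real record
totals (3892 / 500 / 1153 / 500 / 1448); species intercept offsets place
expected exsertion fractions near the observed 0.21–0.77 spread;
contamination defaults (8% possible, 27% unscorable) match the pooled
observed fractions. The count-model intercept defaults to 0.30, which puts
mean counts in the observed 1.4–4.6 flowers-per-plant range (the published
count-model intercept as printed is not internally consistent with the
published predicted counts, so it is not used as a generative default).
λ_V = 2.0 is a convenience default: no empirical distribution of
visible-flower counts per image is available. The range polygons are five
overlapping rectangles between 26° and 52° N — qualitative placeholders
for continental ranges, not mapped range data. The female frequency
default (0.2) is a typical gynodioecious female frequency, chosen in the
absence of printed values.

What the generator does **not** emulate: spatial clustering of observers,
detection bias beyond the two contamination rates, per-species
contamination differences, spatial autocorrelation of traits, and
phylogenetic structure. Passing recovery tests therefore demonstrate that
the pipeline correctly recovers effects under the assumed hurdle
structure, not that the real data meet those assumptions.

## Calibration experiments

`recovery_experiment` repeats generate → filter → design → fit and reports
per-coefficient bias, RMSE, 95% CI coverage, and Wald rejection rates,
excluding (and counting) non-convergent replicates. The suite's
calibration study uses a single-species configuration with contamination
and gynodioecy off so that the fitted n equals the configured n = 2000,
with 200 replicates — sizes at which the full study runs in well under a
minute on one CPU. Under the capped, truncation-ignoring count fit the
visible-flower slope is expected to be attenuated; the experiment reports
this attenuation rather than asserting unbiasedness.

## Known limitations

- The marginality statistic inherits the planar-hull approximation; for
  very high-latitude or antimeridian-spanning ranges a spherical hull
  would be needed (unsupported by design).
- Wald inference and fixed dispersion understate uncertainty under
  overdispersion or spatial autocorrelation; the Pearson diagnostic is
  reported but not acted on.
- The count model's intercept is not comparable across subsets because the
  zero-truncation is handled by subsetting, not by a truncated likelihood.
- The inclusion cascade is a reconstruction of the published filtering;
  exact published sample sizes may not be reproducible from category
  counts alone.
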