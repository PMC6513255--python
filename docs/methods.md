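# Methods

This note documents the models, the parameters that matter, the synthetic
data the package validates itself on, and the numerical choices that were
genuinely open.

## Pipeline model

The pipeline estimates a species' range from presence-only records and a
stack of co-registered gridded predictors. Its assumptions, in order of
appearance:

- **Records are usable at cell resolution.** Pseudo-replicates (one nest or
  individual reported by many observers) are collapsed to at most one
  breeding and one non-breeding record per grid cell, earliest date first,
  then lowest id (undated records lose ties). Identity of individuals is
  unknowable from coordinates, so the cell is the defensible dedup unit at
  analysis resolution. Whether a breeding record should also suppress
  non-breeding records in the same cell is genuinely open; the two-slot
  rule was chosen and is isolated in `dedup_pseudoreplicates`.
- **The study area is a latitude cap.** Cells (and records) north of 40°N
  are masked; the bound is inclusive (lat = 40.0 is kept), a one-cell
  convention at most.
- **Observer bias is density-shaped.** Detection probability is assumed to
  increase with human population density. The correction — drawing
  pseudo-absences with density-proportional weights — cancels the
  *systematic* part of such a bias in the presence/absence contrast. It
  cannot restore information lost when sampling effort concentrates
  spatially; see Limitations.
- **Pseudo-absences live outside the occupied envelope.** A one-class SVM
  (RBF kernel) on the standardized presence environments defines the
  envelope. The rejection parameter nu is tuned by bisection until the
  training inclusion lies in [0.90, 0.96]; if a kernel width caps below the
  band for every nu (which happens on small, tightly clustered presence
  sets), gamma is relaxed by factors of 4 up to 64x and the bisection
  repeated. The achieved inclusion is recorded on the model.
- **One pseudo-absence per cell, never on a presence cell,** drawn without
  replacement; equal count to presences. If all eligible cells have zero
  density the sampler falls back to uniform weights with a warning rather
  than dividing by zero.
- **Pseudo-absences are drawn once per pass** and shared by all seven
  model families (not redrawn per family): this is an assumption, flagged
  here, made so that family AUCs are comparable on an identical design.

## Variable screening

PCA on the standardized screening sample (presence plus pseudo-absence
environments). Each variable is ranked by the eigenvalue of the component
on which its absolute loading is maximal (ties: larger |loading|, then
input order) — "scan variables in order of eigenvalue" is otherwise not
well-defined, since variables have loadings rather than eigenvalues; the
chosen reading yields a total order and is recorded in `scan_order` for
audit. The greedy scan retains a variable iff its Pearson |r| with every
already-retained variable is ≤ 0.7 (exactly 0.7 retains; only strictly
greater excludes). Pearson, not Spearman, as the SDM-literature default.
Constant columns are excluded before PCA with a warning. The screen runs
once, on the all-records design, and the retained set is reused for the
breeding-only pass so both consensus maps live in the same feature space.

## The seven families

All families train on the 80% partition of the balanced design (stratified
seeded split; `round(0.2 * n)` held out per class) and score in [0, 1].

- **bioclim** — climatic envelope. Per variable, with F the midpoint-rank
  ECDF of presence training values, a query scores `1 − 2|F − 0.5|` inside
  the training min–max and 0 outside; site score is the minimum over
  variables. Presence rows only. A zero-variance variable scores 1 at its
  single value and 0 elsewhere, with a warning.
- **glm** — plain maximum-likelihood logistic regression, main effects
  only.
- **gam** — additive logistic model: cubic B-spline basis (5 df) per
  variable, no interactions, mild ridge (C = 10) so separable designs stay
  finite. Prediction inputs are clipped to the training support, where the
  spline basis is defined.
- **mars** — main-effects MARS: forward growth adds the hinge pair
  `(max(0, x−t), max(0, t−x))` minimizing least-squares error over ~20
  quantile knots per variable, up to 21 basis functions, then backward
  deletion by GCV with penalty 3 (conventional defaults). Output clipped
  to [0, 1].
- **rf** — random forest (300 trees, seeded), probability output.
- **maxent_like** — this package's presence-background model: ridge
  logistic regression on standardized linear + quadratic features, penalty
  C chosen from {0.01, 0.1, 1, 10} by held-out log-likelihood on an
  internal seeded 75/25 split of the training rows, then refit on the full
  training partition. Its provenance string is always `maxent_like`.
- **svm** — RBF SVC with sigmoid probability calibration on three
  deterministic stratified folds of the training split.

AUC is the Mann–Whitney statistic (ties at half credit), computed via
midranks; both train and held-out AUC are stored. Consensus weights use the
**held-out** AUC — the 20% partition exists to evaluate the models, and the
weights are an evaluation-driven quantity. (Train-AUC weighting is the
obvious alternative; it was not taken because train AUC is inflated for
the flexible families, which would overweight them.)

## Reproductive constraint and final map

The breeding-only consensus is diffused with an isotropic Gaussian kernel.
Default kernel SD is the literal expression 25000/1.96 in meters
(≈ 12 755 m): the home range is read as the area containing 95% of an
individual's movements, whence the normal quantile z = 1.96. Taken at face
value in kilometers the expression would be a ~12 755 km kernel, which is
absurd on a 1-km grid, so meters is the only defensible unit. A
self-consistent alternative — the radius of a 25 km² circular home range
divided by z, `sqrt(25e6/π)/1.96 ≈ 1 440 m` — is available as blur mode
`home_range`. Both derivations are recorded verbatim in the output
provenance.

The blur is a nodata-aware normalized convolution: values (nodata as 0)
and the validity mask are blurred identically (reflective boundary, kernel
truncated at 4 SD) and divided cell-wise, so holes do not drag their
neighbourhoods toward zero and a fully valid grid preserves its mean.

The blurred reproductive map is combined with the all-records consensus by
a cell-wise **product** (default): the stated rationale — a cell must be
good habitat *and* close enough to reproductive habitat — is conjunctive.
`min` and `mean` are selectable; the rule is recorded in provenance.

The final map is binarized at the threshold minimizing |sensitivity −
specificity| over all distinct observed scores plus midpoints (ties → the
smallest candidate), evaluated by default on the held-out 20% of the
all-records design (configurable). Presence is `score ≥ t` (closed on the
presence side). Range area is presence-cell count × cell area; percent
reduction against a reference area is `100·(1 − area/reference)`, reported
to one decimal and as the nearest integer.

## Bias diagnostic

The shipped diagnostic is a generic screen, not a reproduction of any
particular published test: Spearman correlation between predicted
suitability and population density over all valid cells (and restricted to
presence and pseudo-absence cells), with a seeded permutation p-value
(999 permutations by default; 199 inside the pipeline for speed).
Zero-variance inputs report correlation 0 with a `degenerate` flag.

## Synthetic data: what it emulates and what it does not

The generator emulates exactly the statistical structure the pipeline
assumes: spatially autocorrelated standardized predictor layers
(Gaussian-smoothed white noise, SD 6 cells by default — smoothing of white
noise was preferred over spectral synthesis as simpler and sufficient for
autocorrelation); a right-skewed density layer (exp of a smoothed field,
rescaled to [0, 1000] persons/km², mimicking clustered settlement); a
virtual species whose occupancy is `logistic(b0 + Σ bi·xi)` with default
betas (0, 2.5, −1.5, 1.0) on the first three of five layers; detection
weight `suitability × density^α` (default α = 1); breeding labels
(uniformly one of the three evidence codes — the codes' relative
frequencies are irrelevant downstream, only the boolean matters) on records
in cells with true suitability ≥ 0.6; coordinates snapped to cell centers
to avoid sub-cell extraction ambiguity. Grids are 64×64 cells of nominal
1 km on an equatorial lon/lat window. Default 300 presences.

It deliberately does **not** mimic real bioclim covariance structure, real
density–climate correlation, coastline/nodata geometry, georeferencing
error, or temporal structure. Passing recovery tests therefore shows the
pipeline is a consistent estimator of its own generative model — not that
it is robust to the pathologies of real compiled records.

The packaged 322-record occurrence CSV is a synthetic stand-in for a real
record compilation: it reproduces published marginal counts (148 breeding /
174 non-breeding and the per-source totals) with random coordinates, and
exists purely to exercise bookkeeping code paths.

## Numerical choices

- Cell membership is half-open, [west, east) × (south, north]: points on a
  cell's west or north edge belong to it; deterministic at edges.
- ESRI ASCII grids are written with 17 significant digits, so float64
  round-trips are exact; square cells are required by the format.
- All randomness flows from one integer seed through named substreams;
  reruns are hash-identical (SHA-256 of every artifact in the manifest).
- Degenerate inputs: single-valued score vectors raise on thresholding;
  one-class profile tuning raises after the bisection/gamma ladder is
  exhausted; any pipeline stage failure aborts with the stage name and a
  partial manifest.

## Problem sizes

Validation studies in the test suite use 48×48 grids with 120 presences
for pipeline plumbing and the default 64×64/300 conditions for recovery
studies (10 seeded replicates per condition), sizes at which a full
two-pass run takes a few seconds and the sampling distributions of the
checked statistics are already stable.

## Known limitations

- Density-weighted pseudo-absences cancel only the *systematic* component
  of density-shaped detection bias. When sampling effort concentrates
  strongly (large α, highly skewed density), the presences cover less of
  the species' environmental niche, and that information loss is
  irreducible: an oracle fit on the true generating layers with perfectly
  matched absence weights degrades too. Expect pattern recovery to decline
  with bias strength even though the weighting keeps the maps largely
  unbiased where data exist.
- No reprojection or resampling: input rasters must be pre-aligned.
- The envelope stage assumes presences are informative about the occupied
  environment; with very few presences the one-class boundary is wide and
  pseudo-absences drift toward a uniform background.
- BIOCLIM enters the consensus with an AUC weight like every other family
  but is presence-only; it receives no benefit from the bias-matched
  absences.
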