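# Methods

This note documents the models and algorithms implemented in `msgea`, the
defaults chosen where the design was genuinely open, and what the
synthetic study system does and does not emulate.

## Terrain generalization and derived variables

The base DEM is reduced with a standard Gaussian pyramid: a separable
5-tap binomial kernel (1, 4, 6, 4, 1)/16 with reflect padding, followed
by factor-2 decimation (ceiling rule for odd dimensions).  Constants are
preserved exactly and linear ramps up to border effects; nodata is
propagated by normalized convolution.  Each pyramid level keeps the
origin of the base grid, so a coarse cell covers exactly the 2×2 block of
finer cells it was reduced from.

Primary morphometry uses the Zevenbergen–Thorne second-order fit on the
3×3 neighborhood: slope in degrees from the gradient magnitude, aspect as
the downslope azimuth clockwise from north (eastness = sin, northness =
cos, both set to 0 on flat cells so they are defined everywhere), and
plan curvature as the curvature transverse to the gradient (negative in
converging terrain).  Border cells are masked for these variables; all
other derivations use edge-replicated gradients so coarse levels of small
rasters remain usable.

Secondary attributes:

- **VRM** — unit surface normals from slope/aspect summed over a moving
  window (default 3×3); VRM = 1 − |resultant|/n ∈ [0, 1].
- **SWI** — topographic wetness index ln(a / max(tan β, 0.001)) with the
  specific catchment area `a` from Freeman-style multiple-flow-direction
  accumulation (slope-weighted to the lower 8-neighbors, exponent 1.1),
  after priority-flood sink filling with an epsilon gradient so flats
  drain.  This is a deliberate substitution: the named SAGA wetness
  algorithm's internals are not openly specified, and MFD-TWI is the
  closest standard formulation.
- **SVF** — per azimuth (default 16, search radius 100 m) the maximum
  horizon elevation angle h is found by ray marching in cell-size steps;
  SVF = 1 − mean(sin h).
- **TI6** — clear-sky irradiance integrated over June at 30-minute steps:
  declination by the Cooper approximation, direct beam
  S0 τ^(1/sin α) cos(incidence) on the tilted cell (S0 = 1367 W/m²,
  τ = 0.7), zeroed when the sun sits below the cell's terrain horizon in
  its azimuth; diffuse = 0.3 · S0 · sin α · SVF (isotropic sky).  Output
  in kWh/m².  Latitude defaults to 46.3° N (an alpine mid-latitude) and
  is config-exposed.
- **WEX** — Winstral-style exposure: mean over azimuths of 1 − sin(Sx),
  with Sx the distance-limited maximum upwind slope angle.  Neutral
  terrain scores 1, crests above 1, hollows below.  Also a substitution
  for a named index whose exact formulation is not published.

Extraction is containing-cell lookup (half-open intervals, cell-center
registration), deliberately without interpolation: samples that share a
coarse cell receive identical values, retaining the pseudo-replication
that a real clustered sampling design produces at coarse grains.

## Genotype handling

Dosages are alternate-allele counts (0/1/2, NaN missing).  Filtering
removes loci with MAF < 0.025 (computed from non-missing calls, strict
inequality) or missingness > 10 % (per-locus).  Missing calls are imputed
as Binomial(2, p̂) draws at the locus's observed frequency — a
frequency-preserving, seed-deterministic substitute for latent-factor
imputation, adequate here because imputation feeds only the (centered)
RDA response and the structure PCs.  LD pruning is a greedy retain-first
scan: a locus is dropped when its squared dosage correlation with any of
the previous 50 *retained* loci on the same chromosome exceeds 0.2 (the
windowing dialect of the cited pruners is not published; this one is
simple and reproducible).  Annotation categories partition loci into
intergenic (structure proxies), intragenic (the GEA response) and the
high-impact subcategory of intragenic loci on which outlier summaries
focus.

## Ordination and outlier scan

RDA centers (never scales) the dosage response — dosages share units, so
scaling would only up-weight rare alleles; a config switch exists.
Fitted values come from projection onto an orthonormal basis of the
(conditioned) predictors; canonical eigenvalues are the PCA eigenvalues
of the fitted matrix.  R² is reported against the *full* centered
variance of Y, so a conditioned model's explained share shrinks as the
conditioning absorbs variance (the vegan convention; the implementation
is verified against `vegan::rda` to 1e-6 in the test suite).  Adjusted R²
is the Ezekiel form.  The permutation test permutes rows of the
conditioned response (reduced-model permutation) and uses the pseudo-F
with residual degrees of freedom n − p − 1 − rank(Z); its null rejection
rate at α = 0.05 measures 0.051 ± 0.004 over 3000 simulations.

K retained axes: the scree rule takes the axis index before the largest
successive eigenvalue drop (smallest λ_{i+1}/λ_i), floored at 2 so the
outlier statistic stays multivariate.  Two numerical guards matter on
degenerate inputs: eigenvalues in the numerical null space are ignored,
and the elbow search is limited to the leading 8 axes — on saturated
models (predictor count comparable to locus count) the decaying tail
would otherwise masquerade as the scree drop.  The pipeline additionally
caps K so that loci > 5K, the estimability requirement of the scatter
fit.  An explicit K can be forced through the library API.

Mahalanobis distances default to the minimum-covariance-determinant
estimator (75 % support, seed-deterministic) with a classical fallback
when the locus count is too small or the robust scatter is singular.
The inflation factor is computed on the scanned loadings as
median(D²)/median(χ²_K); corrected p-values are χ²_K upper tails of
D²/λ.  The scan order is fixed: distances → inflation → p-values →
strict Bonferroni threshold 0.01/m.

## Variable sets and forward selection

The six single-resolution sets hold the nine variable types at one grain
size plus elevation at 0.5 m (10 columns); VS-all holds all 55.  Forward
selection runs only after the global (VS-all) model is significant by
permutation test, then adds at each step the candidate with the largest
adjusted-R² gain, provided its marginal permutation p (partial RDA given
the selected columns) is below α = 0.01, the gain is positive, and the
new model's adjusted R² does not exceed the global model's.  Ties break
by a fixed column order (variable type, then resolution); marginal
p-values are not multiplicity-corrected within a step, matching the
published behavior of the selection procedure this follows.  Candidates
that are collinear with the selected set are skipped; the global scope
model tolerates collinear pools by fitting on a rank basis.  A property
worth knowing: when every non-driver candidate is pure noise, the
global-adjusted-R² bound can stop selection before anything enters —
the reference R implementation behaves identically — so the planted
test scenarios include diffuse background signal, as real predictor
panels do.

## Variable assignment

An outlier's loading vector on the K axes, weighted by sqrt(eigenvalue)
(species-score scaling, so each axis counts in proportion to its
constrained variance), is projected onto every predictor's biplot vector
(predictor/site-score correlations); the assignment is the largest
absolute projection.  Biplot vectors are *not* unit-normalized by
default: with standardized predictors their length measures how well a
predictor is represented on the retained axes, and that length is
precisely what discriminates among nearly parallel arrows.  On the
planted fixture, direction-only projection assigns barely half of the
planted loci to their true driver while the raw-vector projection
assigns 19–20 of 20 across seeds; `normalize=True` remains available.

The genotype-probability map fits a logistic regression of a genotype
class indicator on one standardized variable (L2 penalty 1e-4 to keep
perfectly separable fits finite) and applies the curve cell-wise to the
variable's raster.  Logistic rather than linear regression is used so
the mapped values are probabilities in [0, 1].

## Enrichment

Classic one-sided Fisher exact tests per GO term, restricted to terms
with ≥ 5 annotated genes in the universe; significant terms are those
with p < 0.05, ranked by p.  The default universe is the set of genes
containing the tested high-impact SNPs — the natural background for
"genes associated with a variable" — and is overridable.  The
hierarchy-aware weighting of specialised GO tools is out of scope; an
optional `elim` mode (removing the genes of significant child terms from
their ancestors, most-specific-first, given an ontology edge list) is
provided as a closer approximation.

## Synthetic study system

The generator emulates the data layout of a plot-sampled alpine study:

- **DEM** — planar trend plus spectral-synthesis fractal relief
  (power-law spectrum, fixed exponent 2.5).  The `ruggedness` dial scales
  the relief's standard deviation in metres rather than the spectral
  exponent: amplitude scaling keeps the spatial correlation structure
  fixed across ruggedness levels while still ordering VRM as required.
  Defaults: 256×256 cells at 0.5 m, ruggedness 1.5 m, trend (0.1, 0.05).
- **Sampling** — 10 plots of 6–10 individuals, ≥ 1 m apart, within 15 m
  of their plot center, kept 25 % of the extent away from the raster edge
  so coarse-resolution derived cells remain valid at every sample.
- **Genotypes** — neutral loci from the Balding–Nichols model
  (populations = plots, default F_ST 0.05 for the weak within-valley
  structure regime; raise it to emulate strong regional structure);
  planted loci draw dosages Binomial(2, logistic(α + β z)) with z the
  standardized driving variable.  An optional inbreeding coefficient
  inflates homozygosity as partial selfing would (default 0).  Half of
  the neutral loci are labelled intergenic; 40 % of intragenic loci are
  flagged high-impact, matching the proportion a functional annotation
  typically yields.  Genes carry ~2 loci each; GO terms are drawn from a
  30-term pool.
- **Missingness** — uniform at random (default 5 %), enough to exercise
  the 10 % filter and the imputation path.

What it does not emulate: linkage and recombination (loci are
independent draws, so LD pruning sees only sampling noise), spatial
autocorrelation of genotypes within plots beyond shared population
frequencies, isolation-by-distance, and selection on more than one
variable per locus.  Tests passing on this system therefore demonstrate
the statistical machinery — calibration, recovery, assignment — not
robustness to the full correlation structure of real resequencing data.

## Problem sizes and determinism

The planted-recovery experiments run at n ≈ 100 individuals, 2000
neutral + 20 planted loci, |β| = 2, F_ST = 0.05, with 20 genotype
replicates on one landscape for the null calibration; fixture terrain
scans use a 30 m search radius appropriate to the ~128 m synthetic
extent.  Every stochastic step flows from one master seed (recorded in
the run manifest); generators are pure functions of their seeds, so
repeated runs are byte-identical.

## Known limitations

- The wetness and wind-exposure formulations are documented substitutes
  for named GIS-package algorithms, not re-implementations of them.
- Ezekiel's adjustment is used for partial models with the conditioned
  sample size; permutation-based adjusted R² (as some ordination
  packages offer) is not implemented.
- The horizon scan samples rays at nearest cells in cell-size steps;
  horizon angles on diagonal azimuths carry O(cell/radius)
  discretization error.
- Geography in variance partitioning is raw standardized coordinates;
  spatial eigenvector methods are out of scope.
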