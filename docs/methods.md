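# Methods

This note documents the models and procedures implemented in `maizefuse`,
the assumptions behind the synthetic-field generator, the numerical choices
made where the underlying study leaves the design open, and what the
package's passing tests do and do not demonstrate about real field data.

## The synthetic field trial

The generator emulates a split-plot maize nitrogen trial: single-row plots
of 5.33 m × 0.76 m arranged in adjacent north-south blocks, with treatment
(no supplemental N vs. 225 kg/ha) alternating block by block. Plot-level
phenotypes are derived from per-plant latent variables — stalk, cob and
grain biomass (g/plant), grain protein (%) and stalk nitrogen (%) — through
the trial's own trait formulas: area scaling by `plants / plot area`,
harvest index as the grain share of total aboveground biomass, grain
nitrogen via the Jones factor (protein/6.25), plant nitrogen as stalk N +
grain N, and NutE as grain biomass per unit plant N. Deriving traits from
shared latents makes the arithmetic identities (harvest index in (0, 1),
grain N ≤ plant N) hold by construction, exactly as they do in real data.

Latent draws are correlated multivariate normals (biomass correlations
0.5–0.6) scaled per treatment; the treatment gap on grain biomass, protein
and stalk N produces the bimodal pooled distributions of yield, grain N and
plant N that a nitrogen experiment produces. Grain density is independent
of the treatment and of every rendered signal: `1.324 − 0.027·Gamma(2)`,
giving mean ≈ 1.27, sd ≈ 0.038 (cv ≈ 3%) and left skew. Its independence is
deliberate — it serves as the pure-noise control trait in every recovery
experiment. Standing plants are Poisson(20) per plot, adding shared
multiplicative variation across all mass traits. Trait normalization uses
the reference plot area regardless of the rendered polygon size, so
geometrically scaled-down scenes keep realistic kg/ha values.

Rendering is deliberately simple and analyzable rather than radiometrically
realistic. Canopy pixels follow a template spectrum (green bump, red
absorption dip, logistic red edge) whose flat NIR plateau is
`0.25 + 0.001 × total_plant_n` per plot — a linear, recoverable link;
canopy height is `0.8 + 1.2e-4 × dry_stalk_biomass` meters; soil is a
bright sloping spectrum, shadow a dark flat one; thermal is near-uniform
(≈30 °C, canopy 1.5 °C cooler), reflecting a trial where water was not
limiting. Non-vegetation appears as a one-pixel plot border plus random
interior speckle (default 15% soil + 10% shadow of the interior). Noise is
additive Gaussian only. All randomness flows from one seed through named
substreams (design, traits, render, point cloud), so regeneration is
bit-identical. Consequently, a passing recovery test shows that the
pipeline's machinery extracts planted linear signals correctly at realistic
noise levels; it says nothing about radiative transfer, canopy BRDF,
atmospheric effects or sensor artifacts, none of which are modeled.

The LiDAR point generator drops uniformly distributed points at a requested
density (default 1600 pts/m²); over canopy, 20% of pulses penetrate to the
ground, the rest return from the canopy surface with higher intensity than
ground returns. Terrain is flat at z = 0 by default; an optional linear
ramp exercises the DTM interpolation.

## Surfaces

Gridding is 2-D in x–y at the hyperspectral pixel size (3 cm) with the grid
origin snapped to the raster origin, so modalities align without
resampling. The DSM takes the maximum non-ground z per cell; the DTM takes
the minimum ground z per cell (the lowest return best approximates bare
earth — the source is silent here), fills voids by linear interpolation
over the Delaunay triangulation of ground points (the TIN method) and
assigns nearest-ground values outside the convex hull; the CHM is their
difference clipped at zero with nodata propagated. The intensity surface
records the intensity of the *highest* point per cell by default, mirroring
DSM construction; a per-cell maximum-intensity rule is a config switch
(which rule the original used is not stated). The statistical outlier
filter (k = 8 neighbors, 3 global sd, at most 10% of the cloud) uses
standard defaults; the source names the operation but no parameters.

## Segmentation and scaling

Each plot chip is clustered into two classes with k-means++ on per-pixel
z-scored features (all spectral bands plus height, intensity, thermal).
The vegetation cluster is the one with the higher mean NIR reflectance over
750–1000 nm — a rule chosen here because green canopy's NIR plateau
dominates soil and shadow regardless of cluster index order. A chip with
no pixel contrast is labeled entirely vegetation, with a warning.
Standardization (features and deep-learning targets) is plain column
z-scoring fit on training rows only, with exact inversion; zero-variance
columns are rejected by name.

## The NDSI screen

NDSI(i,j) = (Mᵢ − Mⱼ)/(Mᵢ + Mⱼ) over plot-wise masked band means, extended
to height, intensity and thermal bands. R² is the squared Pearson
correlation between per-plot NDSI values and the trait — equivalently the
R² of a simple linear regression, the only scale-free choice for a
two-variable screen (the source shows heatmaps without specifying the
fit). Auxiliary bands are z-scored across plots before entering the index
by default: raw meters or °C make the denominator scale-dependent and can
push the index outside [−1, 1]; raw-scale mode is available. Ties in the
best-pair argmax break toward smaller wavelengths. A stack of s spectral +
3 auxiliary bands evaluates exactly C(s+3, 2) pairs; the full 269 + 3 case
is ~37k pairs per trait and runs in seconds.

## The feature library

95 features per plot: 34 hyperspectral vegetation indices, 30 height
metrics, 30 intensity metrics, 1 thermal index. The index formulas are
implemented as published, including several unusual printed forms kept
deliberately: GNDVI as `(R750 − R540 + R570)/(R750 + R540 − R570)` (not the
common green NDVI), SIPI with the `(R800 − R450)/(R800 + R650)` asymmetry,
FCI = R²683/(R675·R691), and the thermal index in its printed form
`(Ti − Tmin)/(Ti − Tmax)` — whose denominator is negative for any plot
cooler than the field's hottest pixel — with the conventional
`(Ti − Tmin)/(Tmax − Tmin)` one flag away. Tmin/Tmax are the field's
pixel-level thermal extremes, which keeps the printed form defined for
every plot. TCARI's printed formula is parenthesis-mangled in the source
table; the standard `3[(R700 − R670) − 0.2(R700 − R550)(R700/R670)]` is
used. Band lookup takes the nearest band center (lower wavelength on ties)
and raises, naming the requesting index, when a wavelength falls outside
the sensed range.

Distribution metrics use these conventions where the source table's cells
are blank: percentiles by linear interpolation between order statistics;
the mode of a continuous sample as the midpoint of the argmax histogram bin
(0.05 m bins for height, 5 units for intensity); canopy-return densities as
the proportion of masked pixel values strictly above the sample's own
10th–90th quantiles; the canopy/ground ratio as vegetation-to-non-vegetation
pixel counts within the plot (classification flags in point-cloud mode);
moment-based skewness and *excess* kurtosis. Constant input makes cv and
relief ratio undefined; both become 0 with a warning.

## Shallow baselines

SVR (C, kernel, γ grids; ε = 0.1 on standardized targets) and random
forests (trees, depth, min-leaf grids) are tuned by exhaustive grid search
scored with inner 5-fold cross-validated R² and refit on the training
split. Evaluation repeats a stratified-by-treatment 60/20/20
train/validation/test shuffle (default 5 repeats) — stratification
preserves the bimodal treatment structure in every split; resampling is by
reshuffling, not with replacement. Feature scaling and the search see the
training split only (a perturbation test asserts this). MDI importances
come from the fitted forest and sum to 1. The default grids (C ∈ {0.1, 1,
10, 100}, γ ∈ scale-heuristic × {0.1, 1, 10}, kernels {rbf, linear}; trees
{100, 300, 500}, depth {None, 10, 20}, min-leaf {1, 3, 5}) are modest,
reproducible choices; the recovery experiments use a reduced grid to stay
inside minutes.

## The fusion network

Implemented from scratch in numpy with explicit backpropagation (im2col +
BLAS convolutions; gradients verified against finite differences to ~1e-6
relative error). Architecture: one stream per modality group — 3-D
convolutions (kernel 7 spectral × 3×3 spatial, pool 6×2×2) for the
hyperspectral cube; 2-D convolutions (3×3, pool 2×2) for LiDAR, with height
and intensity stacked as channels of a single stream so the full
four-modality model has three streams; 2-D for thermal — with the filter
ladder 8→16→32→64, ReLU, Glorot-uniform weights, zero biases, global
average pooling to 64 values per stream, concatenation fusion, a 32-unit
ReLU head with dropout after it, and one linear output per task.

Numerical and design choices worth noting:

- **Padding.** Convolutions default to 'same' spatial padding. Four valid
  3×3 convolutions interleaved with 2×2 pooling cannot fit a 25-pixel-wide
  window (the width hits 2 before the third conv layer); 'same' padding
  preserves the published four-layer ladder on the published 176×25
  geometry (25→12→6→3→1 through the pools). Valid mode remains available.
- **Pooling at small extents.** A pooling window is clipped to the
  remaining extent when an axis is smaller than the pool size, and trailing
  remainders are dropped (floor division), so deep spectral pooling (270 →
  45 → 7 → 1 → 1) never produces a zero-sized axis.
- **Loss.** Unweighted mean of per-task Huber losses (δ = 1.0) on per-task
  standardized targets; standardization makes the unweighted mean a
  comparable aggregate across traits. Huber keeps genuine extreme plots
  from dominating (quadratic within δ, linear beyond); a side effect is
  range compression of predictions at both extremes.
- **Optimization.** Adam at 1e-3, decayed ×0.9 every 5 epochs; batch 16;
  dropout 0.5; early stopping on validation loss with patience 15; best
  validation weights restored. Unspecified knobs (dropout, batch, patience,
  decay factor, δ) are package defaults, all surfaced in `TrainConfig`.
- **Augmentation.** 20 random crops of the plot-interior window per
  *training* plot, with one offset array per crop iteration shared across
  all modalities (exact-equality tested). Validation and prediction use
  the deterministic center crop. The original chip does not join the crop
  set. Plots never straddle splits: splitting happens at plot level before
  crop generation.
- **Determinism.** Stream weights draw from a seed substream independent
  of the head, so mono- and multi-task builds share stream initializations
  at the same seed; split, shuffle, dropout and augmentation each have
  their own substream.

## Evaluation

R² = 1 − SS_res/SS_tot; MAE is the mean absolute residual; RMSE divides by
n − 1 by default — the form printed in the emulated study — with the
conventional n denominator behind a flag (for identical residuals the
printed form is strictly larger). Trait summaries report count, mean, sd,
cv% = 100·sd/mean, min, quartiles (linear interpolation), max.

Global Moran's I uses row-standardized k-nearest-neighbor weights (k = 8, a
robust choice on a regular plot grid; inverse-distance weights are the
alternative — the source never states its scheme). With row-standardized
weights, I = zᵀWz / zᵀz for centered residuals z; the null expectation is
−1/(n−1). Significance is a two-sided permutation test rather than a normal
approximation. The experiment drivers use 1999 permutations because a
strict p < 0.001 decision is unreachable with 999 (the minimum attainable
p-value is 1/(n_perm + 1)); the operation's own default remains 999.

## Problem sizes in the shipped experiments

The recovery experiments run a scaled-down study chosen once: 300 plots
(20 blocks × 15), 12 spectral bands, 0.96 m × 0.30 m plots (32×10-pixel
chips, 2-pixel margins), a 24×8 crop window, a two-layer (8, 16) filter
ladder, batch 64, at most 40 epochs — a complete run (segmentation,
features, RFR with grid search, fusion network at 0 and 20 crops) takes
about seven minutes on one CPU. The full-scale geometry (270 bands,
176×25 windows, four layers to 64 filters) is constructed and
forward-passed in tests but not trained there. Moran calibration uses 100
plots × 200 null repetitions × 1999 permutations.

## Known limitations

- The generator's linearity makes recovery *easier* than real phenotyping;
  reported R² values on synthetic data are upper bounds of machinery
  correctness, not predictions of field performance, and the original
  study's field-data R² values are not reproducible without its data.
- Thermal carries almost no signal by design (water not limiting), so
  models fed thermal alone should and do perform near chance.
- The point cloud has no multi-return/waveform structure; ground
  classification is generated, not inferred.
- GeoTIFF georeferencing lives in a JSON sidecar rather than embedded tags;
  point clouds are exchanged as tab-separated tables.
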