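# Methods

## Problem and scope

`fecalnirs` implements a calibration-transfer study design from quantitative
fecal near-infrared spectroscopy (NIRS): predicting the organic matter
digestibility (OMD, g/g) of cattle diets from the absorbance spectra
(log10(1/R), 400–2,500 nm) of dried, ground feces, and asking whether locally
weighted calibration beats a single global model when the sample population is
a heterogeneous mixture of diets. Four estimators are compared under one
protocol: global PLS regression (PLSR), locally weighted PLS (LWPLSR), its
k-nearest-neighbor restriction (KNN-LWPLSR), and an aggregated variant that
averages KNN-LWPLSR over a range of latent-variable counts (KNN-LWPLSR-AGG).

Because no public fecal OMD spectral library is available, the package ships a
synthetic-data generator whose defaults encode the population the analysis
targets, and every claim the test suite makes is a claim about data with that
structure (see "What the generator does and does not emulate").

## Preprocessing

Spectra are transformed, in fixed order, by

1. optional conversion from reflectance, `A = log10(1/R)`;
2. a Savitzky–Golay first derivative (3rd-order local polynomial, 11-point
   window, derivative per data-point interval). Only full-window positions are
   kept, so the grid loses 5 channels at each edge — the simplest contract and
   the common chemometric choice; no polynomial edge extrapolation.
3. standard normal variate (SNV): each spectrum is centered and scaled to unit
   sample SD (n−1 denominator).

The derivative annihilates additive offsets and turns linear baselines into
constants, which SNV centering removes; SNV removes multiplicative scatter.
Hence `preprocess(a·x + b) = preprocess(x)` for a > 0, tested to 1e−10. The
derivative is per index rather than per nm: the constant 2 nm spacing is a
scale factor absorbed by the regression coefficients. Whether SNV preceded or
followed the derivative in the original protocol is ambiguous; the
derivative→SNV order is fixed here and documented.

## PLS core

PLS1 with mean centering only (no variance scaling — NIRS convention) via
NIPALS-style sequential extraction. Observation weights enter the centering
means and all cross-products; uniform weights reproduce the unweighted fit and
zero-weight samples drop out exactly, which the local models rely on.
Components are nested, so one fit at `nlv_max` serves every smaller component
count — both for prediction and for the latent-space distances below. If the
response residual becomes orthogonal to the predictor residual (constant y,
exhausted rank), remaining components are null and predictions fall back to
the weighted mean, rather than erroring.

## Local models

For each sample to be predicted:

1. A preliminary global PLS defines a score space. Its dimension equals the
   candidate `nlv` being evaluated (a `dist_nlv` override exposes a fixed
   distance dimension, since the original protocol does not state which was
   used).
2. Distances from the target to every calibration sample are Euclidean on
   scores standardized by the training score SDs — a diagonal "standardized H"
   metric in latent space.
3. KNN variants keep the k nearest samples (ties broken by lower row index,
   making everything deterministic).
4. Weights are `w_i = exp(−d_i/(h·s))` with `s = median(d)` (mean fallback;
   all-zero distances give uniform weights), truncated to zero below 1e−4 of
   the maximum. The negative-exponential kernel on a median-scaled distance is
   the standard choice of the locally-weighted PLS literature and makes the
   grid h = 0.5…6 span sharp-to-flat weighting, with h = ∞ recovering
   uniform weights exactly.
5. A weighted PLS with `nlv` components is fitted on the (possibly truncated)
   neighborhood and the target predicted. If a neighborhood retains fewer
   than 2 nonzero weights the model refuses and advises a larger h.

The AGG variant averages KNN-LWPLSR over nlv = nlv_min…nlv_max, re-selecting
neighbors and weights in each nlv's own score space (re-selection per nlv is a
documented choice; the alternative of freezing neighbors once is not exposed).

These definitions nest exactly: AGG(min=max) ≡ KNN-LWPLSR, KNN(k=n) ≡ LWPLSR,
LWPLSR(h=∞) ≡ global PLS, verified to 1e−8.

Implementation note: all local fits run in the orthonormal basis of the
calibration row span (rank ≤ n). PLS predictions, scores and distances are
invariant under this change of basis, and it cuts the per-fit cost roughly by
p/n for p-channel spectra.

## Splitting, screening, tuning

- **Kennard–Stone** maximin selection on the preprocessed spectra (not PC
  scores), ties by lowest index. Following the study design the selected,
  maximally diverse set becomes the *validation* subset; `select="calibration"`
  gives the conventional use.
- **Outlier screening**: standardized Mahalanobis H = D²/p computed in the
  calibration PCA score space retaining 99% cumulative variance (mean H ≈ 1
  convention); samples with H > 3 are excluded. Whether the original protocol
  screened in PCA or PLS scores is not stated; PCA is the package's choice.
- **Cross-validation**: five-fold interleaved ("venetian blinds", fold = row
  index mod 5, no shuffling). RMSECV pools out-of-fold residuals rather than
  averaging per-fold RMSEs — deterministic and standard. The selected tuning
  point minimizes RMSECV with ties (at 1e−12 resolution) broken toward fewer
  latent variables, then smaller k, then smaller h, then a narrower nlv range.
- **Grids**: `TuningGrid.full()` holds the complete grids (nlv 1–30,
  h ∈ {0.5,…,6[,∞]}, k ∈ {50,…,250}, AGG ranges 1–5 × 15–30). The default
  pipeline profile is `TuningGrid.reduced()` (h ∈ {0.5, 2, 6}, k ∈ {100, 200},
  nlv ≤ 15): the full KNN/AGG grids mean tens of thousands of per-target
  weighted fits per fold and are a cluster job, not a desk run. k candidates
  exceeding the available neighbors are dropped with a log note.

## Evaluation and comparison

Errors are `predicted − observed`. RMSEP uses the n denominator; bias is the
mean error; RMSEP(C) (the SEP) is the bias-corrected error with n−1, so
`n·RMSEP² = n·bias² + (n−1)·RMSEP(C)²` exactly. R² is `1 − SSE/SST`
(penalizing bias), not a squared correlation. The 95% individual prediction
interval is ±1.96·RMSEP and the minimum detectable difference between two
predictions is 2·1.96·RMSE.

Paired model comparison follows the classic two-part scheme: a paired t-test
with CI on the error difference (bias), and the Pitman–Morgan
correlated-variances test for the SEP ratio — t on the correlation between the
sum and difference of the bias-centered errors, df = n−2, with the ratio CI
obtained by numerically inverting the test (the pivot
`cov(e_a+λe_b, e_a−λe_b) = σ_a²−λ²σ_b²` vanishes at λ = σ_a/σ_b). Two models
differing by an exact constant are reported as "exactly offset" with no
t-test; identical inputs give t = 0, p = 1. Significance letters come from an
insert-and-absorb compact letter display at α = 0.05; no multiplicity
adjustment is applied across the six pairwise comparisons (plain letter
groups). Type-I error of both tests is verified by simulation to lie in
[3%, 7%] at α = 5% with n = 76.

The power analysis uses the two-means formula
`n = 2(Z_α + Z_{1−β})²·SD²/d²` with Z_α = 1.96, Z_{1−β} = 1.28, rounded up and
clamped at 2 animals per treatment. Note 1.28 is conventionally the 90%-power
deviate even though it is often quoted alongside 80% power; the deviates are
parameters and can be overridden. The reference in vivo method's standard
error, 0.0135 g/g, is carried as the named constant `REFERENCE_METHOD_SE` (it
comes from a repeated-measures analysis of an external trial and is
configuration here, not something the package estimates).

## Synthetic data generator

One seeded `numpy` generator drives all draws in a fixed order (cluster
assignment; cluster chemistry; per-sample latent scores; scatter; spectral
noise; reference noise), so datasets are bit-reproducible.

Structure: `n_clusters` diet clusters (multinomial assignment, equal
probabilities), each with a mean absorbance spectrum built from Gaussian
absorption bands on a broad baseline. A single smooth spectral loading carries
the digestibility signal in *every* cluster; cluster c maps its latent score z
to OMD with slope `s_c = 1 + slope_heterogeneity·η_c` and its own intercept.
This shape is deliberate: in high-dimensional spectra, *any* arrangement in
which clusters respond along different spectral directions remains exactly
solvable by one global linear model (each direction gets its own coefficient),
so it cannot make local models win. Genuine global nonlinearity requires the
clusters to disagree about the slope on a *shared* direction — which is what
`slope_heterogeneity` controls, giving a clean dial from "global PLS suffices"
(0: one global linear law, exactly) to "local models win". Zero-slope nuisance
directions per cluster, multiplicative scatter `exp(N(0, scatter_mult_sd))`,
additive baseline offsets and tilts, and white spectral noise complete the
spectra; the scatter terms are exactly removed by preprocessing.

OMD values: the pooled cluster-affine scores are rescaled so that the
*observed* values hit the target moments — the noise-free truth gets SD
`sqrt(omd_sd² − reference_noise_sd²)` (floored at omd_sd/4), reference noise
`N(0, 0.0135²)` is added, and both truth and observation are clipped to the
configured range (clipped fractions are logged). Defaults reproduce the
population the analysis targets: mean 0.709, SD 0.0350, range 0.597–0.782 g/g,
466 samples, 3 clusters, slope heterogeneity 0.5 (chosen so that the global
model's structural error, ~0.007–0.010 g/g, is comparable to but does not
dwarf the reference noise — the regime in which the local-vs-global question
is actually interesting). Trial labels partition each cluster (80/20 by
default) purely as grouping labels — no trial-level random effects — so the
pipeline can hold out "later campaigns" as a test subset.

What the generator does **not** emulate: real fecal chemistry (no NDF/ash/
nitrogen band assignments — clusters are abstract diet types), instrument
drift, repack/replicate scan variance, trial-level random effects, and
heteroscedastic reference error. Passing tests therefore demonstrate that the
algorithms behave correctly on data with the assumed cluster-heterogeneous,
locally linear structure; they do not certify performance figures on real
feces.

## Numerical choices and degenerate inputs

- Tolerances: reduction-chain identities at 1e−8; derivative exactness at
  1e−9; scatter invariance at 1e−10; RMSECV ties at 1e−12.
- SNV refuses constant spectra; `mahalanobis_h` refuses singular covariances
  (advising fewer components); `local_weights` refuses negative distances;
  local fits refuse neighborhoods with fewer than 2 nonzero weights.
- Kennard–Stone and KNN ties resolve to the lowest sample index; fold
  assignment follows row order — the whole pipeline is deterministic given the
  seed.
- A candidate nlv is silently capped at (effective neighborhood size − 1) in
  local fits, since sharp weighting can shrink the effective sample below the
  requested component count.

## Problem sizes used by the test suite and acceptance script

Simulation studies run at desk scale by choice: heterogeneous replications use
a 6 nm grid (351 channels) and the homogeneous no-harm check a 10 nm grid
(211 channels) with 299 calibration / 91 test samples and reduced grids
(h ∈ {0.5, 2, 6}, nlv ≤ 15); the spectral physics is identical to the 2 nm
grid. The full pipeline in `scripts/acceptance.py` runs the complete
466-sample population on the native 2 nm grid (1,051 channels) with the
reduced tuning profile. The benefit-of-locality replication uses 20 seeds, the
no-harm check 10, and the type-I calibration 2,000 null replicates at n = 76.

## Known limitations

- The weight kernel and distance metric are one concrete realization of the
  locally-weighted PLS framework; other kernels (tricube, Gaussian on squared
  distance) are not implemented.
- No PLS2, no variable selection, no robust PCA, no MSC/detrend alternatives
  to SNV, and no aggregation over h or k.
- The Pitman–Morgan ratio CI assumes bivariate normal errors; heavy-tailed
  prediction errors will distort its coverage.
- `describe_dataset` exports PC scores for plotting but figure rendering is
  cosmetic (`plot_scores`), not part of the tested surface.
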