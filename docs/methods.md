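# Methods

## Problem and scope

`polgsv` estimates stand-level growing stock volume (GSV, m³/ha) of planted
conifer forest from time-series quad-polarimetric SAR, at the plot scale.
The pipeline assumes fully pre-processed imagery: polarimetric calibration,
speckle filtering, terrain correction and geocoding all happen upstream, and
the package starts from either four-component decomposition power rasters or
coherency-matrix (T3) stacks. Because no field campaign data ship with the
package, a first-class synthetic scene generator reproduces the statistical
structure of the target study design, and all trend results quoted anywhere
in this repository are computed on those synthetic scenes.

## Ground truth: plot GSV from tree lists

Each plot is a 20 m or 30 m square in which every tree of DBH ≥ 5 cm has DBH
(cm) and height (m). Single-tree stem volume is `g · (H + 3) · f` with
`g = π (DBH/200)²` the breast-height cross-section (m²) and `f` a
dimensionless trunk taper coefficient; plot GSV is the per-hectare sum.
Species-specific taper tables are pluggable (`TaperModel.from_table`); the
default is a constant `f = 0.45`, a synthetic-only stand-in — real use should
supply the operational table for the species. Whether `f` varies per tree or
per plot is an open choice; per-tree lookup is implemented. Trees below the
5 cm threshold are excluded with a reported count, not an error.

## Yamaguchi four-component decomposition

`yamaguchi4` splits a Hermitian 3×3 coherency matrix T into surface (Odd),
double-bounce (Dbl), volume (Vol) and helix (Hlx) powers with
`P_Odd + P_Dbl + P_Vol + P_Hlx = trace(T)`. Helix power is `2 |Im T23|`. The
volume model is selected by the co-pol ratio `10 log10(|S_vv|²/|S_hh|²)`
computed from the Pauli entries: the symmetric random-dipole cloud
(diag(2,1,1)/4) within ±2 dB, and the two asymmetric dipole models
([[15,±5,0],[±5,7,0],[0,0,8]]/30) outside. The surface/double-bounce split of
the remainder uses the dominant-scattering criterion
(`T11 − T22 − T33 + Pc > 0` ⇒ surface dominant) with the `|C|²/S` (or
`|C|²/D`) transfer term. These branch constants are compile-time constants of
the classical four-component method; the later rotated/generalised variants
are deliberately not implemented.

Negative intermediate powers (over-subtracted volume, helix exceeding the
cross-pol budget) are clipped to zero and the four powers rescaled so the
span identity holds exactly; the number of adjusted pixels is logged. On
random Hermitian PSD input the decomposition conserves the span to 1e-8 and
is homogeneous of degree one in T.

## Features and temporal fusion

Seven characteristics are screened per plot and source: Odd, Dbl, Vol and
the fused ratios Dbl/Odd, Vol/Odd, Dbl×Vol, Dbl×Vol/Odd, all on linear
powers. Plot values are means of the 7×7 pixel window centred on the pixel
containing the plot centre (odd windows only; a plot is unusable if
shadow-flagged or if more than half the window is masked). For
multi-acquisition sources the base powers are averaged arithmetically across
acquisitions first and the fused features recomputed from the averaged
powers; averaging pre-computed ratios is not equivalent (on odd = (1,4),
dbl = (4,1) the two orders give 1 vs 2.125) and is available only behind
`fuse_after=False` for sensitivity analysis. Ratio features are propagated
as missing (NaN) wherever Odd is zero, never silently zeroed.

## Retrieval models

Exponential GLM: `σ = exp(a0 + a1·GSV)`, fitted as OLS of `ln σ` on GSV
(log link, `scipy.stats.linregress`); non-positive σ are excluded with a
count. Inversion `GSV = (ln σ − a0)/a1` is monotone and unbounded — the
model has no saturation level.

Semi-exponential (water-cloud-type): `σ = βs + (βn − βs) e^(−GSV/k)`, with
βn the bare-ground power, βs the dense-forest asymptote and k (m³/ha) the
saturation constant. (A printed variant of this model with exponent
`GSV − k` violates both of its own boundary conditions and is treated as an
erratum.) Fitted by trust-region nonlinear least squares with analytic
Jacobian, tolerances 1e-10, k bounded in [1e-3, 1e6]; initial values are
range-based — βn₀ = mean σ of the 10 % lowest-GSV plots, βs₀ = mean σ of the
10 % highest, k₀ = median GSV — with up to 5 deterministic jittered restarts.
A fit that ends non-converged or with k at a bound is returned flagged, and
LOOCV reports how many folds were flagged. On data actually generated from
the model, parameters are recovered to better than 1e-6 relative.

Inversion maps `r = (σ − βs)/(βn − βs)` to `−k ln r` for r ∈ (0, 1]; r ≤ 0
(at or beyond the dense-forest asymptote) returns the configurable cap
(default 500 m³/ha, just above the densest stands modelled) with a
saturation flag, r > 1 returns 0 with a flag. The cap is the operational
expression of the model's finite invertible range; the GLM has none.

A known behaviour worth stating: on scenes generated from the log-linear
(GLM) law the power–GSV response is convex, so the saturating semi-
exponential model degenerates towards its linear limit (k driven to the
upper bound, flagged). This is a genuine model mismatch, not a solver
failure; the saturation contrast between the models is therefore
demonstrated on data drawn from the saturating law itself.

## Assessment

Pearson gamma per feature and source, with a two-tailed t test; the critical
|gamma| is always computed from the actual post-exclusion n (at n = 50,
alpha = 0.01 it is 0.361). LOOCV refits the model from scratch on each fold,
including the initialisation rule. RMSE, RRMSE = 100·RMSE/mean(obs), and
R² = squared Pearson correlation of observed vs predicted — chosen over
1 − SSE/SST because LOOCV residuals can push the latter negative; the
alternative is available via `r2_method="ss"`. The exceedance fraction
counts plots with relative error above a threshold that is never implied,
always printed (default 0.5). Report tables round half-up: 3 decimals for
correlations and R², 2 for RMSE/RRMSE; the aggregate of printed correlation
columns is computed in decimal arithmetic so exact decimal ties round the
way the printed values demand.

## Synthetic scenes: what they emulate and what they do not

Defaults are the study conditions: 50 plots; GSV from a three-stratum
mixture of uniforms — young (60–130), immature (130–280), mature
(250–450) m³/ha with weights 10/52/38 % — matching the age-class composition
and range of the target plantation landscape; four acquisitions within one
growing season. Tree lists are constructed so the stem-volume formula
reproduces each plot's drawn GSV exactly (heights follow a monotone
DBH–height curve peaking near 20.5 m at 29.5 cm DBH; DBH values are scaled
by √(target/current), which is exact because stem volume is quadratic in DBH
at fixed height).

Powers follow `ln σ_c = a0(c) + a1(c)·GSV + bias_t(c) + ε`,
ε ~ N(0, noise_sd² + extra_noise_sd_t²). Default slopes per (m³/ha):
Dbl +0.0030, Odd −0.0025, Vol +0.0012, Hlx 0 (helix held near zero:
building-type scattering, negligible over forest). Baseline noise_sd = 0.35;
the two mid-season acquisitions carry extra noise (0.35) and a moisture bias
(+0.15 on Odd, −0.10 on Dbl), the September one a milder disturbance
(0.15). No quantitative noise model exists for the target study, so these
magnitudes are calibrated to one criterion only: seed-averaged
single-acquisition correlations in the published ranges (Dbl ≈ 0.46–0.63,
Odd ≈ −0.39…−0.53, Vol ≈ 0.21–0.31), weakest on the rain-affected dates.

The generator does not emulate: saturation of the power response (its law is
log-linear, so the GLM wins by construction and the semi-exponential model
is structurally disadvantaged); the sign pattern of the published fused
ratios (there Dbl/Odd correlates negatively with GSV despite Dbl positive
and Odd negative — under any monotone per-channel law the ratio correlates
positively, so that empirical feature of real stands is out of reach of this
noise model); spatial correlation of speckle; terrain, DEM or weather
covariates. Passing trend tests therefore show that the estimator chain
behaves correctly under the assumed statistical structure, not that the
accuracy figures transfer to real imagery.

Optional speckle is a complex-Wishart multilook draw (Cholesky of T times
i.i.d. circular complex normals, L looks), disabled by default for
plot-level tables since 7×7 spatial averaging makes plot-level noise
approximately log-normal. All randomness stems from one root seed via fixed
`SeedSequence` child streams (plots / powers / T3 / rasters / shadow), so
every operation is bit-reproducible independently.

Synthetic rasters place each plot at the centre of its own 7×7-pixel tile
(10 m pixels) with a plot-constant latent GSV, so window extraction and
map-then-extract consistency are exact in the noise-free case.

## Replicated experiments and problem sizes

The headline comparison (`polgsv.experiments`) regenerates 100 independent
default scenes and computes LOOCV RRMSE for Dbl×Vol/Odd from each single
acquisition and from the 4-acquisition temporal average, for both models —
50 plots × 5 sources × 2 models × 100 seeds. Median RRMSE of the temporal
average beats every single acquisition for both models (GLM ≈ 23 % vs
38–52 %; semi-exponential ≈ 32 % vs 51–73 %), and does so seed-by-seed in
well over 90 % of replicates. These sizes keep the whole suite and the
acceptance script each under a few minutes on one CPU.

## Numerical choices and edge cases

- Hermiticity tolerance 1e-10 (scaled); non-Hermitian input errors.
- Degenerate zero-width GSV law with more than one plot is refused
  (downstream correlations undefined).
- GLM fit requires ≥ 3 usable pairs and non-constant GSV; semi-exponential
  ≥ 4 pairs and > 1 distinct GSV.
- Raster convention: 0-based row/col, pixel-centre registration, odd
  windows only; even windows rejected.
- Raster files are plain multi-band TIFF plus a JSON grid sidecar; T3 stacks
  a documented 9-plane `.npy` container. Nodata is IEEE NaN.
- GLM map inversions may be clamped to [0, cap] for display; the clamp is
  off in any consistency check.

## Known limitations

Single-predictor models only (no multivariate regression); no physical
scattering model; no Lee filtering, orientation-angle compensation or
geocoding; no significance test between competing models (the choice of
test is not pinned down and is left out rather than guessed).
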