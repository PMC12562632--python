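# Methods

## Scope and data model

The package implements a hyperspectral quality-assessment pipeline for pears:
reflectance calibration of raw cubes, extraction of mean spectra from an
elliptical region of interest, stratified SPXY partitioning, spectral
regression of three quality indices (firmness FI in newtons, soluble solid
content SSC in percent, and their ratio FSR = FI/SSC), maturity-stage
classification, and pixel-wise quality mapping. No instrument data ship with
the package; a synthetic generator reproduces the statistical and geometric
structure the pipeline assumes, and every claim the test suite makes is a
claim about that structure.

A cube is a rows × cols × bands array with a strictly increasing wavelength
vector in nm. Whiteboard correction, R = (R_O − R_D)/(R_W − R_D), is applied
elementwise; pixels where the white and dark frames coincide carry no
information and are set to a fill value (default 0) with their count recorded
in metadata rather than raising, so whole-cube calibration survives dead
detector elements. Negative reflectance is clipped to 0; values above 1
(specular highlights) are retained, with a configurable upper clip of 1.2 in
tabular form. The working spectral range is 950–1650 nm, inclusive on both
ends; on the fixed instrument grid (below) this window holds exactly 421
bands, the input dimension every model assumes.

The region of interest is an axis-aligned ellipse (the fruit's stem–calyx
axis lies along the scan direction, so no rotated ellipses are needed);
image coordinates are 0-based and row-major. The study's ROI of 90 × 60 px
axes corresponds to semi-axes 45/30.

## Instrument wavelength grid

The nominal instrument description (512 bands, 5 nm resolution, 900–1700 nm)
is internally inconsistent: a uniform 512-point grid over 800 nm has 1.57 nm
spacing, and no uniform grid of 512 points yields exactly 421 bands in
[950, 1650]. Because the 421-band working dimension anchors all downstream
geometry (the 128 × 53 branch maps, the 6784-dim fused feature), the package
fixes a documented non-uniform 512-point grid: 421 uniformly spaced points
spanning [950, 1650] (spacing 700/420 nm), 45 points padding down to 900 nm
and 46 up to 1700 nm. Truncation to the working window is then exact by
construction.

## SPXY partitioning

SPXY distance: d(i,j) = dX(i,j)/max dX + dy(i,j)/max dy with Euclidean dX
and absolute response difference dy; selection is Kennard–Stone max–min
(first the most distant pair, then repeatedly the sample maximizing the
minimum distance to the selected set). Ties break to the lowest index after
a seeded within-stratum shuffle — the seed (default 2) affects only tie
resolution, so the split is deterministic and platform-independent. The
split runs independently within each maturity stage; per-stratum calibration
counts use round-half-to-even with the final stratum adjusted so the global
4:1 ratio is exact (600 → 480/120, 96/24 per stage). One shared split,
computed on a single designated response column (default FI), serves all
three regression targets and the classifiers. With a constant response the
joint distance is undefined (the normalizer vanishes); passing `y=None`
selects on the spectral distance alone.

## Deep architectures

All deep models run on a compact numpy neural-network core (conv1d via
im2col + GEMM, batch norm, max pooling, linear, a single-step LSTM cell,
Adam) with manual backpropagation, verified against finite differences in
the test suite. Arithmetic is float32; convolution lowering to one GEMM per
layer makes 1-CPU training practical.

**Multiscale CNN.** Three parallel branches with kernels 3/5/7 (channels
1→16→128, 1→64→128, 1→128→128; stride 2; paddings 1/2/3; conv → batch norm
→ ReLU twice, then 2×1 max pool). For a 421-band input each branch emits a
128 × 53 map. Branch maps are fused elementwise with learnable per-channel
weight vectors w1–w3 (length 128, broadcast over positions, initialized to
1/3, unconstrained): the fusion weights' dimensionality is a design choice —
scalars would under-parameterize channel selection and per-element weights
would triple the head's parameter count without a clear gain, so one weight
per channel is used. The fused map is flattened (6784), reduced by a fully
connected 6784→128 layer with ReLU, and read out linearly.

**CNN–LSTM.** The same trunk; the 128-dim fused feature is treated as a
length-1 sequence into a single-layer LSTM (input 128, hidden 128, gate
order i/f/g/o, two bias vectors, hence 4·(128·128 + 128² + 2·128) = 132 096
parameters), whose final hidden state feeds the linear head. With zero
initial state the forget gate is inert; the LSTM acts as a learned gated
re-weighting of the fused feature.

**ResNet18-1D.** Stem Conv(1→64, k=7, s=2, p=3) + BN + ReLU + MaxPool(k=3,
s=2, p=1), four groups of two residual blocks with 64/128/256/512 channels
(3-kernels; 1-kernel projection on channel/stride changes), global average
pooling to 512 features, linear head. For 421 bands the length chain is
421→211→106→106/53/27/14.

## Training

Adam (lr 1e-4, β 0.9/0.999), MSE loss, batch size 32; "iterations" are
epochs over the calibration set with seeded without-replacement shuffles.
Default budgets: 500 epochs with early stopping for ResNet18, 1000 for the
multiscale models. Early stopping, when enabled, holds out 10 % of the
calibration samples, evaluates validation MSE each epoch, stops after a
patience of 50 non-improving epochs and restores the best parameters.
Spectra are standardized per band, and the response is standardized too,
using calibration-set statistics stored in the model artifact and inverted
at predict time; response standardization is an optimization
reparameterization only (the network's output unit starts near the target
mean), and recorded losses are rescaled to squared target units. No
regularization beyond early stopping is used. Weight initialization is a
seeded uniform fan-in scheme; batch-norm eps 1e-5 and momentum 0.1 are
recorded in the config echo. Training is bitwise reproducible for a fixed
seed on one thread; note that with batch norm the epoch loss depends on
batch composition, so even a frozen model's epoch losses vary at the 1e-7
relative level across shuffles.

## Baselines

PLSR (centred, default 10 latent variables, optional internal 5-fold CV
selection), RBF-SVR with C=90 and γ=1, and PCR with 10 principal components
(component signs fixed by making the largest-magnitude loading positive, so
refits are bitwise reproducible). Classification: PLS-DA (PLS on one-hot
indicators + argmax; bands standardized so decisions are invariant to common
rescaling), RBF-SVM with C=10 and γ="scale", and LDA with recursive feature
elimination that drops the 10 % of surviving bands with the smallest
aggregate absolute discriminant coefficient per round (the elimination
schedule is unspecified upstream; 10 % per round is this package's choice,
recorded in the model's parameters). Scale-sensitive models standardize
internally; projection models are centred only.

## Metrics and cross-validation

R² = 1 − SS_res/SS_tot (about the reference mean — the RPD identity below
rules out the squared-correlation reading), RMSE, and RPD = SD(y_ref)/RMSE.
RPD uses the population SD (divide by n) by default so RPD = 1/√(1−R²)
holds exactly — the convention consistent with published metric tables,
verified in the suite against an independently transcribed 18-row benchmark
table (identity within ±0.01; RPD × RMSEP constant within each index to
±0.003). The sample-SD convention is available by flag. Perfect predictions
yield RMSE 0 and an RPD overflow flag. Percent changes are reported to one
decimal, rounded half-away-from-zero. Stage summary tables use the sample
SD (n−1); a single-record stage reports SD as missing.

Classification uses stratified five-fold cross-validation in which the whole
pipeline — scaling, feature elimination, model fit — is refitted from
scratch on each fold's training portion; accuracy, macro precision, macro
recall and macro F1 are computed from predictions aggregated across folds
(with balanced classes, micro-averaging equals accuracy; macro is reported
for robustness). A guard test confirms the protocol stays at chance on
random labels even with aggressive feature selection in the loop.

## Synthetic generator

Quality records: per-stage truncated normal FI and SSC (Table-style means,
SDs and ranges for P1–P5), joined by a Gaussian copula with correlation −0.3
(firmer fruit tend to be less sweet; the true joint distribution is unknown,
so the value is configurable), sampled by exact inverse-CDF with no
rejection. FSR is computed per record, so FSR = FI/SSC holds to machine
precision.

Spectra: a smooth linear baseline whose level (+0.010 per N) and slope
(−0.006 per N) track FI, emulating scattering changes with texture; Gaussian
absorption dips at 970, 1080 and 1270 nm whose depths follow per-stage
multiplier profiles; a 1200 nm dip with depth 0.015 per % SSC (C–H sugar
overtone); and a 1450 nm water band whose depth grows 0.03 per stage and
whose centre drifts 5 nm per stage. Each fruit sits at a jittered position
on the maturity continuum (SD 0.06 stages). The per-stage profiles for
1080/1270 nm are deliberately non-monotone: real absorbers evolve at
different, partly non-monotonic rates, so the five stage-mean spectra span a
non-degenerate simplex in band space. This matters for PLS-DA specifically —
with a collinear stage signature, least-squares regression on class
indicators masks the middle classes (the classic masking pathology) even
when LDA separates perfectly, and the generator's calibration contract is
that both linear classifiers reach 100 % five-fold accuracy at default
noise. Additive i.i.d. band noise (SD 0.008) is applied last and reflectance
is clipped to [0.01, 1.0].

What the generator does **not** emulate: radiative transfer, scatter/path-
length artefacts (MSC/SNV territory), instrument drift, wavelength
miscalibration, fruit-to-fruit surface geometry, or any nonlinear
quality–spectrum coupling. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes — not that it would achieve the
same numbers on orchard data, where noise and confounding are far less
benign. The deliberately favourable signal-to-noise ratio is why synthetic
R²/RPD values exceed those achievable on real fruit.

Synthetic cubes: an elliptical "fruit" (semi-axes 42 % of the frame) whose
per-pixel FI/SSC fields vary smoothly (radial softening plus a low-frequency
lobe scaled by the stage SDs), a flat 0.25-reflectance background, and raw
digital numbers constructed as RD + R·(RW − RD) so whiteboard correction
recovers the intended reflectance exactly; ground-truth per-pixel maps are
returned for visualization tests.

## Problem sizes in the test suite

The acceptance-level regression check trains the CNN–LSTM on the full
480-sample calibration split for 60 epochs per target — convergence on the
synthetic coupling is reached well before that (held-out R² plateaus near
0.99 by epoch 40), so a longer budget would only add runtime. The
noise-degradation check runs at a compact scale (40 fruit per stage, 40
epochs, three noise levels 0.008/0.06/0.2) where the monotone R² decline
(≈0.98 → 0.88 → 0.66) is already unambiguous. Layer gradients are verified
by central finite differences at float32-appropriate tolerances; forward
passes are verified against naive loop/scipy oracles.

## Numerical choices and edge cases

- Convolution/pool length formula: floor((L + 2p − k)/s) + 1; geometries
  with empty outputs raise before any compute. A 10-band input yields
  (128, 1) branch maps — short inputs stay fusable down to the formula's
  limit.
- Batch-norm in inference mode uses running statistics, making prediction
  batch-size independent to float tolerance.
- SPXY ties: lowest index after the seeded shuffle; duplicated samples
  (zero distances) still terminate with the requested count.
- Empty ROI masks, out-of-bounds ellipses/rectangles, band-count mismatches,
  zero-variance references, non-positive SSC, degenerate color scales and
  unfitted predictors all raise typed contract errors.
- Pixel-wise prediction is chunked row-major; results are independent of
  chunk size up to BLAS rounding. Mean-over-region equals prediction of the
  mean spectrum for linear models only; no such identity is asserted for the
  nonlinear networks.

## Known limitations

- The numpy training core is single-threaded and CPU-bound; it is meant for
  desk-scale experiments, not GPU-scale hyperparameter sweeps.
- The LSTM stage sees a length-1 sequence by construction; claims about
  "temporal" modeling reduce to a gated nonlinearity on the fused feature.
- PLS-DA latent-variable count and the LDA-RFE schedule are conventions, not
  fitted constants; both are exposed as parameters.
- The generator's couplings are phenomenological and linear-Gaussian;
  distribution shift, batch effects and seasonal variation are out of scope.
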