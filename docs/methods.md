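# Methods

`hsiph` implements a complete near-infrared hyperspectral-imaging (HSI)
chemometrics chain for determining and mapping the pH of anaerobic-digestion
liquid, together with a phantom generator that supplies statistically
realistic test scenes. This note records the models, the tunable parameters
and the design decisions, in the package's own terms.

## Measurement model and preprocessing

A push-broom NIR camera produces a cube of raw counts `I_r(row, col, band)`
over a nominal 874–1734 nm range (256 bands by default). Counts are
converted to relative reflectance with a white reference `I_w` (Teflon tile,
~100 %) and a dark frame `I_d`:

    R = (I_r − I_d) / (I_w − I_d).

Elements with `I_w − I_d ≤ 0` are flagged invalid (NaN plus a validity
plane) rather than silently divided. Spectral edges of this detector class
are noisy, so analysis is restricted to the working range
**1042.16–1578.13 nm**; on the default wavelength grid that window holds
exactly **160 bands**. The grid is even with step
(1578.13 − 1042.16)/159 ≈ 3.3709 nm, anchored so both window endpoints are
grid points; the exact instrument grid is not public, so band count and
range are configurable, and the band-reduction bookkeeping
(`reduction_percentage`) is computed from whatever grid is configured.

Each pixel spectrum is denoised by a multilevel discrete wavelet transform,
**Daubechies-5 at level 5** by default, with symmetric boundary extension.
Detail coefficients are soft-thresholded at the universal threshold
`σ√(2 ln n)`, with `σ` estimated from the median absolute deviation of the
finest detail level (MAD/0.6745). Soft vs hard thresholding is configurable
(`WaveletSpec.threshold_rule`); the exact rule used in the original
workflow is unpublished, so the choice is explicit and logged. Note that
level 5 on a 160-point spectrum exceeds PyWavelets' conservative
"useful maximum" of 4; the decomposition is well defined and perfectly
reconstructing, so the package enforces only the hard bound `n ≥ 2^level`.

The **sample spectrum** is the dish-interior mean of the denoised pixel
spectra — denoise first, then average. The order matters: soft thresholding
is nonlinear and shrinks signal detail coefficients by up to the threshold,
a systematic bias of order 0.003–0.01 reflectance at pixel noise SD 0.005.
Training on spectra that carry this bias and predicting on pixels that
carry it too makes the bias cancel; training on noise-free means and
predicting on shrunken pixels does not.

The Petri-dish ROI is segmented at a single reference band: Otsu threshold,
largest connected component, then morphological erosion by the rim width,
because the dish edge has spectral features unlike the liquid. The
segmentation recipe is this package's choice; only its goal (interior
without the rim) is inherited from the workflow being reproduced.

## Sample splitting

Samples are split **2:1** into calibration and prediction sets by repeated
random draws (≤ 1000, seeded) until the prediction-set pH range lies inside
the calibration-set range, so prediction-set evaluation never extrapolates.
93 samples give sizes (62, 31).

## Wavelength selection

* **SPA** (successive projections algorithm). From a start column, grow a
  chain by repeatedly appending the band whose column has the largest norm
  in the orthogonal complement of the selected columns' span (ties to the
  lowest index; columns mean-centred). Every (start, chain-length) pair
  with lengths 5–30 (configurable) is scored by 5-fold cross-validated
  multiple linear regression RMSE, and the global minimiser is returned.
  The validation scheme behind the original subset scoring is unpublished;
  5-fold CV is this package's documented choice.
* **Random frog.** A stochastic subset search: from a current subset of
  size Q (initially 10), propose a candidate whose size is drawn from
  `round(N(Q, 0.3 Q))`; grow by pooling random outside bands (3× the
  deficit) and keeping the best by |PLS coefficient|, shrink by keeping the
  best by |PLS coefficient|. Candidates are scored by cross-validated PLS
  RMSE; better candidates are always accepted, worse ones with probability
  `0.1 · RMSECV_cur / RMSECV_cand`. The per-band inclusion frequency over
  N iterations (default 10,000) is its selection probability; the final
  subset is the probability top-k minimising RMSECV. CV folds are re-drawn
  at every evaluation — a fixed partition lets the search overfit that one
  split and drift toward bloated subsets — while the final top-k curve uses
  one common partition so sizes are comparable.
* **VIP.** From a fitted PLS model with A components,
  `v_j = sqrt( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a )` with
  `SSY_a = q_a² t_aᵀt_a`; bands with `v_j > 1.21` (the workflow's threshold)
  are kept. The mean squared VIP score is identically 1. VIP uses the same
  A as the chosen full-spectrum PLS model.

## Calibration models

* **PLS1**, iterative NIPALS with mean-centring (no scaling). Exposes
  weights, loadings, y-loadings and scores (the VIP ingredients); training
  scores are mutually orthogonal, and prediction via the collapsed
  coefficient vector `B = W(PᵀW)⁻¹q` equals prediction via the deflation
  recursion to 1e−10. The number of latent variables is chosen by 5-fold
  cross-validated RMSE (the original workflow delegated this to commercial
  software whose rule is unpublished).
* **BPNN**, a three-layer feed-forward network: standardised inputs, tanh
  hidden layer, linear output on a min–max-scaled response. Hidden-layer
  width candidates follow `b = round(√(m+n)) + a`, `a = 1…10` (the widely
  used heuristic; the printed form of this rule in the source workflow is
  typographically corrupt, and its own node counts — 14 hidden nodes for
  160 inputs — match the rooted version). Each candidate is trained and the
  one with minimal held-out RMSE wins. Training is full-batch
  backpropagation with the Adam step rule (1500 epochs, learning rate 0.01,
  seeded initialisation, loss curve retained); plain fixed-step gradient
  descent needs an impractical epoch budget to reach the same training
  error on these small problems. The original training algorithm is
  unpublished.

Models are scored by Pearson correlation (r_c, r_p) and RMSE (RMSEC,
RMSEP) on the calibration and prediction sets.

## Pixel-wise pH mapping

Applying a calibration model to every ROI pixel of a calibrated, cropped
cube yields the pH distribution map. Pixel spectra are denoised with the
training-time wavelet settings (train/apply preprocessing must match),
subset to the selected bands when the model was built on a selection, and
predicted. Predictions outside the calibration pH range are **kept and
flagged**, not clipped — such pixels mark model extrapolation and hiding
them would overstate validity. Rendering writes an 8-bit PNG at the cube's
exact pixel dimensions (display clipping is presentation-only), a colourbar
legend, a CSV dump of the value grid and a JSON sidecar with the flagged
fraction.

## The phantom generator

No raw images are public, so every stage is exercised on synthetic scenes.
The optical model is deliberately plain chemometrics, not radiative
transfer:

* liquid reflectance `R(pH, λ) = baseline(λ) − Σ_k A_k g_k(λ)` with three
  Gaussian absorption features near **1200, 1395 and 1520 nm** (widths
  45/35/40 nm), placed where the selection methods are expected to find
  signal; amplitudes are affine in pH,
  `A_k = base_k + slope_k (pH − 7.34) + δ_k`, with slopes
  (0.060, −0.080, 0.050) absorbance per pH unit — chosen so the full pH
  range moves reflectance by a realistic few per cent;
* `δ_k ~ N(0, 0.003)` is per-sample compositional jitter unrelated to pH:
  real digestate varies in more than pH, and this term sets the phantom's
  ceiling on attainable prediction quality near the levels the original
  study reports rather than at r_p ≈ 1;
* each scan carries a spectrally white, **spatially constant** reflectance
  error `~N(0, 0.002)` per band (white-reference/illumination drift between
  scans). This term is essential: it is the noise that does *not* average
  out over a dish, so it is what keeps averaged sample spectra off the
  exact model manifold. Without it, cross-validation on averaged spectra
  cannot penalise collinear coefficient blow-up, and a model that looks
  perfect on sample means amplifies per-pixel noise catastrophically when
  applied pixel-wise;
* i.i.d. Gaussian per-pixel, per-band noise (default SD 0.005 reflectance);
* geometry: a disc-shaped dish on a dark background (reflectance 0.12) with
  a bright, spectrally flat rim (0.95) whose spectrum differs from the
  liquid; raw/white/dark count cubes are emitted so the reflectance
  correction is exercised end to end.

True pH is drawn from a normal distribution truncated to [7.13, 7.48].
The parent (μ, σ) is solved numerically so the *truncated* law matches the
target mean 7.34 and SD 0.10 as closely as the family allows; an exact
match is infeasible — the supremum SD of any truncated normal on that
interval with mean 7.34 is ≈ 0.097 (the tilted-uniform limit) — so the
achieved moments are ≈ (7.340, 0.097), inside the 0.01 tolerance the tests
use. Mapped scenes draw an independent pH per interior pixel; training
dishes are uniform at their sample's pH (one reference reading per dish).

What the phantom does **not** emulate: scattering and radiative-transfer
physics, spatially smooth illumination gradients, wavelength-correlated
(pink) noise, instrument spectral response, digestion kinetics over time.
Passing tests therefore demonstrate correctness and statistical sanity of
the algorithms under a faithful noise budget, not instrument-level realism.

## Problem sizes and numerical choices

* Pipeline and acceptance runs use 93 samples, 300 dish pixels per sample
  (the mean's noise floor scales as 1/√n, so 300 of ~1500 interior pixels
  is statistically equivalent for training), a 64×64 mapped scene, and the
  full 160-band working range. Unit tests use 32–64-band grids and smaller
  dishes; recovery suites use the sample sizes stated in their docstrings.
* SPA ties break to the lowest band index; chains stop with an error when
  the residual rank is exhausted (norm < 1e−12 of the matrix scale).
* PLS truncates with a warning if rank is exhausted before the requested
  component count; degenerate (constant) responses are rejected.
* The BPNN rejects non-finite losses with advice to lower the learning
  rate; y-scaling requires a non-constant response.
* Out-of-range map pixels are flagged where prediction < min or > max of
  the calibration-set pH.
* All randomness flows through `numpy.random.Generator` objects seeded from
  explicit config fields; identical configs reproduce identical artifacts
  (the run manifest records SHA-256 hashes to verify this).

## Known limitations

* The published performance tables of the source workflow were measured on
  real, undeposited images; they are context, not reproduction targets —
  phantom metrics land in a similar range by construction of the noise
  budget, not by fitting to those tables.
* The BPNN is intentionally minimal (one hidden layer, full-batch Adam);
  it is not a general-purpose regressor.
* Random frog probabilities at N = 2000 still carry visible Monte-Carlo
  noise; the study default N = 10,000 sharpens them at proportional cost.
* The ENVI codec covers the plain header + BSQ/BIL/BIP raster subset
  (byte order 0, five dtypes), not the full ENVI specification.
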