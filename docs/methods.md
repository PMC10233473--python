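# Methods

`tiltsheet` models an immersion tilted light-sheet / epi-illumination
fluorescence microscope and the computational chain built on it: sheet
calibration, cross-modality background removal with a recurrent
convolutional network, image-quality metrics, and single-molecule
localization. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data do and do not capture.

## Illumination and image formation

The excitation sheet is a cylindrically focused Gaussian beam whose
mid-plane is inclined by the tilt angle θ to the detection focal plane and
crosses it at a configurable lateral position. Its irradiance is

    I(d, s) = I₀ · (w₀ / w(s)) · exp(−2 d² / w(s)²),
    w(s) = w₀ · sqrt(1 + (s / z_R)²),

with d the perpendicular distance to the mid-plane, s the in-plane
distance from the focus along propagation, w₀ the 1/e² half-thickness and
z_R the Rayleigh range. Thickness is always reported as an intensity FWHM,
FWHM = sqrt(2 ln 2)·w. The effective field of view — the lateral extent of
the focal plane lying inside the sheet's FWHM thickness — is
`eFOV = FWHM / sin θ`; at θ = 18° this gives 4.0, 7.8 and 5.2 µm for
FWHM 1.25, 2.4 and 1.6 µm, reproducing the characteristic values of such
instruments after rounding.

Detection uses an isotropic Gaussian PSF whose standard deviation grows
with defocus, σ(z) = sqrt(σ₀² + (αz)²) with defaults σ₀ = 130 nm and
α = 200 nm/µm — the simplest model that produces out-of-focus haze under
epi illumination and clean optical sectioning under the sheet. Emitters
are rendered as pixel-integrated 2D Gaussians (error-function integration
over 157 nm pixels, the camera's sample-plane pitch); photons are
conserved up to border clipping. Pixel (row, col) has its centre at
((col + 0.5)·p, (row + 0.5)·p); z = 0 is the focal plane.

The camera is an EMCCD-style Poisson–Gaussian model: photoelectrons are
Poisson-drawn from the expected image, amplified by the EM gain — with an
optional gamma-distributed gain that doubles the shot-noise variance, the
standard high-gain approximation of the EM register — then offset and
Gaussian read noise are added. Defaults: gain 100, offset 100 counts,
read noise 10 counts, QE 0.9.

Phantoms come in three classes: `shell` (emitters uniform in a spherical
annulus — hollow, nucleolus-surface-like structures), `dense_volume`
(uniform in an ellipsoid) and `sparse_molecules` (uniform in a box, with
an optional minimum lateral separation; see Localization below). Blinking
is a per-frame two-state Markov chain with an optional absorbing bleached
state.

## Sheet calibration

A profile z-scan images the sheet cross-section at focal planes from −10
to +10 µm in 0.5 µm steps, 100 camera frames averaged per plane. Per
plane, the image is collapsed along the stripe (mean) and fitted with a
Gaussian plus constant baseline (seeding: centre = argmax, width from the
background-subtracted second moment, baseline = 10th percentile); FWHM is
2·sqrt(2 ln 2)·σ. Tilt comes from the OLS slope of centre vs z
(centre(z) = z/tan θ + c); the stripe's lateral FWHM times sin θ is the
perpendicular sheet thickness, fitted against s = z/sin θ with the
Gaussian-beam hyperbola F(s) = F₀·sqrt(1 + ((s−s₀)/s_R)²).

The stripe seen in one z-plane is an *oblique cut* of the beam: the
thickness varies across the cut, so the per-plane Gaussian width
overestimates the true thickness — by up to ~8% for a 3 µm sheet at 10°
tilt (it is <1% at 18°/1.25 µm). `calibrate_stack` therefore refines the
two-step estimates with a joint least-squares fit of all collapsed
profiles to the full oblique-cut model (seven parameters: θ, w₀, z_R,
focus position along x and s, amplitude, baseline), which removes the
bias; `refine=False` restores the plain two-step procedure. Round-trip
recovery on noisy scans over tilt ∈ [10°, 40°], waist ∈ [1, 3] µm is
within ±1° and 5% (in practice ≪1%). Degenerate inputs (flat profiles,
monotone or constant FWHM series) are flagged, not silently fitted.

## Training-data preparation

Raw material is pairs of 100-frame stacks of the same field under epi and
sheet illumination. Frames are averaged (noise ∝ 1/√100), then patches are
cut from the ~5 µm illumination centre strip — 32 px at 157 nm — where the
tilted sheet actually sections the sample; crops_per_pair defaults to 3,
spaced along the strip, with identical windows on both modes. A
quality filter rejects pairs whose averaged sheet strip has low contrast
(mean of the brightest decile over the dimmest half, on raw counts so the
camera offset serves as the background floor; threshold 1.2). Patches are
percentile-normalized (0.1 → 0, 99.9 → 1, clipped), by default with the
affine computed from the *target* so input and target stay on one
intensity scale; the affine is stored for inversion. The train/validation
split is seeded and applied at the pair level, so no field contributes to
both sets.

## The restoration network

The background-removal network is a progressive recurrent design: one
parameter set applied over T stages. Each stage concatenates the original
input with the previous stage's output (2 channels) and passes it through
batch normalization, a 3×3 convolution + ReLU (`f_in`), a convolutional
LSTM cell whose hidden/cell state persists across stages (`f_lstm`), five
residual blocks (conv–ReLU–conv with additive skip, ReLU after the add;
`f_res`), and a 1×1 convolution back to one channel (`f_out`). The BN on
the raw input lets the network learn its own input scaling. The loss is
the mean squared error of the final stage's output; Adam with lr 10⁻³,
β₁ 0.9, β₂ 0.999, ε 10⁻⁸ and batch size 128 are the full-scale defaults.
`MPReNetConfig.desk()` is the CPU profile used throughout the tests:
T = 3, 16 channels, batch 16, a few hundred optimizer steps.

Two behaviours are config hooks rather than fixed: `global_residual`
(default off) adds each stage's output to the original input, so the
network predicts a correction — minus the background — rather than the
image itself; and the normalization convention (`norm_source`) can anchor
to the input instead of the target. The network and its training loop run
on a small in-package reverse-mode autodiff engine over numpy (stride-1
same-padding convolution as per-tap BLAS matmuls, ConvLSTM gating, batch
normalization with running statistics, Adam); gradients are verified
against finite differences in the test suite.

Large-field inference normalizes the input (dataset convention, a stored
photon-unit affine, or an explicit one), runs overlapping tiles, and
blends them after trimming a receptive-field margin from each tile border:
a pixel at least R = T·(2 + 2·n_res) px inside a tile is unaffected by
padding, so with overlap ≥ 2R the stitched result equals the full-frame
pass to float precision. Images smaller than the tile get one pass.

Receptive field and patch size interact: R = 36 px for the desk profile,
so a 32×32 patch is *entirely* border-influenced. Models intended for
whole-frame inference are therefore trained on patches of the acquisition
frame size (the spot-background model below uses 64×64); training at
32×32 and inferring at 64×64 transfers poorly.

## Image metrics

Structure SBR is mean(signal ROI)/mean(background ROI); the spot form is
(peak-disk mean − annulus median)/annulus median, which can fall below 1
for molecules dimmer than their surroundings. Both assume camera-offset-
corrected images. SSIM uses the standard Gaussian-window formulation
(11×11, σ = 1.5, k₁ = 0.01, k₂ = 0.03, population covariance), verified
against scikit-image to 10⁻⁶; NRMSE is RMSE over the reference dynamic
range. Enhancement is a plain ratio of SBRs.

## Single-molecule localization

Per frame, in order: (1) counts minus offset; (2) optional denoising
(identity, light Gaussian, or Anscombe-VST wavelet soft-thresholding with
the closed-form unbiased inverse) — the stage is pluggable because the
choice of denoiser is data-dependent; (3) background removal: none, the
learned model (tiled inference), or rolling-ball subtraction. Rolling-ball
runs on the count scale, where a radius-50 px ball cannot follow a
multi-thousand-count step — exactly the documented failure mode near
nucleus/nucleolus edges; on a rescaled image the same ball would track the
step and the comparison would be meaningless. (4) Counts become photons
(÷ gain); (5) the à-trous B-spline wavelet first plane F1 = V1 − V2
(kernel [1,4,6,4,1]/16, then its ×2-dilated version applied to V1);
(6) local maxima of F1 above k·std(F1) (k = 4, per-frame statistics;
connected plateaus count once, represented by the lexicographically
smallest pixel); (7) weighted least squares over a 9×9 window: integrated
symmetric 2D Gaussian + constant, weights 1/max(model, 1) (shot-noise
weighting), rejecting border windows, non-convergence, fits below one
photon, and widths outside [0.5, 3]·σ₀. Localization uncertainty is the
Thompson-style combination of width, pixelation and background.

Table post-processing: inclusive photon filter 500–2500; drift correction
by plain FFT cross-correlation of 2D histograms of 5 temporal bins at
pixel/5 bin width, sub-bin quadratic peak interpolation, per-frame linear
interpolation between bin centres (the first bin is the reference, so
drift is recovered up to a global constant; bins with <10 localizations
are interpolated through with a warning); duplicate removal merges
same-frame pairs closer than 30 nm in increasing-distance order, keeping
the higher-photon record, until no close pair remains. Evaluation uses
per-frame greedy one-to-one matching on sorted distances within a
tolerance (100 nm in the tests).

Only single-emitter fitting is implemented. Accordingly the fidelity
experiments place emitters with a minimum lateral separation (0.6–0.8 µm):
for closer pairs the single-Gaussian model absorbs the neighbour into its
background term and the photon estimate is not meaningful.

## Reference experiments and their problem sizes

`tiltsheet.experiments` packages the desk-scale protocols used by the
validation suite:

- **Calibration recovery** — 10 random geometries, full ±10 µm scan with
  100-frame averages on a field wide enough to follow the stripe drift.
- **Shell training** — 96 fields of a 500-emitter surface shell plus a
  2000-emitter dim volume population (the out-of-focus labeling that
  produces the epi haze the sheet rejects); 100 frames per mode, photon
  rates 60/15 per frame, gain 50; 3 crops each → ~260 training patches of
  32×32; desk network, 300 Adam steps. Held-out evaluation: SSIM and
  NRMSE against the sheet target, and the SBR enhancement of predictions
  over epi inputs on the shell mid-plane ring.
- **Spot-background model** — 288 64×64 patches of 4–12 molecules of
  700–1600 photons over smooth backgrounds with random sharp steps up to
  240 photons/px; targets are the noiseless signal (the analogue of the
  heavily frame-averaged ground truth); `global_residual` on; fixed
  unclipped photon-unit normalization (600 photoelectrons → 1, above the
  full signal range) stored in the model so fitted amplitudes survive the
  round trip.
- **Step retention** — a 50-frame blinking movie over an 8 → 188
  photons/px vertical background step, a step height comparable to a
  molecule's peak-pixel signal (the nucleolus-edge regime where a sharp
  edge genuinely competes with detection); true localizations recovered
  within 500 nm of the step are counted under model-based vs rolling-ball
  background removal.
- **Localization fidelity / drift** — 50-frame flat-background movie of
  20 continuously emitting 1000-photon molecules; and a clustered
  localization table with 100 nm of injected linear drift.

## What the synthetic data do not capture

The phantoms are geometric idealizations: no refractive-index aberrations,
no fiber speckle, no vectorial PSF, no sample motion, no heterogeneous
labeling density, and the out-of-focus background is exactly the model
PSF's haze rather than real intracellular autofluorescence. Passing the
suite therefore demonstrates that the algorithms are implemented correctly
and behave as designed under the stated noise model — not that a network
trained here would transfer to real acquisitions, which is why the
full-scale training profile, the pluggable denoiser and all acquisition
parameters remain configurable.

## Known limitations

- Single-emitter fitting only; dense fields bias photon estimates.
- The EM-register model is the gamma variance-doubling approximation, not
  a cascade simulation.
- Drift recovery is limited by the temporal-bin discretization (constant
  offset to the reference bin; ~bin-width accuracy per bin before
  interpolation).
- The autodiff engine is deliberately minimal (float32, stride-1 odd
  kernels only) and favours clarity over speed; desk-scale training takes
  minutes on one CPU core.
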