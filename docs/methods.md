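# Methods

This note documents the models, numerical choices and limitations behind the
`mlao` package: a simulation-backed implementation of machine-learning-assisted
wavefront-sensorless adaptive optics (MLAO) for microscopy.

## Image formation

Aberrations are expressed on the Zernike basis with Noll indexing and RMS
normalization: a coefficient is the mode's RMS phase contribution in radians,
and the RMS wavefront error of a modal aberration is the Euclidean norm of its
coefficient vector. Piston is excluded; the default estimated-mode sets also
exclude tip, tilt and defocus (Noll 2–4), which displace rather than blur the
image — standard sensorless-AO practice. N estimated modes default to Noll
5 … 4+N (N=7 → Noll 5–11).

The pupil is sampled on pixel centers (a pixel belongs to the pupil iff its
center lies in the unit disk) with `n_pupil` samples across the diameter inside
an `n_fft ≥ 2 n_pupil` array, so the intensity PSF

    f = |FFT(mask · e^{iφ})|²

is at least Nyquist sampled. Orthonormality of the sampled basis holds to
~1e-2 at `n_pupil = 128` (tested), so disk-RMS and coefficient-RMS agree to the
same tolerance, and the computed Strehl ratio matches the extended Maréchal
approximation exp(−σ²) within 2 % at σ = 0.3 rad (tested).

Modality enters as an excitation nonlinearity on the unit-sum excitation PSF:
widefield uses it directly (flux conserved under aberration, by Parseval),
two-photon squares it, three-photon cubes it — so the total nonlinear signal
strictly decreases with aberration, which is the physical basis of intensity
metrics. The detection PSF of the scanning modalities is ignored
(non-descanned detection). Images are circular FFT convolutions of a
nonnegative specimen map with the effective PSF, plus

    background + Poisson(photon_scale · clean)/photon_scale + N(0, σ_read),

deterministic given a seed. An optional widefield plane list `(defocus_rad,
weight)` sums the same specimen imaged through defocused PSFs to emulate
out-of-focus light; it is off by default and not part of the desk-scale study.

## Pseudo-PSF pre-processing

For a pair of frames acquired with equal-magnitude opposite-sign bias
aberrations, the pseudo-PSF is the inverse FFT of the spectral ratio
F(I₁)/F(I₂). Both spectra share the specimen factor F(O), which cancels,
leaving a specimen-independent function of the two PSFs. Numerical choices:

* **Regularized division** — `F(I₁)·conj(F(I₂)) / (|F(I₂)|² + eps·max|F(I₂)|²)`
  with `eps = 1e-3` by default. This equals the plain ratio away from spectral
  zeros and suppresses the blow-up near them; as eps → 0 on noiseless input it
  converges to the exact ratio (tested against an oracle computed directly
  from the PSFs).
* **Mean subtraction** of each frame before the FFT removes the arbitrary
  background/DC term. A fully structureless frame then has a zero spectrum;
  that degenerate case returns a zero map rather than NaNs.
* The real part is taken after the inverse FFT; the imaginary residue is
  numerical round-off.
* Both orderings (I₁/I₂ and I₂/I₁) are computed per pair — between the two
  channels every frequency is well conditioned in at least one.
* The central 32×32 crop (the input-center pixel lands at index (16, 16))
  is kept and each channel is normalized by its max-abs value, making the
  network input invariant to specimen brightness.

Specimen independence is quantitative, not absolute: across ten random bead
fields under a fixed aberration the pairwise correlation of cropped
pseudo-PSFs exceeds 0.95 (tested), while sparse fibre-like objects with strong
spectral zeros correlate less. Aberration changes of ≥ 0.5 rad RMS move the
pseudo-PSF by far more than specimen changes do (tested).

## Image-quality metrics

Four standard metrics are implemented: y_I (sum of the `l` brightest pixels,
`l > 200` in the published configuration, default 256), y_F (spectral
magnitude integrated over 0.1 f_max < |f| < 0.6 f_max), y_S (ratio of the
(n f_max, m f_max) band to the (0, n f_max] band, defaults n = 0.05, m = 0.6,
brightness-invariant), and y_T (mean over 36 10° angular segments of the
largest radius whose 1-pixel radial rings stay above the noise floor estimated
from the four spectrum corners). Frequencies are measured in DFT bins;
`f_max` defaults to the Nyquist radius, which on the default grid coincides
with the incoherent cutoff. The segment/ring granularity of y_T is a free
choice; results are insensitive to it for the images used here.

## Synthetic training data

Specimens are procedurally generated: Gaussian bead ensembles (Poisson count,
default density 1e-3 beads/pixel — a realistic dense ensemble field, and rich
enough spectrally for stable pseudo-PSFs), random-walk fibres, and power-law
filtered-noise textures standing in for natural microscope images (spectral
exponent drawn from [1, 2.5], soft-thresholded to keep a dim background).
Aberrations are drawn isotropically on the mode set with RMS uniform in
[0, 2.5] rad, covering the evaluated range. Per-example augmentations emulate
experimental uncertainty: brightness ×[0.5, 2], background ×[0, 2], photon
budget ×[0.5, 2], and a Gaussian blur of σ ∈ [0, 0.6] px applied to the frames
(PSF model mismatch). Each is toggleable. Dataset generation is a pure
function of (configuration, seed); a manifest allows byte-identical
regeneration.

What the generator does **not** model: specimen-induced field-varying
aberrations, sample motion between frames, fluorescence fluctuations
(a brightness-fluctuation toggle would sit naturally in `ModalityConfig` but
is out of scope), detector artifacts, and real natural-image content. Passing
tests therefore demonstrate correctness of the method under the stated imaging
model, not performance on any particular real microscope.

## The estimator network

The CNN maps an M-channel 32×32 pseudo-PSF stack to N coefficients through
five convolutional stages whose receptive fields grow 1 → 3 → 7 → 15 → 31
pixels (a 1×1 stage, then 3×3 stride-2 stages), 16 feature maps each. Each
stage is globally average-pooled; the concatenated 80-vector feeds a 64-unit
fully connected layer (FCL) and a linear output. Default parameter count is
~15k (tens of thousands), orders of magnitude below generic image-to-wavefront
networks.

Training minimizes MSE on the coefficient vector with Adam (lr 2e-3, batch
64), optional decoupled weight decay (0.05 in the desk-scale study, where it
improves validation RMSE; off by default since a fixed decay is miscalibrated
for very small datasets), early stopping on a 10 % validation split (patience
6); fully deterministic given a seed, NumPy throughout. Non-finite losses
abort with diagnostics rather than silently continuing.

### Weight introspection

`layer_weight_rms` reports, per scale stage, the RMS of the FCL weight block
fed by that stage's pooled features, expressed in standardized-feature units
(raw block RMS × the stage's calibrated feature standard deviation). The
common scale is what makes the per-stage comparison meaningful; raw weight
magnitudes confound information content with the arbitrary numeric range of
each stage's features. Feature statistics are calibrated on the training set
and stored in the checkpoint; they do not enter the forward computation
(scaling features inside the network was tried and destabilizes training by
amplifying gradients into rarely-active late-stage channels).

A caveat established by this package's own experiments: under the desk-scale
study the readout comes out near-uniform across stages (within ~15–25 % of
the isotropic initialization), i.e. the even weighting that full-scale astX
ensembles show, and it does **not** reproduce the strong single-pixel-stage
dominance reported for ensembles of fully trained all-modes-biased networks.
Two structural reasons: global average pooling dilutes the central-pixel
(Strehl-related) cue of the 1×1 stage by the whole 32×32 map area, and
desk-scale training barely reorganizes aggregate weight statistics. The
introspection API is in place and tested for its mechanics; its physical
pattern should be interpreted only for substantially trained models.

## Conventional baselines

`conv_2N1` (shared zero-bias frame + one ±b pair per mode, simultaneous) and
`conv_3N` (zero/+b/−b per mode, sequential) maximize a modality-appropriate
metric (y_I for 2-P/3-P, y_S for widefield) by fitting a parabola through the
three samples of each mode and moving to the stationary point

    x* = b (y₋ − y₊) / (2 (y₋ − 2 y₀ + y₊)),

clipped into [−b, b] and flagged when the samples are convex or the vertex is
out of range. The stationary point is applied as-is, exactly as in the
classical algorithm: when the metric samples are convex (large aberrations,
where the metric curve's tails flatten), the stationary point is a *minimum*
and the step is anti-corrective. This is the known failure mode of the
conventional method at large aberration, and it reproduces in the study below.
Mode order for `conv_3N` is ascending Noll index.

A relevant property of this simulator: the 2-P intensity-metric curve versus a
single mode coefficient has a half-width of roughly 0.5 rad, narrower than in
typical experimental systems. Consequently ±1 rad biases (the conventional
default) leave the quadratic regime once per-mode coefficients exceed
~0.5 rad, and the conventional methods underperform at mid-range aberrations
here more than they would on a wider-curve system. The quadratic-regime
demonstration in the tests therefore scans with b = 0.75 rad around a 0.4 rad
aberration, where the recovery error is < 0.05 rad.

## The desk-scale study

All statistical results are computed by one pinned experiment (`mlao.study`):
64-sample pupil in a 128-point FFT, 128×128 field, two-photon modality with
photon_scale 1e5 (≈10³ photons at a bead peak), read noise 2e-4, background
2e-3; `2N` biasing at ±1 rad over N = 3 modes (Noll 5–7); 5,000 training
examples, 30 epochs, weight decay 0.05. The reduced grid and N keep the full
pipeline — synthesis, training, evaluation — at around six minutes on one CPU;
the package defaults for one-off simulation remain 128/256.

The study evaluates: (i) held-out per-mode predicted-vs-true correlation,
(ii) the fraction of one-cycle closed-loop corrections with input RMS in
[0.8, 2.0] rad that reduce the residual, (iii) mean residuals of the learned
estimator and `conv_2N1` on identical systems with input RMS in [2.0, 2.4]
rad, and (iv) the per-stage FCL weight RMS. `scripts/acceptance.py` recomputes
all of it from a single seed.

## Known limitations

* Scalar (low-NA) diffraction; no vectorial effects, no specimen-induced
  raytracing, no SIM pattern formation.
* Circular convolution wraps structure at field edges; objects are generated
  on the full field so wrap-around is statistically harmless but present.
* The conventional-baseline comparison inherits the narrow metric curve noted
  above; absolute conventional-method performance at mid-range aberrations is
  pessimistic relative to wide-curve experimental systems.
* The study trains at N = 3; recovery quality at N = 7–9 modes with the same
  desk-scale budget degrades gracefully but is not pinned by tests.
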