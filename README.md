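# mlao — machine-learning-assisted sensorless adaptive optics for microscopy

High-resolution microscope images are degraded by optical aberrations, most
often induced by the specimen's own refractive-index structure. Adaptive
optics (AO) corrects them with a reconfigurable element (deformable mirror or
spatial light modulator). In *sensorless* AO the aberration is inferred from
images themselves: known **bias aberrations** are deliberately applied, and
the way the image changes reveals the unknown wavefront.

This package is a simulation-backed toolkit for the machine-learning-assisted
variant of that idea (MLAO), aimed at microscopy/AO researchers who want to
study, train, and benchmark the approach without hardware:

* **Physics simulation** — Zernike wavefronts (Noll indexing, RMS
  normalization), Fourier-optics PSFs, and image formation for two-photon,
  three-photon and widefield modalities with a Poisson + Gaussian noise model.
* **Pseudo-PSF pre-processing** — for a frame pair acquired with opposite
  biases, `F⁻¹[F(I₁)/F(I₂)]` cancels the unknown specimen structure
  (`I = O ∗ f + δ`), leaving a specimen-independent function of the two PSFs.
  The central 32×32 crop is the estimator input.
* **A compact multi-scale CNN** (~15k parameters, NumPy, deterministic
  training) mapping M pseudo-PSF channels to N Zernike coefficients. Five
  convolutional stages probe the pseudo-PSF at receptive fields growing from
  a single pixel to 31 pixels; per-stage fully-connected weight blocks are
  individually addressable, so the trained network's reliance on each spatial
  scale can be read out (`layer_weight_rms`).
* **Bias schemes** — `ast2`/`ast4` (astigmatism-only, M = 2 or 4 frames per
  cycle), `2N`/`4N` (all estimated modes biased, M = 2N or 4N), plus the
  conventional `2N+1` (simultaneous) and `3N` (sequential) baselines with
  parabolic metric fitting.
* **Closed-loop correction and evaluation** — a simulated microscope with a
  hidden aberration, uniform estimator interfaces, correction traces,
  image-budget accounting, and residual-vs-input statistics; four standard
  image-quality metrics (y_I, y_F, y_S, y_T).

See `docs/methods.md` for the models, parameter choices, and limitations.

## Worked example

One conventional 2N+1 correction cycle on a simulated two-photon microscope
(three estimated modes, ±0.5 rad biases, seven frames):

```python
import numpy as np
from mlao import (PupilGrid, ModalityConfig, ZernikeCoefficients,
                  SimulatedMicroscope, ConventionalEstimator, default_metric_for,
                  generate_specimen, SpecimenSpec)

grid = PupilGrid(n_pupil=64, n_fft=128)
cfg = ModalityConfig("2P", photon_scale=1e5)
obj = generate_specimen(SpecimenSpec("beads", seed=42), shape=(128, 128))
aberration = ZernikeCoefficients({5: 0.3, 6: -0.25, 7: 0.2})
system = SimulatedMicroscope(obj, aberration, cfg, grid, seed=0)
estimator = ConventionalEstimator("conv2N1", (5, 6, 7), default_metric_for(cfg), b=0.5)

print(f"input aberration RMS: {aberration.rms():.3f} rad")
correction = estimator.one_cycle(system)
print(f"applied correction:   {dict((j, round(c, 3)) for j, c in correction)}")
print(f"residual RMS:         {system.residual_rms():.3f} rad "
      f"after {system.images_acquired} images")
```

prints

```
input aberration RMS: 0.439 rad
applied correction:   {5: -0.339, 6: 0.25, 7: -0.181}
residual RMS:         0.044 rad after 7 images
```

— the metric scan recovered most of each mode (the small residual is the
parabolic-fit approximation error), reducing a 0.44 rad wavefront error to
0.04 rad, i.e. well into the diffraction-limited regime. The learned
estimator does the same job from as few as two frames and keeps working at
aberration sizes where the parabolic fit breaks down; train one with
`mlao.study.train_study_model` or the CLI below.

## Command line

```sh
mlao simulate --config cfg.yaml --outdir out --seed 1   # biased frames + ground truth
mlao dataset  --config cfg.yaml --outdir ds             # synthetic training set
mlao train    --config cfg.yaml --outdir run            # CNN checkpoint + loss curve
mlao correct  --config cfg.yaml --method conv2N1        # closed-loop run, trace CSV
mlao evaluate --config cfg.yaml --model run/model.npz   # residual-vs-input statistics
mlao inspect-weights run/model.npz                      # per-stage FCL weight RMS
```

Every run writes a `manifest.json` (config hash, seeds, outputs) from which
it can be reproduced exactly.

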