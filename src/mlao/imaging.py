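"""Fourier-optics PSF generation and image formation for 2-P, 3-P and widefield.

The scalar-diffraction model: the pupil field is ``mask * exp(i*phase)``; the
intensity PSF is the squared modulus of its Fourier transform, DC-centered.
Modality enters through the excitation nonlinearity — the effective PSF of a
two-photon system is the pointwise square of the (unit-sum) excitation PSF,
three-photon the cube, widefield the detection PSF itself.  Images are circular
convolutions of a nonnegative specimen map with the effective PSF plus
background, Poisson shot noise and Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift

from .zernike import PupilGrid, ZernikeCoefficients, evaluate_wavefront

__all__ = [
    "ModalityConfig",
    "ImageFrame",
    "psf_from_phase",
    "effective_psf",
    "form_image",
    "acquire_biased",
]

_ORDER = {"widefield": 1, "2P": 2, "3P": 3}


@dataclass
class ModalityConfig:
    """Imaging modality and noise model.

    Parameters
    ----------
    modality:
        ``"2P"``, ``"3P"`` or ``"widefield"``; sets the excitation
        nonlinearity order (2, 3, 1).
    photon_scale:
        Expected photons per unit of clean image intensity; 0 disables shot
        noise.  Shot noise is ``Poisson(photon_scale * clean) / photon_scale``.
    read_noise:
        Standard deviation of additive Gaussian read noise (intensity units).
    background:
        Constant background level added before the noise.
    brightness:
        Global gain applied to the noiseless specimen signal.
    defocus_planes:
        Optional list of ``(defocus_rad, weight)`` pairs modelling
        out-of-focus planes in widefield imaging: the image is the weighted
        sum of the object seen through the PSF defocused by ``defocus_rad``
        of Noll-4 defocus.  ``None`` means a single in-focus plane.
    """

    modality: str = "2P"
    photon_scale: float = 0.0
    read_noise: float = 0.0
    background: float = 0.0
    brightness: float = 1.0
    defocus_planes: Optional[List[Tuple[float, float]]] = None

    def __post_init__(self):
        if self.modality not in _ORDER:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {sorted(_ORDER)}"
            )
        for name in ("photon_scale", "read_noise", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def order(self) -> int:
        return _ORDER[self.modality]


@dataclass
class ImageFrame:
    """A simulated (or measured) 2-D intensity frame plus acquisition metadata."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ImageFrame expects a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")


def psf_from_phase(phase: np.ndarray, grid: PupilGrid) -> np.ndarray:
    """Intensity PSF |FT(mask * e^{i phase})|^2, DC-centered on the FFT grid.

    The total energy is independent of the pupil phase (Parseval), so the
    widefield detection PSF conserves flux under aberration.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.shape != (grid.n_fft, grid.n_fft):
        raise ValueError(
            f"phase shape {phase.shape} does not match grid ({grid.n_fft}, {grid.n_fft})"
        )
    pupil = grid.mask * np.exp(1j * phase)
    return fftshift(np.abs(fft2(pupil)) ** 2)


def effective_psf(psf: np.ndarray, cfg: ModalityConfig) -> np.ndarray:
    """Modality-effective PSF: unit-sum excitation PSF raised to the order.

    Normalizing the excitation PSF to unit sum makes the widefield effective
    PSF flux-conserving, while for 2-P/3-P the total of ``psf**order`` falls
    as aberration spreads the focus — the physical signal-loss mechanism that
    intensity metrics exploit.
    """
    psf = np.asarray(psf, dtype=float)
    if np.any(psf < 0):
        raise ValueError("PSF must be nonnegative")
    total = psf.sum()
    if total <= 0:
        raise ValueError("PSF has no energy")
    p = psf / total
    return p ** cfg.order


def _convolve(obj: np.ndarray, kernel_centered: np.ndarray) -> np.ndarray:
    # circular convolution; kernel is DC-centered so shift it back first
    return ifft2(fft2(obj) * fft2(ifftshift(kernel_centered))).real


def form_image(
    obj: np.ndarray,
    psf: np.ndarray,
    cfg: ModalityConfig,
    seed: Optional[int] = None,
) -> ImageFrame:
    """Image a specimen map through a PSF under the configured noise model.

    ``psf`` is the raw intensity PSF; the modality nonlinearity is applied
    here.  Deterministic given ``seed``.
    """
    obj = np.asarray(obj, dtype=float)
    if np.any(obj < 0):
        raise ValueError("specimen map must be nonnegative")
    if obj.shape != psf.shape:
        raise ValueError(f"object shape {obj.shape} != PSF shape {psf.shape}")
    eff = effective_psf(psf, cfg)
    clean = cfg.brightness * _convolve(obj, eff) + cfg.background
    np.clip(clean, 0.0, None, out=clean)  # FFT round-off can dip below zero
    pixels = _apply_noise(clean, cfg, seed)
    return ImageFrame(pixels, meta={"modality": cfg.modality, "seed": seed})


def _apply_noise(clean: np.ndarray, cfg: ModalityConfig, seed: Optional[int]) -> np.ndarray:
    if cfg.photon_scale == 0 and cfg.read_noise == 0:
        return clean.copy()
    rng = np.random.default_rng(seed)
    out = clean.copy()
    if cfg.photon_scale > 0:
        out = rng.poisson(cfg.photon_scale * out).astype(float) / cfg.photon_scale
    if cfg.read_noise > 0:
        out = out + rng.normal(0.0, cfg.read_noise, size=out.shape)
    return out


def acquire_biased(
    obj: np.ndarray,
    base_aberration: ZernikeCoefficients,
    bias: ZernikeCoefficients,
    cfg: ModalityConfig,
    grid: PupilGrid,
    seed: Optional[int] = None,
) -> ImageFrame:
    """Acquire one frame with a known bias added to the unknown aberration.

    The adaptive element applies ``bias`` on top of the specimen-induced
    ``base_aberration``; the frame records the bias in its metadata.  With
    ``cfg.defocus_planes`` set, the same specimen map is also imaged through
    defocused PSFs and the planes are summed before noise, emulating
    out-of-focus light in widefield detection.
    """
    total = base_aberration + bias
    planes = cfg.defocus_planes or [(0.0, 1.0)]
    clean = np.zeros(obj.shape, dtype=float)
    obj = np.asarray(obj, dtype=float)
    if np.any(obj < 0):
        raise ValueError("specimen map must be nonnegative")
    for dz, w in planes:
        coeffs = total + ZernikeCoefficients({4: dz}) if dz else total
        phase = evaluate_wavefront(coeffs, grid)
        eff = effective_psf(psf_from_phase(phase, grid), cfg)
        clean += w * _convolve(obj, eff)
    clean = cfg.brightness * clean + cfg.background
    np.clip(clean, 0.0, None, out=clean)
    pixels = _apply_noise(clean, cfg, seed)
    return ImageFrame(
        pixels,
        meta={
            "modality": cfg.modality,
            "seed": seed,
            "bias": dict(bias.coeffs),
        },
    )
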