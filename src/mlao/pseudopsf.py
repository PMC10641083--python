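"""Pseudo-PSF phase-diversity pre-processing.

A pseudo-PSF is the inverse Fourier transform of the spectral ratio of two
images of the same field acquired with different bias aberrations,

    pseudo-PSF = F^-1[ F(I1) / F(I2) ].

Because both images share the specimen spectrum F(O), the ratio cancels it
and leaves (approximately) F(f1)/F(f2), a specimen-independent function of
the two PSFs — and hence of the unknown aberration.  The central 32x32 crop
of each pseudo-PSF is the network input.
"""

from __future__ import annotations

from typing import Tuple, Union

import numpy as np
from numpy.fft import fft2, fftshift, ifft2

from .imaging import ImageFrame

__all__ = [
    "compute_pseudo_psf",
    "crop_center",
    "pseudo_psf_pair",
    "normalize_stack",
    "CROP_SIZE",
]

CROP_SIZE = 32

ArrayLike = Union[np.ndarray, ImageFrame]


def _pixels(img: ArrayLike) -> np.ndarray:
    if isinstance(img, ImageFrame):
        return img.pixels
    return np.asarray(img, dtype=float)


def compute_pseudo_psf(
    i1: ArrayLike,
    i2: ArrayLike,
    eps: float = 1e-3,
    subtract_mean: bool = True,
) -> np.ndarray:
    """Regularized spectral ratio of two frames, returned DC-centered.

    The division is implemented Wiener-style,

        F(I1) * conj(F(I2)) / (|F(I2)|^2 + eps * max|F(I2)|^2),

    which equals the plain ratio wherever ``|F(I2)|`` is well above the
    regularization floor and suppresses the blow-up near spectral zeros.
    Each image is mean-subtracted first so the arbitrary background/DC level
    drops out.  The real part is returned (the imaginary residue is
    numerical); the zero-shift pixel sits at the array center.
    """
    a1, a2 = _pixels(i1), _pixels(i2)
    if a1.shape != a2.shape:
        raise ValueError(f"image shapes differ: {a1.shape} vs {a2.shape}")
    if not eps > 0:
        raise ValueError("eps must be > 0")
    if subtract_mean:
        a1 = a1 - a1.mean()
        a2 = a2 - a2.mean()
    f1 = fft2(a1)
    f2 = fft2(a2)
    p2 = np.abs(f2) ** 2
    peak = p2.max()
    if peak == 0.0:
        # structureless reference frame (e.g. blank field): no ratio exists
        return np.zeros_like(a1)
    ratio = f1 * np.conj(f2) / (p2 + eps * peak)
    return fftshift(ifft2(ratio)).real


def crop_center(p: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Central ``size`` x ``size`` window; the input center lands at (size//2, size//2)."""
    p = np.asarray(p)
    if p.shape[-2] < size or p.shape[-1] < size:
        raise ValueError(f"input {p.shape} smaller than crop size {size}")
    r0 = p.shape[-2] // 2 - size // 2
    c0 = p.shape[-1] // 2 - size // 2
    return p[..., r0 : r0 + size, c0 : c0 + size]


def in_crop_fraction(p: np.ndarray, size: int = CROP_SIZE) -> float:
    """Fraction of total absolute energy retained by the central crop."""
    total = np.abs(p).sum()
    if total == 0:
        return 1.0
    return float(np.abs(crop_center(p, size)).sum() / total)


def pseudo_psf_pair(
    i_plus: ArrayLike,
    i_minus: ArrayLike,
    eps: float = 1e-3,
    size: int = CROP_SIZE,
) -> Tuple[np.ndarray, np.ndarray]:
    """Order-swapped pseudo-PSF pair from a (+bias, -bias) image pair.

    Channel 0 is ratio(i_plus / i_minus), channel 1 the swapped order; both
    are cropped to ``size``.  Swapping the order is the standard mitigation
    for zeros in either transfer function: between the two channels every
    spatial frequency is well conditioned in at least one.
    """
    c0 = crop_center(compute_pseudo_psf(i_plus, i_minus, eps=eps), size)
    c1 = crop_center(compute_pseudo_psf(i_minus, i_plus, eps=eps), size)
    return c0, c1


def normalize_stack(stack: np.ndarray) -> np.ndarray:
    """Per-channel max-abs normalization of an (M, H, W) pseudo-PSF stack."""
    stack = np.asarray(stack, dtype=float)
    peaks = np.max(np.abs(stack), axis=(-2, -1), keepdims=True)
    peaks[peaks == 0] = 1.0
    return stack / peaks
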