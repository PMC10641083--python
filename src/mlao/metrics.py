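"""Image-quality metrics for sensorless adaptive optics.

Four scalar metrics quantify how well an image is corrected:

* ``metric_yI`` — intensity: sum of the ``l`` brightest pixels.  Total
  fluorescence rises with correction in nonlinear (2-P/3-P) systems.
* ``metric_yF`` — Fourier content: integral of the spectral magnitude over
  the annulus 0.1 f_max < |f| < 0.6 f_max, where most PSF-related frequency
  information lives.
* ``metric_yS`` — sharpness: ratio of high-band to low-band spectral
  content; invariant to overall brightness, so usable in widefield systems
  and under fluorescence fluctuations.
* ``metric_yT`` — frequency threshold: mean, over angular segments, of the
  largest spatial frequency whose spectral magnitude stays above the noise
  floor (estimated from the spectrum's high-frequency corners).

Frequencies are measured in DFT bins (cycles per field of view); ``f_max``
defaults to the Nyquist radius ``n // 2`` of the square image, which for the
default simulation grid coincides with the incoherent cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.fft import fft2, fftshift

from .imaging import ImageFrame

__all__ = ["MetricConfig", "metric_yI", "metric_yF", "metric_yS", "metric_yT", "METRICS"]


def _pixels(img) -> np.ndarray:
    if isinstance(img, ImageFrame):
        return img.pixels
    return np.asarray(img, dtype=float)


@dataclass
class MetricConfig:
    """Bundled metric parameters with the published defaults."""

    l: int = 256
    n: float = 0.05
    m: float = 0.6
    f_max: Optional[float] = None  # None -> Nyquist radius of the image
    n_segments: int = 36

    def __post_init__(self):
        if self.l <= 200:
            raise ValueError("l must be larger than 200")
        if not (0.0 < self.n < self.m < 1.0):
            raise ValueError("band fractions must satisfy 0 < n < m < 1")
        if self.f_max is not None and self.f_max <= 0:
            raise ValueError("f_max must be positive")


def metric_yI(img, l: int = 256) -> float:
    """Sum of the ``l`` largest pixel values."""
    a = _pixels(img).ravel()
    if l < 1 or l > a.size:
        raise ValueError(f"l={l} outside [1, {a.size}]")
    # partial selection; ties are irrelevant to the sum
    top = np.partition(a, a.size - l)[a.size - l :]
    return float(top.sum())


def _radius_grid(n: int) -> np.ndarray:
    f = np.fft.fftfreq(n) * n  # frequency in bins, cycles per FOV
    fx, fy = np.meshgrid(f, f)
    return fftshift(np.hypot(fx, fy))


def _spectrum(img) -> np.ndarray:
    return np.abs(fftshift(fft2(_pixels(img))))


def metric_yF(img, f_max: Optional[float] = None) -> float:
    """Spectral magnitude integrated over the 0.1-0.6 f_max annulus."""
    a = _pixels(img)
    if a.shape[0] != a.shape[1]:
        raise ValueError("metric_yF expects a square image")
    if f_max is None:
        f_max = a.shape[0] / 2
    r = _radius_grid(a.shape[0])
    band = (r > 0.1 * f_max) & (r < 0.6 * f_max)
    return float(_spectrum(a)[band].sum())


def metric_yS(img, n: float = 0.05, m: float = 0.6, f_max: Optional[float] = None) -> float:
    """High-to-low spectral content ratio; brightness invariant."""
    if not (0.0 < n < m < 1.0):
        raise ValueError("require 0 < n < m < 1")
    a = _pixels(img)
    if a.shape[0] != a.shape[1]:
        raise ValueError("metric_yS expects a square image")
    if f_max is None:
        f_max = a.shape[0] / 2
    r = _radius_grid(a.shape[0])
    spec = _spectrum(a)
    hi = (r > n * f_max) & (r < m * f_max)
    lo = (r > 0) & (r <= n * f_max)
    if not lo.any() or not hi.any():
        raise ValueError("frequency bands empty after discretization; image too small")
    denom = spec[lo].sum()
    if denom == 0:
        return 0.0
    return float(spec[hi].sum() / denom)


def metric_yT(img, n_segments: int = 36, corner_frac: float = 0.125) -> float:
    """Mean noise-limited cutoff frequency over angular segments (in bins).

    The noise floor ``T`` is the average spectral magnitude in the four
    corner blocks of the (shifted) spectrum — frequencies beyond the optical
    cutoff that carry only noise.  In each angular segment the spectrum is
    averaged in 1-bin radial rings; the segment's cutoff is the largest
    radius up to which every ring stays at or above ``T``.  Pure noise
    yields ~0; a noiseless broadband image yields the largest measurable
    radius.
    """
    a = _pixels(img)
    if a.shape[0] != a.shape[1]:
        raise ValueError("metric_yT expects a square image")
    nn = a.shape[0]
    spec = _spectrum(a)
    k = max(1, int(round(corner_frac * nn)))
    corners = np.concatenate(
        [
            spec[:k, :k].ravel(),
            spec[:k, -k:].ravel(),
            spec[-k:, :k].ravel(),
            spec[-k:, -k:].ravel(),
        ]
    )
    threshold = corners.mean()

    r = _radius_grid(nn)
    f = np.fft.fftfreq(nn) * nn
    fx, fy = np.meshgrid(f, f)
    ang = fftshift(np.arctan2(fy, fx))  # [-pi, pi]
    seg = np.floor((ang + np.pi) / (2 * np.pi) * n_segments).astype(int)
    seg = np.clip(seg, 0, n_segments - 1)
    rbin = np.floor(r).astype(int)
    r_max = nn // 2

    cutoffs = np.zeros(n_segments)
    for s in range(n_segments):
        in_seg = seg == s
        cutoff = 0
        for rad in range(1, r_max + 1):
            ring = in_seg & (rbin == rad)
            if not ring.any():
                continue  # empty inner rings in narrow segments are skipped
            if spec[ring].mean() >= threshold:
                cutoff = rad
            else:
                break
        cutoffs[s] = cutoff
    return float(cutoffs.mean())


METRICS = {"yI": metric_yI, "yF": metric_yF, "yS": metric_yS, "yT": metric_yT}
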