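"""Conventional modal sensorless-AO baselines.

Both methods scan each Zernike mode with a +/- ``b`` bias, fit a parabola to
the three metric samples and move the corrector to the fitted vertex:

* ``conv_2N1`` — one shared zero-bias frame plus two biased frames per mode
  (2N + 1 images); all N modes fitted against the shared zero sample and the
  full correction applied once at the end.
* ``conv_3N`` — three frames per mode (zero, +b, -b), modes processed
  sequentially with each mode's correction applied before the next scan
  (3N images).

The parabolic fit is exact when the metric is quadratic in the coefficient,
which holds near the optimum for the standard intensity and sharpness
metrics; it degrades for large aberrations, which is the regime where the
learned estimator retains an advantage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

from .control import SimulatedMicroscope
from .imaging import ModalityConfig
from .metrics import metric_yI, metric_yS
from .zernike import ZernikeCoefficients

__all__ = [
    "parabolic_peak",
    "ModalScanResult",
    "conv_2N1",
    "conv_3N",
    "ConventionalEstimator",
    "default_metric_for",
]


def _fit_vertex(b: float, y_minus: float, y_0: float, y_plus: float) -> Tuple[float, bool]:
    curvature = y_minus - 2.0 * y_0 + y_plus
    if y_minus == y_0 == y_plus:
        return 0.0, True
    if curvature == 0.0:
        # exactly collinear samples: no stationary point to report
        return 0.0, True
    # the stationary point is applied as-is (clipped into the scan range),
    # exactly as the classical algorithm does; when the samples are convex
    # (curvature > 0) this is a minimum and the step is anti-corrective --
    # the known large-aberration failure mode of the conventional method
    x = b * (y_minus - y_plus) / (2.0 * curvature)
    clipped = float(np.clip(x, -b, b))
    return clipped, bool(curvature > 0 or clipped != x)


def parabolic_peak(b: float, y_minus: float, y_0: float, y_plus: float) -> float:
    """Vertex of the parabola through (-b, y-), (0, y0), (+b, y+).

    Returns ``b (y- - y+) / (2 (y- - 2 y0 + y+))``; exact for any quadratic
    metric.  Non-concave or out-of-range fits are clamped to ``+/- b`` (the
    better endpoint) with a warning; all-equal samples give a flagged zero.
    """
    if not b > 0:
        raise ValueError("bias magnitude b must be > 0")
    x, flagged = _fit_vertex(b, y_minus, y_0, y_plus)
    if flagged:
        warnings.warn(
            f"parabolic fit degenerate or out of range (samples {y_minus}, {y_0}, {y_plus}); "
            f"clamped to {x}",
            stacklevel=2,
        )
    return x


@dataclass
class ModalScanResult:
    """Per-mode scan samples, fitted peaks and the resulting correction."""

    method: str
    bias_magnitude: float
    samples: Dict[int, Tuple[float, float, float]] = field(default_factory=dict)  # j -> (y-, y0, y+)
    peaks: Dict[int, float] = field(default_factory=dict)
    flagged: Dict[int, bool] = field(default_factory=dict)
    images_used: int = 0

    @property
    def correction(self) -> ZernikeCoefficients:
        return ZernikeCoefficients(dict(self.peaks))


def default_metric_for(cfg: ModalityConfig) -> Callable[[np.ndarray], float]:
    """Conventional optimization metric per modality: y_I for 2-P/3-P, y_S widefield."""
    if cfg.modality in ("2P", "3P"):
        return lambda img: metric_yI(img, l=min(256, np.asarray(img).size))
    return metric_yS


def conv_2N1(
    system: SimulatedMicroscope,
    modes: Sequence[int],
    metric_fn: Callable[[np.ndarray], float],
    b: float = 1.0,
    apply: bool = True,
) -> ModalScanResult:
    """Simultaneous 2N+1 correction: shared zero frame, one +/- pair per mode."""
    if len(modes) < 1:
        raise ValueError("need at least one mode")
    result = ModalScanResult(method="conv2N1", bias_magnitude=b)
    start = system.images_acquired
    y0 = metric_fn(system.acquire(ZernikeCoefficients()).pixels)
    for j in modes:
        yp = metric_fn(system.acquire(ZernikeCoefficients({j: +b})).pixels)
        ym = metric_fn(system.acquire(ZernikeCoefficients({j: -b})).pixels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x, flagged = _fit_vertex(b, ym, y0, yp)
        result.samples[j] = (ym, y0, yp)
        result.peaks[j] = x
        result.flagged[j] = flagged
    result.images_used = system.images_acquired - start
    if apply:
        system.apply_correction(result.correction)
    return result


def conv_3N(
    system: SimulatedMicroscope,
    modes: Sequence[int],
    metric_fn: Callable[[np.ndarray], float],
    b: float = 1.0,
) -> ModalScanResult:
    """Sequential 3N correction: per-mode (0, +b, -b) scan, applied mode by mode."""
    if len(modes) < 1:
        raise ValueError("need at least one mode")
    result = ModalScanResult(method="conv3N", bias_magnitude=b)
    start = system.images_acquired
    for j in modes:
        y0 = metric_fn(system.acquire(ZernikeCoefficients()).pixels)
        yp = metric_fn(system.acquire(ZernikeCoefficients({j: +b})).pixels)
        ym = metric_fn(system.acquire(ZernikeCoefficients({j: -b})).pixels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x, flagged = _fit_vertex(b, ym, y0, yp)
        result.samples[j] = (ym, y0, yp)
        result.peaks[j] = x
        result.flagged[j] = flagged
        system.apply_correction(ZernikeCoefficients({j: x}))
    result.images_used = system.images_acquired - start
    return result


class ConventionalEstimator:
    """Adapter exposing the conventional methods through the estimator protocol."""

    def __init__(
        self,
        kind: str,
        modes: Sequence[int],
        metric_fn: Callable[[np.ndarray], float],
        b: float = 1.0,
    ):
        if kind not in ("conv2N1", "conv3N"):
            raise ValueError("kind must be 'conv2N1' or 'conv3N'")
        self.kind = kind
        self.modes = list(modes)
        self.metric_fn = metric_fn
        self.b = b
        self.last_result: ModalScanResult | None = None

    def one_cycle(self, system: SimulatedMicroscope) -> ZernikeCoefficients:
        if self.kind == "conv2N1":
            res = conv_2N1(system, self.modes, self.metric_fn, b=self.b)
        else:
            res = conv_3N(system, self.modes, self.metric_fn, b=self.b)
        self.last_result = res
        return res.correction
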