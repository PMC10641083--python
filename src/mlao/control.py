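"""Bias-scheme planning, the simulated microscope, and closed-loop correction.

A correction cycle acquires ``M`` differently biased frames of the same
field, feeds them to an estimator (learned or conventional), and applies the
negated aberration estimate to the corrector.  The schemes:

===========  ====================================================  =======
name         biased modes                                          M
===========  ====================================================  =======
``ast2``     astigmatism (Noll 5) at +/- b                         2
``ast4``     astigmatism at +/- b/2 and +/- b                      4
``2N``       every estimated mode at +/- b                         2N
``4N``       every estimated mode at +/- b/2 and +/- b             4N
``conv2N1``  zero frame + every mode at +/- b (simultaneous fit)   2N + 1
``conv3N``   per mode: zero, +b, -b (sequential fit)               3N
===========  ====================================================  =======
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd

from .imaging import ImageFrame, ModalityConfig, acquire_biased
from .zernike import PupilGrid, ZernikeCoefficients, default_mode_set

__all__ = [
    "BiasScheme",
    "make_scheme",
    "plan_acquisitions",
    "SimulatedMicroscope",
    "Estimator",
    "OracleEstimator",
    "ZeroEstimator",
    "CorrectionTrace",
    "correct_iterate",
    "evaluate_statistics",
    "SCHEME_NAMES",
]

SCHEME_NAMES = ("ast2", "ast4", "2N", "4N", "conv2N1", "conv3N")


@dataclass(frozen=True)
class BiasScheme:
    """An ordered list of bias wavefronts defining one acquisition cycle."""

    name: str
    modes: Tuple[int, ...]           # modes being estimated (N of them)
    biases: Tuple[ZernikeCoefficients, ...]  # one per planned frame (M of them)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def m_images(self) -> int:
        return len(self.biases)

    @property
    def pairs(self) -> List[Tuple[ZernikeCoefficients, ZernikeCoefficients]]:
        """Consecutive (+bias, -bias) frame pairs (MLAO schemes only)."""
        if self.name in ("conv2N1", "conv3N"):
            raise ValueError("conventional schemes are not organized in +/- pairs")
        return [(self.biases[i], self.biases[i + 1]) for i in range(0, len(self.biases), 2)]

    @property
    def n_channels(self) -> int:
        """Pseudo-PSF channels fed to the network: two per biased pair."""
        return 2 * len(self.pairs)


def make_scheme(
    name: str,
    n_modes: int,
    bias_magnitude: float = 1.0,
    astig_mode: int = 5,
    modes: Optional[Sequence[int]] = None,
) -> BiasScheme:
    """Build one of the named bias schemes for ``n_modes`` estimated modes.

    ``ast4``/``4N`` use the two magnitudes (b/2, b) per biased mode.
    """
    if modes is None:
        modes = default_mode_set(n_modes)
    modes = tuple(int(j) for j in modes)
    if len(modes) != n_modes:
        raise ValueError("modes list length must equal n_modes")
    b = float(bias_magnitude)
    z = lambda j, a: ZernikeCoefficients({j: a})
    zero = ZernikeCoefficients()

    if name == "ast2":
        biases = [z(astig_mode, +b), z(astig_mode, -b)]
    elif name == "ast4":
        biases = [z(astig_mode, +b / 2), z(astig_mode, -b / 2), z(astig_mode, +b), z(astig_mode, -b)]
    elif name == "2N":
        biases = [z(j, s * b) for j in modes for s in (+1, -1)]
    elif name == "4N":
        biases = [z(j, s * a) for j in modes for a in (b / 2, b) for s in (+1, -1)]
    elif name == "conv2N1":
        biases = [zero] + [z(j, s * b) for j in modes for s in (+1, -1)]
    elif name == "conv3N":
        biases = [bias for j in modes for bias in (zero, z(j, +b), z(j, -b))]
    else:
        raise ValueError(f"unknown scheme {name!r}; expected one of {SCHEME_NAMES}")
    return BiasScheme(name=name, modes=modes, biases=tuple(biases))


def plan_acquisitions(scheme: BiasScheme, n_modes: Optional[int] = None) -> List[ZernikeCoefficients]:
    """The ordered bias list for one cycle (length = the scheme's M)."""
    if n_modes is not None and n_modes != scheme.n_modes:
        raise ValueError(
            f"scheme was built for N={scheme.n_modes} modes, asked for N={n_modes}"
        )
    return list(scheme.biases)


class SimulatedMicroscope:
    """A microscope with a hidden specimen aberration and a modal corrector.

    The corrector state accumulates applied corrections; every acquisition
    sees ``aberration + corrector + bias`` and a fresh noise seed (no frame
    reuse between exposures).  ``residual()`` is ground truth available only
    in simulation.
    """

    def __init__(
        self,
        obj: np.ndarray,
        aberration: ZernikeCoefficients,
        cfg: ModalityConfig,
        grid: PupilGrid,
        seed: Optional[int] = None,
    ):
        self.obj = np.asarray(obj, dtype=float)
        self.aberration = aberration
        self.cfg = cfg
        self.grid = grid
        self.corrector = ZernikeCoefficients()
        self.images_acquired = 0
        self._seed = seed
        self._frame = 0

    def acquire(self, bias: ZernikeCoefficients = ZernikeCoefficients()) -> ImageFrame:
        seed = None if self._seed is None else self._seed + self._frame
        self._frame += 1
        self.images_acquired += 1
        return acquire_biased(self.obj, self.residual(), bias, self.cfg, self.grid, seed=seed)

    def apply_correction(self, delta: ZernikeCoefficients) -> None:
        self.corrector = self.corrector + delta

    def residual(self) -> ZernikeCoefficients:
        return self.aberration + self.corrector

    def residual_rms(self) -> float:
        return self.residual().rms()


class Estimator(Protocol):
    """One correction cycle: acquire frames via the system, apply a correction."""

    def one_cycle(self, system: SimulatedMicroscope) -> ZernikeCoefficients:
        """Run one cycle and return the correction that was applied."""
        ...


class OracleEstimator:
    """Perfect estimator (simulation-only): applies the exact negated residual.

    Acquires the scheme's frames so that image accounting matches a real
    estimator; upper bound for any learned or conventional method.
    """

    def __init__(self, scheme: BiasScheme):
        self.scheme = scheme

    def one_cycle(self, system: SimulatedMicroscope) -> ZernikeCoefficients:
        for bias in self.scheme.biases:
            system.acquire(bias)
        correction = -system.residual()
        system.apply_correction(correction)
        return correction


class ZeroEstimator:
    """Null estimator: acquires the frames, applies nothing (control arm)."""

    def __init__(self, scheme: BiasScheme):
        self.scheme = scheme

    def one_cycle(self, system: SimulatedMicroscope) -> ZernikeCoefficients:
        for bias in self.scheme.biases:
            system.acquire(bias)
        correction = ZernikeCoefficients()
        system.apply_correction(correction)
        return correction


@dataclass
class CorrectionTrace:
    """Per-iteration record of a closed-loop correction run."""

    rows: List[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def residual_rms(self) -> List[float]:
        return [r["residual_rms"] for r in self.rows]

    @property
    def images(self) -> List[int]:
        return [r["images_acquired"] for r in self.rows]


def correct_iterate(
    system: SimulatedMicroscope,
    estimator: Estimator,
    iterations: int = 1,
    metric_fn: Optional[Callable[[np.ndarray], float]] = None,
) -> CorrectionTrace:
    """Run ``iterations`` correction cycles, logging residuals and image counts.

    If ``metric_fn`` is given, a dedicated zero-bias frame is acquired after
    each cycle to log an image-quality proxy (it counts toward the image
    budget, mirroring a real extra exposure).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    trace = CorrectionTrace()
    trace.append(
        iteration=0,
        images_acquired=system.images_acquired,
        correction_rms=0.0,
        residual_rms=system.residual_rms(),
        metric=None,
    )
    for it in range(1, iterations + 1):
        try:
            correction = estimator.one_cycle(system)
        except Exception as exc:  # halt gracefully, keep the partial trace
            trace.append(iteration=it, error=repr(exc), images_acquired=system.images_acquired,
                         residual_rms=system.residual_rms(), metric=None)
            break
        metric_val = None
        if metric_fn is not None:
            frame = system.acquire(ZernikeCoefficients())
            metric_val = float(metric_fn(frame.pixels))
        trace.append(
            iteration=it,
            images_acquired=system.images_acquired,
            correction_rms=correction.rms(),
            residual_rms=system.residual_rms(),
            metric=metric_val,
        )
    return trace


# input-RMS bin edges used in the statistical evaluation (rad)
DEFAULT_RMS_BINS = (0.63, 0.84, 1.19, 1.92, 2.12, 2.23)


def evaluate_statistics(
    runs: Sequence[dict],
    rms_bins: Sequence[float] = DEFAULT_RMS_BINS,
) -> pd.DataFrame:
    """Tabulate mean +/- SD residual RMS per input-RMS bin per method.

    ``runs`` is a sequence of dicts with keys ``method``, ``input_rms`` and
    ``residual_rms`` (one correction run each).  Bins are the intervals
    between consecutive edges; runs outside the edges are dropped.
    """
    df = pd.DataFrame(list(runs))
    if df.empty:
        raise ValueError("no runs to evaluate")
    edges = list(rms_bins)
    df = df[(df.input_rms >= edges[0]) & (df.input_rms <= edges[-1])].copy()
    df["rms_bin"] = pd.cut(df.input_rms, edges, include_lowest=True)
    out = (
        df.groupby(["method", "rms_bin"], observed=False)["residual_rms"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return out
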