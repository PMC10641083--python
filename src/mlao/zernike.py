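"""Zernike polynomials under Noll indexing and RMS normalization.

Conventions used throughout the package:

* Single-index ordering follows Noll (1976): radial order ``n`` increases,
  within an order the azimuthal frequencies ``|m|`` increase, and for
  ``m != 0`` the even Noll index carries the cosine term (``m > 0``) while
  the odd index carries the sine term (``m < 0``).
* Each mode is normalized to unit RMS over the unit pupil disk, so a
  coefficient is directly the mode's RMS phase contribution in radians and
  the RMS of a wavefront is the Euclidean norm of its coefficient vector.
* Piston (Noll 1) carries no image information and is excluded from
  :class:`ZernikeCoefficients`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "ZernikeCoefficients",
    "PupilGrid",
    "noll_to_nm",
    "nm_to_noll",
    "zernike_mode",
    "evaluate_wavefront",
    "decompose_wavefront",
    "default_mode_set",
]


_NOLL_CACHE: Dict[int, Tuple[int, int]] = {}
_NM_CACHE: Dict[Tuple[int, int], int] = {}


def _extend_noll_tables(up_to_j: int) -> None:
    j = 1
    n = 0
    while True:
        for am in range(n % 2, n + 1, 2):
            if am == 0:
                entries = [(n, 0, j)]
                j += 1
            else:
                # the even Noll index of the pair takes the cosine (+m) term
                j1, j2 = j, j + 1
                even, odd = (j1, j2) if j1 % 2 == 0 else (j2, j1)
                entries = [(n, am, even), (n, -am, odd)]
                j += 2
            for nn, mm, jj in entries:
                _NOLL_CACHE[jj] = (nn, mm)
                _NM_CACHE[(nn, mm)] = jj
        if j > up_to_j:
            return
        n += 1


def noll_to_nm(j: int) -> Tuple[int, int]:
    """Map a Noll index to (radial order n, signed azimuthal order m)."""
    if not isinstance(j, (int, np.integer)) or isinstance(j, bool) or j < 1:
        raise ValueError(f"Noll index must be a positive integer, got {j!r}")
    j = int(j)
    if j not in _NOLL_CACHE:
        _extend_noll_tables(j)
    return _NOLL_CACHE[j]


def nm_to_noll(n: int, m: int) -> int:
    """Inverse of :func:`noll_to_nm`."""
    if n < 0 or abs(m) > n or (n - abs(m)) % 2:
        raise ValueError(f"invalid Zernike orders (n={n}, m={m})")
    key = (int(n), int(m))
    if key not in _NM_CACHE:
        # indices up to radial order n occupy (n+1)(n+2)/2 slots
        _extend_noll_tables((n + 1) * (n + 2) // 2)
    return _NM_CACHE[key]


def default_mode_set(n_modes: int, start: int = 5) -> Tuple[int, ...]:
    """Default estimated-mode list: ``n_modes`` consecutive Noll indices from 5.

    Tip, tilt and defocus (Noll 2-4) displace rather than blur the image, so
    sensorless estimation conventionally starts at astigmatism (Noll 5):
    N=7 gives Noll 5-11, N=9 gives 5-13.
    """
    if n_modes < 1:
        raise ValueError("need at least one mode")
    return tuple(range(start, start + n_modes))


@dataclass(frozen=True)
class ZernikeCoefficients:
    """Sparse aberration state: Noll index -> coefficient in rad RMS."""

    coeffs: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        clean: Dict[int, float] = {}
        for j, c in dict(self.coeffs).items():
            ji = int(j)
            if ji != j or ji < 2:
                raise ValueError(f"Noll index must be an integer >= 2, got {j!r}")
            cf = float(c)
            if not math.isfinite(cf):
                raise ValueError(f"coefficient for Noll {ji} is not finite")
            if cf != 0.0:
                clean[ji] = cf
        object.__setattr__(self, "coeffs", clean)

    def rms(self) -> float:
        """RMS wavefront error in rad: sqrt(sum of squared coefficients)."""
        return math.sqrt(sum(c * c for c in self.coeffs.values()))

    def __getitem__(self, j: int) -> float:
        return self.coeffs.get(int(j), 0.0)

    def __iter__(self) -> Iterator[Tuple[int, float]]:
        return iter(sorted(self.coeffs.items()))

    def __len__(self) -> int:
        return len(self.coeffs)

    def __add__(self, other: "ZernikeCoefficients") -> "ZernikeCoefficients":
        out = dict(self.coeffs)
        for j, c in other.coeffs.items():
            out[j] = out.get(j, 0.0) + c
        return ZernikeCoefficients(out)

    def __sub__(self, other: "ZernikeCoefficients") -> "ZernikeCoefficients":
        return self + (-other)

    def __neg__(self) -> "ZernikeCoefficients":
        return ZernikeCoefficients({j: -c for j, c in self.coeffs.items()})

    def __mul__(self, k: float) -> "ZernikeCoefficients":
        return ZernikeCoefficients({j: k * c for j, c in self.coeffs.items()})

    __rmul__ = __mul__

    def as_vector(self, modes: Sequence[int]) -> np.ndarray:
        return np.array([self[j] for j in modes], dtype=float)

    @classmethod
    def from_vector(cls, modes: Sequence[int], values: Iterable[float]) -> "ZernikeCoefficients":
        return cls(dict(zip(map(int, modes), map(float, values))))

    def to_json(self) -> str:
        return json.dumps({str(j): c for j, c in sorted(self.coeffs.items())})

    @classmethod
    def from_json(cls, text: str) -> "ZernikeCoefficients":
        return cls({int(j): float(c) for j, c in json.loads(text).items()})


class PupilGrid:
    """Sampled unit pupil disk embedded in an FFT-sized array.

    ``n_pupil`` samples span the pupil diameter inside an ``n_fft`` square
    array (``n_fft >= 2 * n_pupil`` for Nyquist padding of the PSF).  Pixels
    whose centers fall inside the unit disk belong to the pupil.
    """

    def __init__(self, n_pupil: int = 128, n_fft: int = 256):
        if n_pupil < 8:
            raise ValueError("n_pupil too small to resolve the pupil")
        if n_fft < 2 * n_pupil:
            raise ValueError(f"n_fft ({n_fft}) must be >= 2 * n_pupil ({n_pupil})")
        self.n_pupil = int(n_pupil)
        self.n_fft = int(n_fft)
        c = self.n_fft / 2.0 - 0.5  # array center, pixel-center coordinates
        idx = np.arange(self.n_fft)
        x = (idx - c) / (self.n_pupil / 2.0)
        self.xx, self.yy = np.meshgrid(x, x)
        self.rho = np.hypot(self.xx, self.yy)
        self.theta = np.arctan2(self.yy, self.xx)
        self.mask = self.rho <= 1.0
        self._basis: Dict[int, np.ndarray] = {}

    def zernike(self, j: int) -> np.ndarray:
        """Mode ``j`` sampled on the grid (zero outside the pupil)."""
        if j not in self._basis:
            z = zernike_mode(j, self.rho, self.theta)
            z[~self.mask] = 0.0
            self._basis[j] = z
        return self._basis[j]

    def __repr__(self) -> str:
        return f"PupilGrid(n_pupil={self.n_pupil}, n_fft={self.n_fft})"


def _radial_poly(n: int, am: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        coef = (
            (-1) ** k
            * math.factorial(n - k)
            / (math.factorial(k) * math.factorial((n + am) // 2 - k) * math.factorial((n - am) // 2 - k))
        )
        out += coef * rho ** (n - 2 * k)
    return out


def zernike_mode(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Noll-normalized Zernike mode j on polar samples (unit RMS on the disk)."""
    n, m = noll_to_nm(j)
    am = abs(m)
    r = _radial_poly(n, am, np.asarray(rho, dtype=float))
    if m == 0:
        return math.sqrt(n + 1.0) * r
    norm = math.sqrt(2.0 * (n + 1.0))
    if m > 0:
        return norm * r * np.cos(am * theta)
    return norm * r * np.sin(am * theta)


def evaluate_wavefront(c: ZernikeCoefficients, grid: PupilGrid) -> np.ndarray:
    """Phase map (rad) of the modal wavefront on the grid; zero outside the pupil.

    By Noll orthonormality the RMS of the returned phase over the disk equals
    ``c.rms()`` up to discretization error.
    """
    phase = np.zeros((grid.n_fft, grid.n_fft))
    for j, cj in c:
        phase += cj * grid.zernike(j)
    return phase


def decompose_wavefront(phase: np.ndarray, grid: PupilGrid, modes: Sequence[int]) -> ZernikeCoefficients:
    """Project a phase map back onto the listed modes (disk inner products)."""
    if phase.shape != (grid.n_fft, grid.n_fft):
        raise ValueError("phase shape does not match grid")
    npix = grid.mask.sum()
    vals = {}
    for j in modes:
        z = grid.zernike(j)
        vals[int(j)] = float((phase * z)[grid.mask].sum() / npix)
    return ZernikeCoefficients(vals)
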