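"""Synthetic specimens and training-set generation for the learned estimator.

Training images are produced entirely in silico: a specimen structure
(beads, fibres, or power-law textures standing in for natural microscope
images) is convolved with the modality's aberrated PSF, noise and background
are added, pseudo-PSF channels are computed from the biased frame pairs, and
the known aberration coefficients become the regression target.  Randomized
augmentations (brightness, background, noise level, and a small blur of the
nominal PSF) emulate experimental uncertainty so that the estimator does not
overfit a single idealized imaging model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .control import BiasScheme
from .imaging import ModalityConfig, acquire_biased
from .pseudopsf import CROP_SIZE, normalize_stack, pseudo_psf_pair
from .zernike import PupilGrid, ZernikeCoefficients

__all__ = [
    "SpecimenSpec",
    "Augmentations",
    "generate_specimen",
    "sample_aberration",
    "synth_example",
    "make_training_set",
    "build_dataset",
    "load_dataset",
]

STRUCTURES = ("beads", "fibres", "texture", "mixed")


@dataclass(frozen=True)
class SpecimenSpec:
    """Parametric specimen description.

    ``density`` is structures per pixel (beads) or fibres per 1e4 pixels;
    ``size_range`` is the bead/fibre Gaussian radius in pixels;
    ``intensity_range`` scales the peak value of the map.
    """

    structure: str = "beads"
    density: float = 1e-3
    size_range: Tuple[float, float] = (1.0, 2.5)
    intensity_range: Tuple[float, float] = (0.5, 1.0)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.size_range[0] <= 0 or self.size_range[1] < self.size_range[0]:
            raise ValueError("invalid size_range")


def _beads(shape, spec: SpecimenSpec, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(shape)
    n = rng.poisson(spec.density * shape[0] * shape[1])
    if n == 0:
        return out
    rows = rng.uniform(0, shape[0], n)
    cols = rng.uniform(0, shape[1], n)
    sigmas = rng.uniform(*spec.size_range, n)
    amps = rng.uniform(0.3, 1.0, n)
    # bucket radii so each group needs one blur pass
    bins = np.clip(np.round(sigmas * 4).astype(int), 1, None)
    for bval in np.unique(bins):
        sel = bins == bval
        delta = np.zeros(shape)
        np.add.at(delta, (rows[sel].astype(int), cols[sel].astype(int)), amps[sel])
        out += gaussian_filter(delta, sigma=bval / 4.0, mode="wrap")
    return out


def _fibres(shape, spec: SpecimenSpec, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(shape)
    n_fibres = max(1, rng.poisson(spec.density * shape[0] * shape[1] / 3.0)) if spec.density > 0 else 0
    for _ in range(n_fibres):
        length = rng.integers(shape[0] // 2, 2 * shape[0])
        pos = np.array([rng.uniform(0, shape[0]), rng.uniform(0, shape[1])])
        ang = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0)
        for _ in range(int(length)):
            ang += rng.normal(0, 0.12)  # smooth curvature
            pos += np.array([np.sin(ang), np.cos(ang)])
            r, c = int(pos[0]) % shape[0], int(pos[1]) % shape[1]
            out[r, c] += amp
    sigma = rng.uniform(*spec.size_range) / 2.0
    return gaussian_filter(out, sigma=sigma, mode="wrap")


def _texture(shape, spec: SpecimenSpec, rng: np.random.Generator) -> np.ndarray:
    # filtered noise with a power-law spectrum: natural-image-like statistics
    alpha = rng.uniform(1.0, 2.5)
    white = rng.normal(size=shape)
    f = np.fft.fftfreq(shape[0])[:, None] ** 2 + np.fft.fftfreq(shape[1])[None, :] ** 2
    filt = (np.sqrt(f) + 1.0 / shape[0]) ** (-alpha / 2.0)
    tex = np.fft.ifft2(np.fft.fft2(white) * filt).real
    tex -= tex.min()
    # soft threshold keeps sparse bright structure on a dim background
    tex = np.maximum(tex - np.percentile(tex, 55), 0.0)
    return tex


def generate_specimen(spec: SpecimenSpec, shape: Tuple[int, int] = (128, 128)) -> np.ndarray:
    """Nonnegative 2-D specimen map; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.structure == "beads":
        out = _beads(shape, spec, rng)
    elif spec.structure == "fibres":
        out = _fibres(shape, spec, rng)
    elif spec.structure == "texture":
        out = _texture(shape, spec, rng)
    else:  # mixed
        parts = []
        for s, gen in (("beads", _beads), ("fibres", _fibres), ("texture", _texture)):
            w = rng.uniform(0.2, 1.0)
            parts.append(w * gen(shape, replace(spec, structure=s), rng))
        out = sum(parts)
    peak = out.max()
    if peak > 0:
        out *= rng.uniform(*spec.intensity_range) / peak
    return out


def sample_aberration(
    modes: Sequence[int],
    rms_range: Tuple[float, float],
    rng: np.random.Generator,
) -> ZernikeCoefficients:
    """Isotropic random aberration over ``modes`` with RMS uniform in ``rms_range``."""
    if len(modes) == 0:
        raise ValueError("empty mode set")
    lo, hi = rms_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid rms_range")
    g = rng.normal(size=len(modes))
    norm = np.linalg.norm(g)
    if norm == 0:
        g[0] = 1.0
        norm = 1.0
    target = rng.uniform(lo, hi)
    return ZernikeCoefficients.from_vector(modes, g / norm * target)


@dataclass(frozen=True)
class Augmentations:
    """Experimental-uncertainty augmentations applied per training example."""

    intensity: bool = True       # random brightness (x0.5 - x2)
    background: bool = True      # random background offset
    psf_blur: bool = True        # Gaussian blur jitter of the nominal PSF (model mismatch)
    noise_jitter: bool = True    # random scaling of the photon budget (x0.5 - x2)


def _augmented_cfg(cfg: ModalityConfig, aug: Augmentations, rng: np.random.Generator) -> ModalityConfig:
    kw: Dict = {}
    if aug.intensity:
        kw["brightness"] = cfg.brightness * rng.uniform(0.5, 2.0)
    if aug.background:
        kw["background"] = cfg.background * rng.uniform(0.0, 2.0)
    if aug.noise_jitter and cfg.photon_scale > 0:
        kw["photon_scale"] = cfg.photon_scale * rng.uniform(0.5, 2.0)
    return replace(cfg, **kw) if kw else cfg


def synth_example(
    obj: np.ndarray,
    aberration: ZernikeCoefficients,
    scheme: BiasScheme,
    cfg: ModalityConfig,
    grid: PupilGrid,
    rng: Optional[np.random.Generator] = None,
    eps: float = 1e-3,
    aug: Optional[Augmentations] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """One training example: (channels (M, 32, 32) float32, target (N,)).

    Acquires the scheme's biased frames of ``obj`` under ``aberration``,
    computes order-swapped pseudo-PSF pairs, crops to 32x32 and applies
    per-channel max-abs normalization.  The target is the base aberration's
    coefficient vector over the scheme's modes.
    """
    rng = rng or np.random.default_rng()
    if aug is not None:
        cfg = _augmented_cfg(cfg, aug, rng)
    blur = 0.0
    if aug is not None and aug.psf_blur:
        blur = rng.uniform(0.0, 0.6)
    channels: List[np.ndarray] = []
    for b_plus, b_minus in scheme.pairs:
        frames = []
        for bias in (b_plus, b_minus):
            seed = int(rng.integers(0, 2**31 - 1))
            frame = acquire_biased(obj, aberration, bias, cfg, grid, seed=seed)
            if blur > 0:
                frame.pixels = gaussian_filter(frame.pixels, sigma=blur, mode="wrap")
            frames.append(frame)
        c0, c1 = pseudo_psf_pair(frames[0], frames[1], eps=eps)
        channels.extend([c0, c1])
    x = normalize_stack(np.stack(channels)).astype(np.float32)
    y = aberration.as_vector(scheme.modes).astype(np.float32)
    return x, y


DEFAULT_SPEC_MIX: Dict[str, float] = {"beads": 0.3, "fibres": 0.3, "texture": 0.4}


def make_training_set(
    n_examples: int,
    scheme: BiasScheme,
    cfg: ModalityConfig,
    grid: PupilGrid,
    rms_range: Tuple[float, float] = (0.0, 2.5),
    spec_mix: Optional[Dict[str, float]] = None,
    seed: int = 0,
    fov: Optional[int] = None,
    aug: Optional[Augmentations] = Augmentations(),
    eps: float = 1e-3,
) -> Tuple[np.ndarray, np.ndarray, List[dict]]:
    """Generate a full in-memory training set (X, Y, provenance records).

    Deterministic given ``seed``.  ``fov`` defaults to the grid's FFT size
    (images and objects share that grid).
    """
    if n_examples < 1:
        raise ValueError("n_examples must be >= 1")
    mix = dict(spec_mix or DEFAULT_SPEC_MIX)
    names = sorted(mix)
    probs = np.array([mix[k] for k in names], dtype=float)
    probs /= probs.sum()
    fov = fov or grid.n_fft
    rng = np.random.default_rng(seed)
    X = np.empty((n_examples, scheme.n_channels, CROP_SIZE, CROP_SIZE), dtype=np.float32)
    Y = np.empty((n_examples, scheme.n_modes), dtype=np.float32)
    records = []
    for i in range(n_examples):
        structure = names[rng.choice(len(names), p=probs)]
        spec_seed = int(rng.integers(0, 2**31 - 1))
        spec = SpecimenSpec(structure=structure, seed=spec_seed)
        obj = generate_specimen(spec, shape=(fov, fov))
        aberration = sample_aberration(scheme.modes, rms_range, rng)
        x, y = synth_example(obj, aberration, scheme, cfg, grid, rng=rng, eps=eps, aug=aug)
        X[i], Y[i] = x, y
        records.append({"structure": structure, "specimen_seed": spec_seed})
    return X, Y, records


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def build_dataset(
    outdir: Path,
    n_examples: int,
    scheme: BiasScheme,
    cfg: ModalityConfig,
    grid: PupilGrid,
    rms_range: Tuple[float, float] = (0.0, 2.5),
    spec_mix: Optional[Dict[str, float]] = None,
    seed: int = 0,
    shard_size: int = 1000,
    **kwargs,
) -> Path:
    """Generate a dataset to disk as .npz shards plus a JSON manifest.

    The manifest carries everything needed to regenerate the shards
    byte-identically: generation seed, scheme, modality and grid parameters,
    and the class-mix fractions actually realized.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X, Y, records = make_training_set(
        n_examples, scheme, cfg, grid, rms_range=rms_range, spec_mix=spec_mix, seed=seed, **kwargs
    )
    shards = []
    for s0 in range(0, n_examples, shard_size):
        name = f"shard_{s0 // shard_size:04d}.npz"
        np.savez_compressed(outdir / name, x=X[s0 : s0 + shard_size], y=Y[s0 : s0 + shard_size])
        shards.append(name)
    counts: Dict[str, int] = {}
    for r in records:
        counts[r["structure"]] = counts.get(r["structure"], 0) + 1
    payload = {
        "n_examples": n_examples,
        "seed": seed,
        "scheme": {"name": scheme.name, "modes": list(scheme.modes),
                   "biases": [dict(b.coeffs) for b in scheme.biases]},
        "modality": asdict(cfg),
        "grid": {"n_pupil": grid.n_pupil, "n_fft": grid.n_fft},
        "rms_range": list(rms_range),
        "spec_mix": spec_mix or DEFAULT_SPEC_MIX,
        "class_counts": counts,
        "shards": shards,
    }
    payload["config_hash"] = _config_hash({k: v for k, v in payload.items() if k != "shards"})
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2))
    return outdir / "manifest.json"


def load_dataset(manifest_path: Path) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Load a dataset written by :func:`build_dataset`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    xs, ys = [], []
    for name in manifest["shards"]:
        with np.load(manifest_path.parent / name) as z:
            xs.append(z["x"])
            ys.append(z["y"])
    return np.concatenate(xs), np.concatenate(ys), manifest
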