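"""File I/O and reproducibility plumbing: TIFF stacks, sidecar JSON, manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import tifffile
import yaml

from .imaging import ImageFrame

__all__ = [
    "write_tiff",
    "read_tiff",
    "write_frames",
    "read_frames",
    "load_config",
    "config_hash",
    "RunManifest",
]


def write_tiff(path: Path, data: Union[np.ndarray, Sequence[np.ndarray]]) -> Path:
    """Write a single- or multi-page float32 TIFF."""
    path = Path(path)
    arr = np.asarray(data, dtype=np.float32)
    tifffile.imwrite(path, arr)
    return path


def read_tiff(path: Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def write_frames(path: Path, frames: Sequence[ImageFrame]) -> Path:
    """Multi-page TIFF of frames with a JSON metadata sidecar."""
    path = Path(path)
    write_tiff(path, np.stack([f.pixels for f in frames]))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps([_jsonable(f.meta) for f in frames], indent=2))
    return path


def read_frames(path: Path) -> List[ImageFrame]:
    path = Path(path)
    stack = read_tiff(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    metas = json.loads(sidecar.read_text()) if sidecar.exists() else [{}] * len(stack)
    return [ImageFrame(p, meta=m) for p, m in zip(stack, metas)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_config(path: Path) -> dict:
    """Load a YAML (or JSON) experiment configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(_jsonable(cfg), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to re-run a CLI experiment bit-identically."""

    command: str
    config: dict
    seed: Optional[int] = None
    version: str = "0.1.0"
    outputs: List[str] = field(default_factory=list)
    timings: Dict[str, float] = field(default_factory=dict)
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    def record_output(self, path: Path) -> None:
        self.outputs.append(str(path))

    def stage_done(self, name: str) -> None:
        self.timings[name] = round(time.perf_counter() - self._t0, 3)

    def write(self, outdir: Path) -> Path:
        payload = {
            "command": self.command,
            "config": _jsonable(self.config),
            "config_hash": config_hash(self.config),
            "seed": self.seed,
            "version": self.version,
            "outputs": self.outputs,
            "timings": self.timings,
        }
        path = Path(outdir) / "manifest.json"
        path.write_text(json.dumps(payload, indent=2))
        return path
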