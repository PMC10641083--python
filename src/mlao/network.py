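"""Compact multi-scale CNN aberration estimator.

The estimator maps an M-channel stack of 32x32 cropped pseudo-PSFs to N
Zernike coefficients.  Its structure mirrors the physics of the problem:
stacked convolutional stages whose receptive fields grow from a single
pixel (stage 1, a 1x1 convolution — sensitive to the Strehl-related central
pixel of the pseudo-PSF) up to large-scale spatial correlations (stage 5,
receptive field ~31 pixels).  Each stage's feature maps are globally
average-pooled into a per-scale feature vector; the concatenated vector
feeds one fully connected layer (FCL) and a linear output layer.  Because
each scale owns a distinct, addressable block of FCL weights, the trained
weight distribution can be read out per scale — revealing which spatial
scales the estimator relies on.

The network is small (tens of thousands of trainable parameters) and is
implemented directly in NumPy with explicit backpropagation and an Adam
optimizer; training is fully deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .pseudopsf import normalize_stack, pseudo_psf_pair
from .zernike import ZernikeCoefficients, default_mode_set

__all__ = [
    "ModelConfig",
    "MultiScaleCNN",
    "TrainingHistory",
    "train",
    "estimate",
    "layer_weight_rms",
    "save_model",
    "load_model",
    "MLAOEstimator",
]

INPUT_SIZE = 32


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``m_channels`` pseudo-PSF input channels, ``n_modes`` output
    coefficients, ``stages`` convolutional scales (first is 1x1, the rest
    3x3 stride-2), ``channels`` feature maps per stage, ``fcl_width``
    hidden units in the fully connected layer.
    """

    m_channels: int
    n_modes: int
    stages: int = 5
    channels: int = 16
    fcl_width: int = 64
    seed: int = 0
    modes: Optional[Tuple[int, ...]] = None

    def __post_init__(self):
        if self.m_channels < 1 or self.n_modes < 1:
            raise ValueError("m_channels and n_modes must be >= 1")
        if self.stages < 2:
            raise ValueError("need at least 2 scale stages")
        if self.modes is not None and len(self.modes) != self.n_modes:
            raise ValueError("modes list must have n_modes entries")

    @property
    def mode_list(self) -> Tuple[int, ...]:
        return self.modes if self.modes is not None else default_mode_set(self.n_modes)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> Tuple[np.ndarray, Tuple[int, ...]]:
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, k, k)
    b_, c_, ho, wo, _, _ = win.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (b, c, h, w, ho, wo)


class _Conv:
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.b = np.zeros(cout)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, dims = _im2col(x, self.k, self.stride, self.pad)
        b, _, _, _, ho, wo = dims
        y = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, dims)
        return y.reshape(b, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (b, c, h, w, ho, wo) = self._cache
        dyc = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.dW = dyc.T @ cols
        self.db = dyc.sum(axis=0)
        dcols = (dyc @ self.W).reshape(b, ho, wo, c, self.k, self.k)
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dxp = np.zeros((b, c, hp, wp))
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp

    @property
    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nout, nin))
        self.b = np.zeros(nout)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W

    @property
    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class MultiScaleCNN:
    """The scale-interpretable CNN; see module docstring for the layout."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.channels
        self.convs: List[_Conv] = [_Conv(cfg.m_channels, c, k=1, stride=1, pad=0, rng=rng)]
        for _ in range(cfg.stages - 1):
            self.convs.append(_Conv(c, c, k=3, stride=2, pad=1, rng=rng))
        self.fc1 = _Dense(cfg.stages * c, cfg.fcl_width, rng)
        self.fc2 = _Dense(cfg.fcl_width, cfg.n_modes, rng)
        # per-stage pooled-feature statistics, calibrated on the training set;
        # used only by the weight introspection so that weight magnitudes can
        # be compared across stages in common (standardized-feature) units
        self.feature_mean = np.zeros(cfg.stages * c)
        self.feature_scale = np.ones(cfg.stages * c)
        self._cache: Dict = {}

    # -- architecture contracts -------------------------------------------------
    @property
    def receptive_fields(self) -> List[int]:
        """Effective receptive field (pixels) of each stage's features."""
        rf, jump, out = 1, 1, []
        for conv in self.convs:
            rf += (conv.k - 1) * jump
            jump *= conv.stride
            out.append(rf)
        return out

    def parameter_count(self) -> int:
        return sum(layer.W.size + layer.b.size for layer in self.layers)

    # -- forward / backward -----------------------------------------------------
    def pooled_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Raw (unstandardized) concatenated per-stage pooled features."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.cfg.m_channels or x.shape[2:] != (INPUT_SIZE, INPUT_SIZE):
            raise ValueError(
                f"expected input (batch, {self.cfg.m_channels}, {INPUT_SIZE}, {INPUT_SIZE}), got {x.shape}"
            )
        feats, relu_masks, shapes = [], [], []
        h = x
        for conv in self.convs:
            z = conv.forward(h, train=train)
            mask = z > 0
            h = z * mask
            feats.append(h.mean(axis=(2, 3)))  # global average pool per stage
            if train:
                relu_masks.append(mask)
                shapes.append(h.shape)
        if train:
            self._cache = {"relu_masks": relu_masks, "shapes": shapes}
        return np.concatenate(feats, axis=1)

    def calibrate_features(self, X: np.ndarray, batch_size: int = 256) -> None:
        """Record per-stage pooled-feature statistics from a representative set.

        One shared scale per stage block (the block's feature standard
        deviation).  The statistics do not enter the forward computation;
        they convert the FCL weight blocks into standardized-feature units
        for :func:`layer_weight_rms`, making the per-stage comparison fair.
        """
        feats = np.concatenate(
            [self.pooled_features(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        )
        self.feature_mean = feats.mean(axis=0)
        centered = feats - self.feature_mean
        c = self.cfg.channels
        scale = np.ones(feats.shape[1])
        for s in range(self.cfg.stages):
            block_sd = float(centered[:, s * c : (s + 1) * c].std())
            scale[s * c : (s + 1) * c] = block_sd if block_sd > 1e-8 else 1.0
        self.feature_scale = scale

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.pooled_features(x, train=train)
        z1 = self.fc1.forward(f, train=train)
        m1 = z1 > 0
        out = self.fc2.forward(z1 * m1, train=train)
        if train:
            self._cache["m1"] = m1
        return out

    def backward(self, dout: np.ndarray) -> None:
        c = self.cfg.channels
        d1 = self.fc2.backward(dout)
        df = self.fc1.backward(d1 * self._cache["m1"])
        relu_masks, shapes = self._cache["relu_masks"], self._cache["shapes"]
        dh_next = None
        for s in reversed(range(len(self.convs))):
            _, _, hh, ww = shapes[s]
            # pooled-feature gradient spread uniformly over the stage's pixels
            dpool = df[:, s * c : (s + 1) * c, None, None] / (hh * ww)
            dh = np.broadcast_to(dpool, shapes[s]).copy()
            if dh_next is not None:
                dh += dh_next
            dz = dh * relu_masks[s]
            dh_next = self.convs[s].backward(dz)

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = self.forward(x, train=False)
        return out[0] if np.asarray(x).ndim == 3 else out

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {}
        for i, conv in enumerate(self.convs):
            state[f"conv{i}.W"], state[f"conv{i}.b"] = conv.W, conv.b
        state["fc1.W"], state["fc1.b"] = self.fc1.W, self.fc1.b
        state["fc2.W"], state["fc2.b"] = self.fc2.W, self.fc2.b
        state["feature_mean"] = self.feature_mean
        state["feature_scale"] = self.feature_scale
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, conv in enumerate(self.convs):
            conv.W = np.array(state[f"conv{i}.W"])
            conv.b = np.array(state[f"conv{i}.b"])
        self.fc1.W, self.fc1.b = np.array(state["fc1.W"]), np.array(state["fc1.b"])
        self.fc2.W, self.fc2.b = np.array(state["fc2.W"]), np.array(state["fc2.b"])
        self.feature_mean = np.array(state["feature_mean"])
        self.feature_scale = np.array(state["feature_scale"])

    @property
    def layers(self):
        return self.convs + [self.fc1, self.fc2]


def _safe_params(layer):
    out = []
    for name in ("W", "b"):
        p = getattr(layer, name)
        d = getattr(layer, "d" + name, None)
        out.append((name, p, d))
    return out


class _Adam:
    """Adam with decoupled weight decay (biases are not decayed)."""

    def __init__(self, layers, lr: float, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for layer in layers for _, p, _ in _safe_params(layer)]
        self.v = [np.zeros_like(p) for layer in layers for _, p, _ in _safe_params(layer)]

    def step(self):
        self.t += 1
        i = 0
        for layer in self.layers:
            for name, p, g in _safe_params(layer):
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if self.wd and name == "W":
                    p -= self.lr * self.wd * p
                i += 1


@dataclass
class TrainingHistory:
    """Loss curve and the manifest of one training run."""

    train_loss: List[float] = field(default_factory=list)
    val_rmse: List[float] = field(default_factory=list)
    best_epoch: int = -1
    manifest: Dict = field(default_factory=dict)


def train(
    model: MultiScaleCNN,
    X: np.ndarray,
    Y: np.ndarray,
    epochs: int = 20,
    lr: float = 2e-3,
    batch_size: int = 64,
    seed: int = 0,
    val_fraction: float = 0.1,
    patience: int = 5,
    weight_decay: float = 0.0,
    verbose: bool = False,
) -> TrainingHistory:
    """Supervised MSE training of the coefficient regressor.

    A validation split (last ``val_fraction`` of a seeded shuffle) drives
    early stopping: training halts after ``patience`` epochs without a new
    best validation RMSE and the best weights are restored.  Decoupled
    weight decay regularizes the weights (not biases); besides the usual
    generalization benefit it prunes uninformative connections, which is
    what makes the per-stage weight-RMS readout interpretable.  Fully
    deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y lengths differ")
    if X.shape[1] != model.cfg.m_channels or Y.shape[1] != model.cfg.n_modes:
        raise ValueError(
            f"dataset dims (M={X.shape[1]}, N={Y.shape[1]}) do not match model "
            f"(M={model.cfg.m_channels}, N={model.cfg.n_modes})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    n_val = max(1, int(val_fraction * X.shape[0])) if val_fraction > 0 else 0
    train_idx, val_idx = order[: X.shape[0] - n_val], order[X.shape[0] - n_val :]
    model.calibrate_features(X[train_idx])
    opt = _Adam(model.layers, lr=lr, weight_decay=weight_decay)
    history = TrainingHistory(manifest={
        "n_train": int(len(train_idx)), "n_val": int(n_val), "epochs": epochs,
        "lr": lr, "batch_size": batch_size, "seed": seed,
    })
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    for epoch in range(epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for s0 in range(0, len(perm), batch_size):
            idx = perm[s0 : s0 + batch_size]
            xb, yb = X[idx], Y[idx]
            pred = model.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {s0 // batch_size} "
                    f"(lr={lr}); reduce the learning rate"
                )
            losses.append(loss)
            model.backward(2.0 * err / err.size)
            opt.step()
        history.train_loss.append(float(np.mean(losses)))
        if n_val:
            val_pred = model.forward(X[val_idx], train=False)
            val_rmse = float(np.sqrt(np.mean((val_pred - Y[val_idx]) ** 2)))
            history.val_rmse.append(val_rmse)
            if val_rmse < best_val - 1e-6:
                best_val = val_rmse
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
                history.best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
            if verbose:
                print(f"epoch {epoch:3d}  train mse {history.train_loss[-1]:.5f}  val rmse {val_rmse:.4f}")
            if bad_epochs >= patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def estimate(model: MultiScaleCNN, pseudo_psf_stack: np.ndarray) -> ZernikeCoefficients:
    """Predict the base aberration from an (M, 32, 32) pseudo-PSF stack.

    The correction to apply is the negation of the returned coefficients.
    """
    stack = np.asarray(pseudo_psf_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a single (M, 32, 32) stack")
    pred = model.predict(stack)
    return ZernikeCoefficients.from_vector(model.cfg.mode_list, pred)


def layer_weight_rms(model: MultiScaleCNN) -> List[float]:
    """RMS of the FCL weight block connected to each scale stage's features.

    One value per stage: the block of first-FCL columns fed by that stage's
    pooled feature vector, expressed in standardized-feature units (the raw
    block RMS times the stage's calibrated feature scale — the weights the
    network would carry if its features had unit variance).  Without the
    common scale, raw weight magnitudes would confound information content
    with the arbitrary numeric range of each stage's features.  Comparing
    the values shows which spatial scales of the pseudo-PSF the trained
    estimator draws on most.
    """
    c = model.cfg.channels
    W = model.fc1.W  # (fcl_width, stages * channels)
    out = []
    for s in range(model.cfg.stages):
        block_rms = float(np.sqrt(np.mean(W[:, s * c : (s + 1) * c] ** 2)))
        out.append(block_rms * float(model.feature_scale[s * c]))
    return out


def save_model(model: MultiScaleCNN, path: Path, history: Optional[TrainingHistory] = None) -> None:
    """Checkpoint: weights plus embedded config (and training manifest)."""
    path = Path(path)
    cfg = model.cfg
    meta = {
        "m_channels": cfg.m_channels, "n_modes": cfg.n_modes, "stages": cfg.stages,
        "channels": cfg.channels, "fcl_width": cfg.fcl_width, "seed": cfg.seed,
        "modes": list(cfg.mode_list),
    }
    if history is not None:
        meta["training"] = {
            "train_loss": history.train_loss, "val_rmse": history.val_rmse,
            "best_epoch": history.best_epoch, **history.manifest,
        }
    np.savez(path, __config__=json.dumps(meta), **model.state_dict())


def load_model(path: Path) -> MultiScaleCNN:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__config__"]))
        state = {k: z[k] for k in z.files if k != "__config__"}
    cfg = ModelConfig(
        m_channels=meta["m_channels"], n_modes=meta["n_modes"], stages=meta["stages"],
        channels=meta["channels"], fcl_width=meta["fcl_width"], seed=meta["seed"],
        modes=tuple(meta["modes"]),
    )
    model = MultiScaleCNN(cfg)
    model.load_state_dict(state)
    return model


class MLAOEstimator:
    """Closed-loop adapter: acquire the scheme's frames, predict, correct.

    Implements the same cycle interface as the conventional estimators so
    the control loop treats learned and classical methods uniformly.
    """

    def __init__(self, model: MultiScaleCNN, scheme, eps: float = 1e-3):
        if scheme.n_channels != model.cfg.m_channels:
            raise ValueError(
                f"scheme provides {scheme.n_channels} channels, model expects {model.cfg.m_channels}"
            )
        self.model = model
        self.scheme = scheme
        self.eps = eps

    def stack_from_system(self, system) -> np.ndarray:
        channels = []
        for b_plus, b_minus in self.scheme.pairs:
            f_plus = system.acquire(b_plus)
            f_minus = system.acquire(b_minus)
            c0, c1 = pseudo_psf_pair(f_plus, f_minus, eps=self.eps)
            channels.extend([c0, c1])
        return normalize_stack(np.stack(channels))

    def one_cycle(self, system) -> ZernikeCoefficients:
        stack = self.stack_from_system(system)
        predicted = estimate(self.model, stack)
        correction = -ZernikeCoefficients.from_vector(
            self.scheme.modes, predicted.as_vector(self.model.cfg.mode_list)
        )
        system.apply_correction(correction)
        return correction
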