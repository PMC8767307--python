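"""Encoder backbone, projection head and evaluator heads, in pure NumPy.

The contrastive pipeline needs four trainable pieces: an encoder f mapping a
spectrogram to a length-N representation h, a single-linear projection head g
mapping h to a 256-dimensional z for the contrastive loss, a linear evaluator
(frozen-encoder pipeline: one linear layer + sigmoid) and a two-layer SSL
evaluator (linear N->N, batch norm, ReLU, linear N->1, sigmoid) trained
end-to-end with the encoder during fine-tuning.

Everything is implemented as small NumPy layers with explicit forward and
backward passes so training runs anywhere, deterministically, at desk scale.
The encoder family is a compact CNN sized for CPU: ``tiny_cnn`` (two conv
layers + pooling + linear, used throughout the test suite) and ``small_cnn``
(three conv blocks).  Gradients are exact and are verified against finite
differences in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .signal_io import Spectrogram

ARCHITECTURES = ("tiny_cnn", "small_cnn")


@dataclass(frozen=True)
class EncoderConfig:
    architecture: str = "tiny_cnn"
    embedding_dim: int = 32
    projection_dim: int = 256
    input_shape: tuple[int, int] | None = None  # (n_bins, n_frames), optional check
    # affine input standardization (x - offset) / scale applied before conv;
    # log-power spectrograms live around -50 dB with ~25 dB spread
    input_offset: float = 0.0
    input_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}, "
                             f"got {self.architecture!r}")
        if self.embedding_dim < 1 or self.projection_dim < 1:
            raise ValueError("dimensions must be >= 1")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Minimal trainable layer: params/grads dicts + forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params = {"W": rng.normal(0.0, scale, size=(d_out, d_in)),
                       "b": np.zeros(d_out)}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad):
        self.grads = {"W": grad.T @ self._x, "b": grad.sum(axis=0)}
        return grad @ self.params["W"]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    """Used in the conv encoders; avoids dead units at small training scale."""

    def __init__(self, slope: float = 0.1) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution via sliding windows, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {"W": rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)),
                       "b": np.zeros(c_out)}

    def forward(self, x, train):
        k, p = self.kernel, self.pad
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (B, C, Ho, Wo, k, k)
        Ho, Wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k)
        Wmat = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = cols @ Wmat.T + self.params["b"]
        self._cache = (cols, x.shape, (Ho, Wo))
        return out.transpose(0, 2, 1).reshape(B, -1, Ho, Wo)

    def backward(self, grad):
        cols, xshape, (Ho, Wo) = self._cache
        B, C, H, W = xshape
        k, p = self.kernel, self.pad
        c_out = grad.shape[1]
        g = grad.reshape(B, c_out, Ho * Wo).transpose(0, 2, 1)  # (B, HoWo, c_out)
        Wmat = self.params["W"].reshape(c_out, -1)
        dW = np.einsum("bpf,bpc->fc", g, cols)
        self.grads = {"W": dW.reshape(self.params["W"].shape),
                      "b": g.sum(axis=(0, 1))}
        dcols = g @ Wmat  # (B, HoWo, C*k*k)
        dcols = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + H, p:p + W]


class AvgPool2d(Layer):
    """Non-overlapping average pooling; trailing remainder rows/cols dropped."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k

    def forward(self, x, train):
        k = self.k
        B, C, H, W = x.shape
        Ho, Wo = H // k, W // k
        self._in_shape = x.shape
        xc = x[:, :, :Ho * k, :Wo * k].reshape(B, C, Ho, k, Wo, k)
        return xc.mean(axis=(3, 5))

    def backward(self, grad):
        k = self.k
        B, C, H, W = self._in_shape
        Ho, Wo = H // k, W // k
        dx = np.zeros(self._in_shape)
        up = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, :Ho * k, :Wo * k] = up
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], self._in_shape) / (H * W)


class BatchNorm1d(Layer):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            if x.shape[0] < 2:
                raise ValueError("batch norm is undefined for a training batch "
                                 "of size 1; use eval mode or a larger batch")
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._std = np.sqrt(var + self.eps)
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        self.grads = {"gamma": (grad * xhat).sum(axis=0), "beta": grad.sum(axis=0)}
        gx = grad * self.params["gamma"]
        if not self._train:
            return gx / std
        n = grad.shape[0]
        return (gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)) / std


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_params(self) -> Iterator[tuple[str, Layer, str]]:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"layer{i}.{name}", layer, name


def sigmoid(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, None, 60))),
                    np.exp(np.clip(x, -60, None))
                    / (1.0 + np.exp(np.clip(x, -60, None))))


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and gradient w.r.t. the logits."""
    logits = logits.reshape(-1)
    y = y.reshape(-1)
    loss = np.mean(np.logaddexp(0.0, logits) - y * logits)
    grad = (sigmoid(logits) - y) / logits.size
    return float(loss), grad.reshape(-1, 1)


# ---------------------------------------------------------------------------
# Model components
# ---------------------------------------------------------------------------

def _build_encoder_layers(cfg: EncoderConfig, rng: np.random.Generator) -> Sequential:
    if cfg.architecture == "tiny_cnn":
        return Sequential([
            Conv2d(1, 4, 3, rng), LeakyReLU(), AvgPool2d(2),
            Conv2d(4, 8, 3, rng), LeakyReLU(), GlobalAvgPool(),
            Linear(8, cfg.embedding_dim, rng),
        ])
    return Sequential([
        Conv2d(1, 8, 3, rng), LeakyReLU(), AvgPool2d(2),
        Conv2d(8, 16, 3, rng), LeakyReLU(), AvgPool2d(2),
        Conv2d(16, 32, 3, rng), LeakyReLU(), GlobalAvgPool(),
        Linear(32, cfg.embedding_dim, rng),
    ])


def _as_batch(specs) -> np.ndarray:
    if isinstance(specs, Spectrogram):
        specs = [specs]
    if isinstance(specs, np.ndarray):
        arr = specs
        if arr.ndim == 2:
            arr = arr[None]
        return arr[:, None, :, :].astype(np.float64)
    return np.stack([s.values for s in specs])[:, None, :, :]


class Encoder:
    """Spectrogram -> length-N representation h."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.net = _build_encoder_layers(cfg, np.random.default_rng(seed))

    def encode(self, specs, train: bool = False) -> np.ndarray:
        x = _as_batch(specs)
        if self.cfg.input_shape is not None:
            if tuple(x.shape[2:]) != tuple(self.cfg.input_shape):
                raise ValueError(
                    f"input geometry {tuple(x.shape[2:])} does not match the "
                    f"configured {tuple(self.cfg.input_shape)}")
        x = (x - self.cfg.input_offset) / self.cfg.input_scale
        return self.net.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


class ProjectionHead:
    """Single linear map h -> z (length projection_dim)."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0) -> None:
        self.net = Sequential([Linear(cfg.embedding_dim, cfg.projection_dim,
                                      np.random.default_rng(seed))])

    def project(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(np.atleast_2d(h), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


class LinearHead:
    """Frozen-encoder evaluator: one linear layer + sigmoid."""

    def __init__(self, embedding_dim: int, seed: int = 0) -> None:
        self.net = Sequential([Linear(embedding_dim, 1, np.random.default_rng(seed))])

    def logits(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(np.atleast_2d(h), train)

    def predict_proba(self, h: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(h)).reshape(-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


class SSLEvaluator:
    """Two-layer head: linear N->N, batch norm, ReLU, linear N->1, sigmoid."""

    def __init__(self, embedding_dim: int, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.net = Sequential([
            Linear(embedding_dim, embedding_dim, rng),
            BatchNorm1d(embedding_dim),
            ReLU(),
            Linear(embedding_dim, 1, rng),
        ])

    def logits(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(np.atleast_2d(h), train)

    def predict_proba(self, h: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(h, train=False)).reshape(-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


def n_parameters(*components) -> int:
    total = 0
    for comp in components:
        net = comp.net if hasattr(comp, "net") else comp
        for _, layer, name in net.named_params():
            total += layer.params[name].size
    return total


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled-from-nothing classic L2 penalty added to gradients."""

    def __init__(self, nets: Sequence[Sequential], lr: float,
                 weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.nets = list(nets)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for ni, net in enumerate(self.nets):
            for pname, layer, name in net.named_params():
                g = layer.grads.get(name)
                if g is None:
                    continue
                p = layer.params[name]
                if self.weight_decay and name not in ("b", "beta", "gamma"):
                    g = g + self.weight_decay * p
                key = (ni, pname)
                m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                layer.params[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for net in self.nets:
            for _, layer, name in net.named_params():
                layer.grads = {}


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def state_dict(component) -> dict[str, np.ndarray]:
    net = component.net if hasattr(component, "net") else component
    out = {}
    for pname, layer, name in net.named_params():
        out[pname] = layer.params[name].copy()
    for i, layer in enumerate(net.layers):
        if isinstance(layer, BatchNorm1d):
            out[f"layer{i}.running_mean"] = layer.running_mean.copy()
            out[f"layer{i}.running_var"] = layer.running_var.copy()
    return out


def load_state_dict(component, state: dict[str, np.ndarray]) -> None:
    net = component.net if hasattr(component, "net") else component
    for pname, layer, name in net.named_params():
        layer.params[name] = np.array(state[pname])
    for i, layer in enumerate(net.layers):
        if isinstance(layer, BatchNorm1d):
            layer.running_mean = np.array(state[f"layer{i}.running_mean"])
            layer.running_var = np.array(state[f"layer{i}.running_var"])


@dataclass
class Checkpoint:
    """Weights + full config + seed: sufficient to reproduce an evaluation."""

    encoder_config: EncoderConfig
    encoder_state: dict[str, np.ndarray]
    projection_state: dict[str, np.ndarray] | None
    seed: int
    scheme: str | None = None
    loss_curve: list[float] | None = None

    def build_encoder(self) -> Encoder:
        enc = Encoder(self.encoder_config, seed=self.seed)
        load_state_dict(enc, self.encoder_state)
        return enc

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"enc.{k}": v for k, v in self.encoder_state.items()}
        if self.projection_state:
            arrays.update({f"proj.{k}": v for k, v in self.projection_state.items()})
        meta = {"encoder_config": asdict(self.encoder_config), "seed": self.seed,
                "scheme": self.scheme, "loss_curve": self.loss_curve}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            enc_state = {k[4:]: data[k] for k in data.files if k.startswith("enc.")}
            proj_state = {k[5:]: data[k] for k in data.files if k.startswith("proj.")}
        cfg_d = meta["encoder_config"]
        if cfg_d.get("input_shape"):
            cfg_d["input_shape"] = tuple(cfg_d["input_shape"])
        cfg = EncoderConfig(**cfg_d)
        return cls(encoder_config=cfg, encoder_state=enc_state,
                   projection_state=proj_state or None, seed=int(meta["seed"]),
                   scheme=meta.get("scheme"), loss_curve=meta.get("loss_curve"))
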