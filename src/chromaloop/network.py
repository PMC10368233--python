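"""Dilated residual convolutional network for per-pixel interaction logits.

The network maps a ``C x W x W`` input (Hi-C tile plus broadcast ChIP-seq
channels) to a ``W x W`` logit map.  Architecture: a 1x1 convolution lifting
the channel dimension to H (default 128), batch norm and ReLU; a stack of B
(default 40) post-activation residual blocks, each holding two dilated 3x3
convolutions whose dilation values cycle through a configurable schedule so
receptive fields span the whole evaluated distance band; and a 1x1 convolution
with batch norm reducing H to a single logit channel.  A logistic sigmoid is
applied only at inference; training uses the numerically stable weighted
binary cross entropy on logits.

Everything here — convolution via im2col, the normalization layers, and the
backward passes — is implemented in NumPy so the model is self-contained and
exactly reproducible on CPU.
"""
from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

DTYPE = np.float32

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    in_channels: int = 3
    hidden_dim: int = 128
    n_blocks: int = 40
    kernel: int = 3
    dilation_cycle: Tuple[int, ...] = (1, 2, 4, 8, 16)
    norm: str = "batch"  # batch | instance | group
    group_norm_groups: int = 8

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.n_blocks < 1:
            raise ValueError("hidden_dim and n_blocks must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        if not self.dilation_cycle or any(d < 1 for d in self.dilation_cycle):
            raise ValueError("dilation_cycle entries must be positive")
        if self.norm not in ("batch", "instance", "group"):
            raise ValueError(f"unknown norm {self.norm!r}")

    def block_dilations(self) -> List[Tuple[int, int]]:
        """Dilations (d1, d2) per block: the 2B dilated convs take the cycle
        values in order, so the two convs of each block differ."""
        cyc = self.dilation_cycle
        return [
            (cyc[(2 * b) % len(cyc)], cyc[(2 * b + 1) % len(cyc)])
            for b in range(self.n_blocks)
        ]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2d:
    """Same-padding 2D convolution with dilation, via im2col matmul."""

    def __init__(self, cin: int, cout: int, k: int, dilation: int, rng, name: str):
        self.cin, self.cout, self.k, self.dilation = cin, cout, k, dilation
        std = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU nets
        self.w = Param(f"{name}.w", rng.normal(0.0, std, size=(cout, cin * k * k)))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self._cols: Optional[np.ndarray] = None
        self._shape: Optional[tuple] = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        k, d = self.k, self.dilation
        if k == 1:
            return x.transpose(0, 2, 3, 1).reshape(N, H * W, C)
        p = d * (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ext = d * (k - 1) + 1
        v = np.lib.stride_tricks.sliding_window_view(xp, (ext, ext), axis=(2, 3))
        v = v[:, :, :, :, ::d, ::d]  # (N, C, H, W, k, k)
        return v.transpose(0, 2, 3, 1, 4, 5).reshape(N, H * W, C * k * k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        cols = np.ascontiguousarray(self._im2col(x))
        if train:
            self._cols, self._shape = cols, x.shape
        y = cols.reshape(N * H * W, -1) @ self.w.value.T + self.b.value
        return y.reshape(N, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        k, d = self.k, self.dilation
        dy2 = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 1).astype(DTYPE)
        ).reshape(N * H * W, self.cout)
        cols2 = self._cols.reshape(N * H * W, -1)
        self.w.grad += dy2.T @ cols2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.w.value).reshape(N, H * W, -1)
        if k == 1:
            dx = dcols.reshape(N, H, W, C).transpose(0, 3, 1, 2)
        else:
            p = d * (k - 1) // 2
            dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
            dc = dcols.reshape(N, H, W, C, k, k).transpose(0, 3, 4, 5, 1, 2)
            for a in range(k):
                for b in range(k):
                    dxp[:, :, a * d : a * d + H, b * d : b * d + W] += dc[:, :, a, b]
            dx = dxp[:, :, p : p + H, p : p + W]
        self._cols = None
        return np.ascontiguousarray(dx)


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(DTYPE)


class GroupNorm2d:
    """Group normalization (instance norm when groups == channels)."""

    def __init__(self, c: int, groups: int, name: str, eps: float = 1e-5):
        if c % groups != 0:
            raise ValueError("channels must be divisible by groups")
        self.c, self.g, self.eps = c, groups, eps
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        xg = x.reshape(N, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * invstd).reshape(N, C, H, W)
        if train:
            self._cache = (xhat, invstd, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, shape = self._cache
        N, C, H, W = shape
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.value[None, :, None, None]).reshape(N, self.g, -1)
        xh = xhat.reshape(N, self.g, -1)
        m = dxhat.shape[2]
        s1 = dxhat.sum(axis=2, keepdims=True)
        s2 = (dxhat * xh).sum(axis=2, keepdims=True)
        dx = (invstd / m) * (m * dxhat - s1 - xh * s2)
        self._cache = None
        return dx.reshape(N, C, H, W).astype(DTYPE)


def _make_norm(cfg: ModelConfig, c: int, name: str):
    if cfg.norm == "batch":
        return BatchNorm2d(c, name)
    groups = c if cfg.norm == "instance" else min(cfg.group_norm_groups, c)
    return GroupNorm2d(c, groups, name)


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class ResidualBlock:
    """Post-activation residual block: conv-norm-relu-conv-norm + skip, ReLU."""

    def __init__(self, cfg: ModelConfig, d1: int, d2: int, rng, name: str):
        H, k = cfg.hidden_dim, cfg.kernel
        self.conv1 = Conv2d(H, H, k, d1, rng, f"{name}.conv1")
        self.norm1 = _make_norm(cfg, H, f"{name}.norm1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(H, H, k, d2, rng, f"{name}.conv2")
        self.norm2 = _make_norm(cfg, H, f"{name}.norm2")
        self.relu_out = ReLU()
        self.dilations = (d1, d2)

    def params(self) -> List[Param]:
        return (self.conv1.params() + self.norm1.params()
                + self.conv2.params() + self.norm2.params())

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.norm1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.norm2.forward(h, train)
        return self.relu_out.forward(x + h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dy)
        dh = self.norm2.backward(dsum)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.norm1.backward(dh)
        dh = self.conv1.backward(dh)
        return dsum + dh


class DilatedResNet:
    """The full logit network; see the module docstring."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.conv_in = Conv2d(cfg.in_channels, cfg.hidden_dim, 1, 1, rng, "conv_in")
        self.norm_in = _make_norm(cfg, cfg.hidden_dim, "norm_in")
        self.relu_in = ReLU()
        self.blocks = [
            ResidualBlock(cfg, d1, d2, rng, f"block{b}")
            for b, (d1, d2) in enumerate(cfg.block_dilations())
        ]
        self.conv_out = Conv2d(cfg.hidden_dim, 1, 1, 1, rng, "conv_out")
        self.norm_out = _make_norm(cfg, 1, "norm_out")

    def parameters(self) -> List[Param]:
        ps = self.conv_in.params() + self.norm_in.params()
        for b in self.blocks:
            ps += b.params()
        ps += self.conv_out.params() + self.norm_out.params()
        return ps

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Input (N, C, W, W) float -> logits (N, 1, W, W)."""
        x = np.ascontiguousarray(np.asarray(x, dtype=DTYPE))
        h = self.conv_in.forward(x, train)
        h = self.norm_in.forward(h, train)
        h = self.relu_in.forward(h, train)
        for b in self.blocks:
            h = b.forward(h, train)
        h = self.conv_out.forward(h, train)
        return self.norm_out.forward(h, train)

    __call__ = forward

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.norm_out.backward(dlogits.astype(DTYPE))
        d = self.conv_out.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = self.relu_in.backward(d)
        d = self.norm_in.backward(d)
        self.conv_in.backward(d)

    # -- state ---------------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for name, layer in self._norm_layers():
            if isinstance(layer, BatchNorm2d):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value = np.asarray(state[p.name], dtype=DTYPE).copy()
        for name, layer in self._norm_layers():
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.asarray(state[f"{name}.running_mean"], dtype=DTYPE).copy()
                layer.running_var = np.asarray(state[f"{name}.running_var"], dtype=DTYPE).copy()

    def _norm_layers(self):
        yield "norm_in", self.norm_in
        for i, b in enumerate(self.blocks):
            yield f"block{i}.norm1", b.norm1
            yield f"block{i}.norm2", b.norm2
        yield "norm_out", self.norm_out


def build_model(cfg: ModelConfig, seed: int = 0) -> DilatedResNet:
    return DilatedResNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Output head and loss
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_probs(model: DilatedResNet, batch: np.ndarray) -> np.ndarray:
    """Per-pixel interaction probabilities, logistic of the eval-mode logits."""
    return sigmoid(model.forward(batch, train=False))


def weighted_bce(
    logits: np.ndarray,
    labels: np.ndarray,
    pos_weight: float = 1.0,
    return_grad: bool = False,
    pixel_mask: Optional[np.ndarray] = None,
):
    """Mean positive-weighted binary cross entropy on logits.

    ``loss = mean( -[w*y*log(sigma(z)) + (1-y)*log(1-sigma(z))] )`` computed in
    the stable ``(1-y)*z + (1+(w-1)*y)*log(1+exp(-|z|)) + max(-z, 0)...`` form.
    ``pixel_mask`` (same shape, boolean) restricts the mean to valid pixels
    (used to ignore zero-padded tile tails).  With ``return_grad`` the
    gradient with respect to the logits is returned as well.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    w = 1.0 + (pos_weight - 1.0) * y
    # log(1 + exp(-z)) stably: max(-z, 0) + log1p(exp(-|z|))
    softplus_neg = np.maximum(-z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    per_pixel = (1.0 - y) * z + w * softplus_neg
    if pixel_mask is not None:
        m = np.asarray(pixel_mask, dtype=bool)
        count = m.sum()
        loss = float(per_pixel[m].sum() / count) if count else 0.0
    else:
        m = None
        count = per_pixel.size
        loss = float(per_pixel.mean())
    if not return_grad:
        return loss
    s = sigmoid(z)
    grad = ((1.0 - y) * s - pos_weight * y * (1.0 - s)) / max(count, 1)
    if m is not None:
        grad = np.where(m, grad, 0.0)
    return loss, grad.astype(DTYPE)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: DilatedResNet, meta: Optional[dict] = None) -> None:
    """Serialize weights + ModelConfig (+ normalization stats etc.) to .npz."""
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    header = {
        "version": CHECKPOINT_VERSION,
        "model_config": asdict(model.cfg),
        "meta": meta or {},
    }
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8
    )
    np.savez(str(path), **arrays)


def load_checkpoint(path) -> Tuple[DilatedResNet, dict]:
    with np.load(str(path)) as z:
        header = json.loads(bytes(z["header"]).decode("utf-8"))
        state = {
            k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")
        }
    mc = header["model_config"]
    mc["dilation_cycle"] = tuple(mc["dilation_cycle"])
    model = DilatedResNet(ModelConfig(**mc))
    model.load_state_dict(state)
    return model, header.get("meta", {})
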