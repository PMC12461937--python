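"""Minimal CPU neural-network engine used by the classifiers.

Implements exactly the pieces the micro-CNN architecture needs — 2D
convolution (im2col), 2x2 max pooling, inverted dropout, dense layers,
ReLU, softmax cross-entropy with class weights, the class-anchor
distance loss, and Adam — in plain numpy.  The networks involved are
tiny (tens of thousands of parameters, 32x32 inputs), so batched matmul
is fast enough for CPU training, and keeping the engine in-repo makes
training bit-reproducible from a single integer seed.

All stochasticity (weight init, batch shuffling, dropout masks) flows
through explicitly passed ``numpy.random.Generator`` objects.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless unless it holds parameters."""

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


def _im2col(xp: np.ndarray, k: int, H: int, W: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*k*k, H*W) patch matrix."""
    N, C = xp.shape[:2]
    cols = np.empty((N, C, k * k, H, W), dtype=xp.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            cols[:, :, idx] = xp[:, :, i:i + H, j:j + W]
            idx += 1
    return cols.reshape(N, C * k * k, H * W)


class Conv2d(Layer):
    """Same-padded k x k convolution, stride 1, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x, train, rng):
        N, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, self.k, H, W)
        out = np.matmul(self.w, cols) + self.b[:, None]
        self._cache = (cols, (N, C, H, W))
        return out.reshape(N, self.c_out, H, W)

    def backward(self, grad):
        cols, (N, C, H, W) = self._cache
        g = grad.reshape(N, self.c_out, H * W)
        self.dw = np.einsum("nfh,nch->fc", g, cols)
        self.db = g.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, g)  # (N, C*k*k, H*W)
        k, p = self.k, self.k // 2
        dcols = dcols.reshape(N, C, k, k, H, W)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, i, j]
        return dxp[:, :, p:p + H, p:p + W]

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; first maximum wins on ties."""

    def forward(self, x, train, rng):
        N, C, H, W = x.shape
        assert H % 2 == 0 and W % 2 == 0, "feature map must be even-sized"
        xr = (
            x.reshape(N, C, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H // 2, W // 2, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = (N, C, H, W)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        N, C, H, W = self._shape
        flat = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        return (
            flat.reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )


class Dropout(Layer):
    """Inverted dropout; exact identity when rate == 0 or at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_out, d_in))
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.dw = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.w

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def param_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params]


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for l in model.param_layers for p in l.params]
        self.v = [np.zeros_like(p) for l in model.param_layers for p in l.params]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.model.param_layers:
            for p, g in zip(layer.params, layer.grads):
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                mhat = self.m[i] / (1 - self.beta1**self.t)
                vhat = self.v[i] / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray,
    y: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted categorical cross-entropy; returns (loss, dL/dlogits)."""
    n, k = logits.shape
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[y]
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float(-(w * logp).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad


def anchor_distances(embed: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Euclidean distance of each embedding to each class anchor: (N, K)."""
    diff = embed[:, None, :] - anchors[None, :, :]
    return np.sqrt((diff**2).sum(axis=2) + 1e-12)


def cac_loss(
    embed: np.ndarray,
    y: np.ndarray,
    anchors: np.ndarray,
    anchor_weight: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Class-anchor clustering loss; returns (loss, dL/dembed).

    Tuplet term: cross-entropy on the negated anchor distances, pulling
    the sample toward its own anchor relative to the others.  Anchor
    term: the raw distance to the sample's own anchor.  Together they
    shrink intra-class distance while growing inter-class distance.
    """
    n = len(y)
    d = anchor_distances(embed, anchors)  # (N, K)
    p = softmax(-d)
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    tuplet = float(-logp.mean())
    own = float(d[np.arange(n), y].mean())
    # L_tuplet = -log softmax(-d)[y]: dL/d(-d) = (p - onehot)/n, so
    # dL/dd = (onehot - p)/n
    dd = (np.eye(anchors.shape[0])[y] - p) / n
    dd_anchor = np.zeros_like(d)
    dd_anchor[np.arange(n), y] = anchor_weight / n
    dd_total = dd + dd_anchor
    diff = embed[:, None, :] - anchors[None, :, :]
    dembed = (dd_total[:, :, None] * diff / d[:, :, None]).sum(axis=1)
    return tuplet + anchor_weight * own, dembed
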