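"""Minimal NumPy neural-network core for the segmentation model.

Implements exactly the layers the pyramid-pooling segmentation network
needs — strided 2D convolution (im2col), ReLU, block average pooling,
bilinear up-sampling, dropout, sigmoid — with hand-written backward
passes and an Adam optimizer.  Everything is float32 and driven by an
explicit ``numpy.random.Generator``, so training is reproducible on a
fixed BLAS configuration.

Average pooling and bilinear interpolation are both expressed as a pair
of per-axis linear maps ``y = P_r x P_c^T``, which makes their backward
passes plain transposed matmuls and keeps the whole network inside BLAS.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


# ---------------------------------------------------------------------------
# axis resampling matrices


def avgpool_matrix(size_in: int, bins: int) -> np.ndarray:
    """Uniform block-average map from ``size_in`` samples to ``bins`` bins."""
    if size_in % bins != 0:
        raise ValueError(f"pooling needs size {size_in} divisible by bins {bins}")
    block = size_in // bins
    mat = np.zeros((bins, size_in), dtype=F32)
    for b in range(bins):
        mat[b, b * block : (b + 1) * block] = 1.0 / block
    return mat


def bilinear_matrix(size_in: int, size_out: int) -> np.ndarray:
    """Linear-interpolation map from ``size_in`` to ``size_out`` samples.

    Uses the half-pixel-centre (align_corners=False) convention: output
    sample ``o`` reads source coordinate ``(o + 0.5) * size_in/size_out
    - 0.5``, clamped at the borders.
    """
    mat = np.zeros((size_out, size_in), dtype=F32)
    scale = size_in / size_out
    for o in range(size_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        w = src - i0
        i0c = min(max(i0, 0), size_in - 1)
        i1c = min(max(i0 + 1, 0), size_in - 1)
        mat[o, i0c] += 1.0 - w
        mat[o, i1c] += w
    return mat


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: forward caches what backward needs; params/grads paired."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution with stride and symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.w = (rng.standard_normal((c_out, fan_in)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.dw, self.db]
        self._cache: tuple | None = None

    def _out_size(self, size: int) -> int:
        return (size + 2 * self.pad - self.k) // self.stride + 1

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        n, c = xp.shape[:2]
        s = self.stride
        cols = np.empty((n, c, self.k, self.k, oh, ow), dtype=F32)
        for ki in range(self.k):
            for kj in range(self.k):
                cols[:, :, ki, kj] = xp[
                    :, :, ki : ki + s * oh : s, kj : kj + s * ow : s
                ]
        return cols.reshape(n, c * self.k * self.k, oh * ow)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self._out_size(h), self._out_size(w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols = self._im2col(xp, oh, ow)
        y = np.matmul(self.w, cols) + self.b[None, :, None]
        self._cache = (cols, xp.shape, (oh, ow))
        return y.reshape(n, self.c_out, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (oh, ow) = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.c_out, oh * ow)
        self.dw[...] = np.einsum("nol,nkl->ok", dyf, cols)
        self.db[...] = dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, dyf)  # (n, c*k*k, oh*ow)
        dcols = dcols.reshape(n, self.c_in, self.k, self.k, oh, ow)
        dxp = np.zeros(xp_shape, dtype=F32)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[
                    :, :, ki, kj
                ]
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(F32)


class AxisResample(Layer):
    """Separable linear spatial map ``y = P_r @ x @ P_c^T`` per channel."""

    def __init__(self, p_rows: np.ndarray, p_cols: np.ndarray) -> None:
        super().__init__()
        self.pr = p_rows.astype(F32)
        self.pc = p_cols.astype(F32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.matmul(np.matmul(self.pr, x), self.pc.T)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.matmul(np.matmul(self.pr.T, dy), self.pc)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                pairs.extend(layer.parameters())
            else:
                pairs.extend(zip(layer.params, layer.grads))
        return pairs


class Adam:
    """Adam optimizer updating (param, grad) pairs in place."""

    def __init__(self, pairs: list[tuple[np.ndarray, np.ndarray]],
                 lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.pairs = pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
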