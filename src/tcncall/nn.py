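"""NumPy building blocks for the temporal convolutional network.

Each layer stores its parameters, caches what its backward pass needs during
``forward``, and accumulates gradients into ``Param.grad`` during
``backward``.  This is a deliberately small, CPU-oriented reference
implementation: everything reduces to dense matrix products over (batch,
channel, time) arrays, which is exactly the property that makes temporal
convolutions fast relative to recurrent models.

Conventions: activations have shape (B, C, T); convolution weights have shape
(out_channels, in_channels, filter_size).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "DilatedCausalConv",
    "GLU",
    "ReLU",
    "ResidualBlock",
    "receptive_field",
    "sigmoid",
    "log_softmax",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    z = x - m
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


def receptive_field(k: int, d: int) -> int:
    """Span of past time points one dilated causal convolution can see: (k-1)*d."""
    if k < 1 or d < 1:
        raise ValueError("filter size and dilation must be >= 1")
    return (k - 1) * d


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class DilatedCausalConv:
    """Causal convolution with dilation d: H[t] = sum_a W[a] @ X[t - a*d].

    Left zero padding of length (k-1)*d preserves the time dimension, so the
    output at time t depends only on inputs at times <= t.  With
    ``weight_norm`` the filters are reparameterized as w = g * v / ||v||
    (magnitude and direction learned separately), the normalization used on
    every dilated convolution in the network.  Bias is off by default.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        filter_size: int,
        dilation: int = 1,
        weight_norm: bool = True,
        use_bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = filter_size
        self.d = dilation
        self.weight_norm = weight_norm
        self.use_bias = use_bias
        scale = 1.0 / np.sqrt(in_channels * filter_size)
        v = rng.normal(0.0, scale, size=(out_channels, in_channels, filter_size))
        if weight_norm:
            self.v = Param(v, f"{name}.v")
            # g initialized to ||v|| so the effective weight starts equal to v
            self.g = Param(np.linalg.norm(v.reshape(out_channels, -1), axis=1), f"{name}.g")
            self.params = [self.v, self.g]
        else:
            self.w = Param(v, f"{name}.w")
            self.params = [self.w]
        if use_bias:
            self.b = Param(np.zeros(out_channels), f"{name}.b")
            self.params.append(self.b)
        self._cache: tuple | None = None

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.k, self.d)

    def renormalize(self) -> None:
        """Rescale each filter's direction vector to unit norm.

        Function-preserving (w = g * v/||v|| is invariant), but it undoes the
        monotone growth of ||v|| — the gradient of v is orthogonal to v, so
        every update lengthens it — which would otherwise keep shrinking the
        effective step size on the filter direction during long runs.
        """
        if not self.weight_norm:
            return
        v = self.v.value
        norms = np.linalg.norm(v.reshape(self.out_channels, -1), axis=1)
        self.v.value = v / norms[:, None, None]

    def effective_weight(self) -> np.ndarray:
        if not self.weight_norm:
            return self.w.value
        v = self.v.value
        norms = np.linalg.norm(v.reshape(self.out_channels, -1), axis=1)
        return (self.g.value / norms)[:, None, None] * v

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, T = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        w = self.effective_weight()
        pad = (self.k - 1) * self.d
        xp = np.zeros((B, C, T + pad), dtype=x.dtype)
        xp[:, :, pad:] = x
        h = np.zeros((B, self.out_channels, T), dtype=np.float64)
        for a in range(self.k):
            start = pad - a * self.d
            # (O, C) @ (B, C, T) -> (B, O, T), BLAS-backed
            h += np.matmul(w[:, :, a], xp[:, :, start : start + T])
        if self.use_bias:
            h += self.b.value[None, :, None]
        self._cache = (xp, w, T)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        xp, w, T = self._cache
        B = xp.shape[0]
        pad = (self.k - 1) * self.d
        dW = np.zeros_like(w)
        dxp = np.zeros_like(xp)
        dh_flat = np.ascontiguousarray(dh.transpose(1, 0, 2)).reshape(self.out_channels, -1)
        for a in range(self.k):
            start = pad - a * self.d
            seg = xp[:, :, start : start + T]
            seg_flat = np.ascontiguousarray(seg.transpose(1, 0, 2)).reshape(seg.shape[1], -1)
            dW[:, :, a] = dh_flat @ seg_flat.T
            dxp[:, :, start : start + T] += np.matmul(w[:, :, a].T, dh)
        if self.use_bias:
            self.b.grad += dh.sum(axis=(0, 2))
        if self.weight_norm:
            v = self.v.value
            flat_v = v.reshape(self.out_channels, -1)
            norms = np.linalg.norm(flat_v, axis=1)
            flat_dW = dW.reshape(self.out_channels, -1)
            dot = np.sum(flat_dW * flat_v, axis=1)
            self.g.grad += dot / norms
            g = self.g.value
            dv = (g / norms)[:, None] * flat_dW - (g * dot / norms**3)[:, None] * flat_v
            self.v.grad += dv.reshape(v.shape)
        else:
            self.w.grad += dW
        return dxp[:, :, pad:]


class GLU:
    """Gated linear unit in the pointwise self-gating form: y = h * sigmoid(h)."""

    def __init__(self) -> None:
        self.params: list[Param] = []
        self._cache: np.ndarray | None = None

    def forward(self, h: np.ndarray) -> np.ndarray:
        s = sigmoid(h)
        self._cache = (h, s)
        return h * s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, s = self._cache
        return dy * (s + h * s * (1.0 - s))


class ReLU:
    def __init__(self) -> None:
        self.params: list[Param] = []
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class ResidualBlock:
    """Two weight-normalized dilated causal convolutions, each gated by a GLU,
    plus a residual connection and a final ReLU.

    The skip path is the identity when input and output channel counts match;
    otherwise a 1x1 convolution projects the input to the block's width (in
    particular the first block, whose input is the single-channel signal).
    Both convolutions share filter size, dilation and channel count, so one
    block sees 2*(k-1)*d time points of past context.
    """

    def __init__(
        self,
        in_channels: int,
        n_filters: int,
        filter_size: int,
        dilation: int,
        use_bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "block",
    ) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.conv1 = DilatedCausalConv(
            in_channels, n_filters, filter_size, dilation,
            weight_norm=True, use_bias=use_bias, rng=rng, name=f"{name}.conv1",
        )
        self.glu1 = GLU()
        self.conv2 = DilatedCausalConv(
            n_filters, n_filters, filter_size, dilation,
            weight_norm=True, use_bias=use_bias, rng=rng, name=f"{name}.conv2",
        )
        self.glu2 = GLU()
        self.proj = None
        if in_channels != n_filters:
            self.proj = DilatedCausalConv(
                in_channels, n_filters, 1, 1,
                weight_norm=False, use_bias=use_bias, rng=rng, name=f"{name}.proj",
            )
        self.relu = ReLU()
        self.params = list(self.conv1.params) + list(self.conv2.params)
        if self.proj is not None:
            self.params += list(self.proj.params)

    @property
    def receptive_field(self) -> int:
        return self.conv1.receptive_field + self.conv2.receptive_field

    def forward(self, x: np.ndarray) -> np.ndarray:
        main = self.glu2.forward(self.conv2.forward(self.glu1.forward(self.conv1.forward(x))))
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu.forward(main + skip)

    def backward(self, dz: np.ndarray) -> np.ndarray:
        dsum = self.relu.backward(dz)
        dskip = self.proj.backward(dsum) if self.proj is not None else dsum
        dmain = self.conv1.backward(
            self.glu1.backward(self.conv2.backward(self.glu2.backward(dsum)))
        )
        return dmain + dskip
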