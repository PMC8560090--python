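"""NumPy building blocks of the sequence-labeling network.

Every layer implements ``forward(x, train=False)`` and ``backward(dy)``;
``backward`` returns the gradient with respect to the input and accumulates
parameter gradients in :class:`Param` objects.  Arrays are ``[batch, time,
channels]`` float64 throughout.

Conventions
-----------
* Convolutions use centered zero "same" padding: for a kernel of size ``k``
  and dilation ``a`` the total pad is ``(k-1)*a``, split floor-left.
* The dilated convolution is implemented as cross-correlation
  ``y(t) = sum_tau W(tau) x(t + a*tau - pad_left)`` (the standard
  deep-learning orientation of the written form ``sum_tau k(tau) x(t - a*tau)``;
  kernels are learned, so the orientation is a private detail).
* The max-abs normalization ``y/(max|y| + 1e-5)`` takes the maximum per
  batch item and channel over the time axis of the current chunk during
  training, and a frozen running statistic at inference so that inference
  is purely convolutional (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1D",
    "SeparableConv1D",
    "ReLU",
    "MaxAbsNorm",
    "Dense",
    "STFTFrontend",
    "init_stft_kernels",
    "upsample_repeat",
    "softmax",
]

EPSILON = 1e-5  # normalization stabilizer
LOG_FLOOR = 1e-10  # magnitude floor inside the frontend log


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def upsample_repeat(y: np.ndarray, factor: int) -> np.ndarray:
    """Repeat each frame ``factor`` times along the time axis."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return y
    return np.repeat(y, factor, axis=-2)


def init_stft_kernels(T: int, pairs: int, rate: float | None = None):
    """DFT-initialized cos/sin banks of shape [T, pairs].

    Pair ``f`` is ``cos(2*pi*f*tau/T)`` and ``-sin(2*pi*f*tau/T)`` for
    ``tau = 0..T-1`` — the real and imaginary parts of the length-``T``
    DFT kernels for the first ``pairs`` non-negative frequency bins.
    Returns (cos_bank, sin_bank, frequencies); frequencies are in Hz when
    ``rate`` is given, else in cycles/sample.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if pairs > T // 2 + 1:
        raise ValueError("pairs must be <= T/2 + 1")
    tau = np.arange(T)[:, None]
    f = np.arange(pairs)[None, :]
    cos_bank = np.cos(2 * np.pi * f * tau / T)
    sin_bank = -np.sin(2 * np.pi * f * tau / T)
    freqs = np.arange(pairs) / T * (rate if rate is not None else 1.0)
    return cos_bank, sin_bank, freqs


def _same_pad(k: int, dilation: int) -> tuple[int, int]:
    total = (k - 1) * dilation
    left = total // 2
    return left, total - left


class Conv1D:
    """Full dilated convolution over time and channels."""

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int = 1, rng=None,
                 weight_scale: float | None = None):
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / (k * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.k, self.dilation = k, dilation
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, d = self.k, self.dilation
        left, right = _same_pad(k, d)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        Tlen = x.shape[1]
        y = np.zeros((x.shape[0], Tlen, self.W.v.shape[2]))
        for tau in range(k):
            y += xp[:, tau * d : tau * d + Tlen, :] @ self.W.v[tau]
        y += self.b.v
        if train:
            self._cache = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._cache
        k, d = self.k, self.dilation
        left, _ = _same_pad(k, d)
        Tlen = dy.shape[1]
        dxp = np.zeros_like(xp)
        for tau in range(k):
            sl = slice(tau * d, tau * d + Tlen)
            dxp[:, sl, :] += dy @ self.W.v[tau].T
            self.W.g[tau] += np.einsum("bti,bto->io", xp[:, sl, :], dy)
        self.b.g += dy.sum(axis=(0, 1))
        return dxp[:, left : left + Tlen, :]


class SeparableConv1D:
    """Time-channel separable convolution: one shared temporal kernel applied
    to every input channel, followed by ``c_out`` across-channel mixes.
    Parameter count (ex. bias): ``k + c_out * c_in``."""

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int = 1, rng=None):
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.Wt = Param(rng.normal(0.0, np.sqrt(2.0 / k), size=(k,)))
        self.Wc = Param(rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.k, self.dilation = k, dilation
        self._cache = None

    def params(self):
        return [self.Wt, self.Wc, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, d = self.k, self.dilation
        left, right = _same_pad(k, d)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        Tlen = x.shape[1]
        yd = np.zeros_like(x)
        for tau in range(k):
            yd += self.Wt.v[tau] * xp[:, tau * d : tau * d + Tlen, :]
        y = yd @ self.Wc.v + self.b.v
        if train:
            self._cache = (xp, yd)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, yd = self._cache
        k, d = self.k, self.dilation
        left, _ = _same_pad(k, d)
        Tlen = dy.shape[1]
        self.Wc.g += np.einsum("bti,bto->io", yd, dy)
        self.b.g += dy.sum(axis=(0, 1))
        dyd = dy @ self.Wc.v.T
        dxp = np.zeros_like(xp)
        for tau in range(k):
            sl = slice(tau * d, tau * d + Tlen)
            self.Wt.g[tau] += np.sum(xp[:, sl, :] * dyd)
            dxp[:, sl, :] += self.Wt.v[tau] * dyd
        return dxp[:, left : left + Tlen, :]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxAbsNorm:
    """Rescale to max absolute value close to 1: ``y = x/(max|x| + 1e-5)``.

    Training: the max is taken per (batch item, channel) over the chunk's
    time axis, and an exponential moving average of the per-channel max is
    tracked.  Inference: the frozen running statistic is used, which keeps
    the network translation-covariant and chunk-size independent.
    """

    def __init__(self, channels: int, momentum: float = 0.1):
        self.running = np.ones(channels)
        self.momentum = momentum
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            s = np.max(np.abs(x), axis=1, keepdims=True) + EPSILON  # [B,1,C]
            self.running = (1 - self.momentum) * self.running + self.momentum * np.mean(
                s[:, 0, :] - EPSILON, axis=0
            )
            y = x / s
            self._cache = (x, s, y)
            return y
        return x / (self.running[None, None, :] + EPSILON)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, y = self._cache
        dx = dy / s
        # gradient through the max: s depends on x at the argmax sample
        ds = -np.sum(dy * y, axis=1, keepdims=True) / s  # [B,1,C]
        idx = np.argmax(np.abs(x), axis=1)[:, None, :]  # [B,1,C]
        sign = np.sign(np.take_along_axis(x, idx, axis=1))
        np.put_along_axis(
            dx, idx, np.take_along_axis(dx, idx, axis=1) + ds * sign, axis=1
        )
        return dx


class Dense:
    """Per-sample affine map (1x1 convolution over time)."""

    def __init__(self, c_in: int, c_out: int, rng=None, weight_scale: float | None = None):
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        scale = weight_scale if weight_scale is not None else np.sqrt(1.0 / c_in)
        self.W = Param(rng.normal(0.0, scale, size=(c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W.v + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.g += np.einsum("bti,bto->io", x, dy)
        self.b.g += dy.sum(axis=(0, 1))
        return dy @ self.W.v.T


class STFTFrontend:
    """Trainable short-time Fourier frontend.

    Two strided convolution banks (initialized with the real and imaginary
    parts of DFT kernels) produce, per frame ``i`` and filter ``f``,
    ``y(i, f) = log10(max(sqrt(re^2 + im^2), 1e-10))`` — the log magnitude
    of the (trainable) cos/sin projections of the window starting at
    ``i * s``.  The stride downsamples the input by a factor ``s``; the
    input is right-padded with ``T - s`` zeros so the frame count is exactly
    ``len(x) / s``.  ``power=True`` switches to ``log10(re^2 + im^2)``.
    """

    def __init__(self, T: int, pairs: int, stride: int, rate: float | None = None,
                 power: bool = False):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if T % stride != 0:
            raise ValueError("T must be a multiple of the stride")
        cos_bank, sin_bank, freqs = init_stft_kernels(T, pairs, rate)
        self.cos = Param(cos_bank)
        self.sin = Param(sin_bank)
        self.T, self.stride, self.frequencies, self.power = T, stride, freqs, power
        self._cache = None

    def params(self):
        return [self.cos, self.sin]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # x: [B, time, 1]
        if x.shape[-1] != 1:
            raise ValueError("STFT frontend expects single-channel input")
        B, n, _ = x.shape
        s, T = self.stride, self.T
        if n % s != 0:
            raise ValueError("input length must be a multiple of the stride")
        xp = np.pad(x[:, :, 0], ((0, 0), (0, T - s)))
        win = np.lib.stride_tricks.sliding_window_view(xp, T, axis=1)[:, ::s]  # [B,F,T]
        re = win @ self.cos.v
        im = win @ self.sin.v
        if self.power:
            mag = re**2 + im**2
        else:
            mag = np.sqrt(re**2 + im**2)
        clipped = np.maximum(mag, LOG_FLOOR)
        y = np.log10(clipped)
        if train:
            self._cache = (win, re, im, mag, clipped)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win, re, im, mag, clipped = self._cache
        active = mag > LOG_FLOOR
        dmag = np.where(active, dy / (clipped * np.log(10.0)), 0.0)
        if self.power:
            dre = dmag * 2 * re
            dim = dmag * 2 * im
        else:
            safe = np.maximum(mag, LOG_FLOOR)
            dre = dmag * re / safe
            dim = dmag * im / safe
        self.cos.g += np.einsum("bft,bfp->tp", win, dre)
        self.sin.g += np.einsum("bft,bfp->tp", win, dim)
        dwin = dre @ self.cos.v.T + dim @ self.sin.v.T  # [B, F, T]
        B, F, T = dwin.shape
        s = self.stride
        dxp = np.zeros((B, F * s + (T - s)))
        for q in range(T // s):
            dxp[:, q * s : q * s + F * s] += dwin[:, :, q * s : (q + 1) * s].reshape(B, F * s)
        return dxp[:, : F * s, None]
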