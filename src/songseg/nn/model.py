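"""The sequence-labeling network.

Architecture: optional trainable STFT frontend (downsampling by its stride)
-> a stack of TCN blocks, each a stack of five residual blocks whose
dilation doubles from 1 to 16 -> elementwise sum of every residual block's
skip output -> a single dense layer with softmax over the song classes
(plus 'no song') -> repeat-upsampling back to the audio rate when the
frontend downsampled.

Each residual block is: dilated convolution (full or time-channel
separable) -> rectifier -> max-abs normalization -> output ``z`` routed both
to the skip sum and to the residual addition ``o = x + z`` (with a 1x1
projection of ``x`` when channel widths differ).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from ..config import NetworkConfig
from .layers import (
    Conv1D,
    Dense,
    MaxAbsNorm,
    ReLU,
    SeparableConv1D,
    STFTFrontend,
    softmax,
    upsample_repeat,
)

__all__ = ["ResidualBlock", "Network", "build_network", "receptive_field", "trim_margin"]


class ResidualBlock:
    def __init__(self, c_in: int, c_out: int, k: int, dilation: int,
                 separable: bool, rng):
        conv_cls = SeparableConv1D if separable else Conv1D
        self.conv = conv_cls(c_in, c_out, k, dilation, rng=rng)
        self.relu = ReLU()
        self.norm = MaxAbsNorm(c_out)
        self.proj = Dense(c_in, c_out, rng=rng) if c_in != c_out else None
        self._cache = None

    def params(self):
        ps = self.conv.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train=False):
        z = self.norm.forward(self.relu.forward(self.conv.forward(x, train), train), train)
        res = self.proj.forward(x, train) if self.proj is not None else x
        return res + z, z

    def backward(self, do, dz):
        """do: grad wrt residual output; dz: grad wrt skip output."""
        dz_total = do + dz
        dx = self.conv.backward(self.relu.backward(self.norm.backward(dz_total)))
        if self.proj is not None:
            dx = dx + self.proj.backward(do)
        else:
            dx = dx + do
        return dx


class Network:
    """Forward/backward network over ``[batch, time, channels]`` audio."""

    def __init__(self, config: NetworkConfig, rng=None):
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.config = config
        self.frontend = None
        c_in = config.channels
        if config.use_stft:
            self.frontend = STFTFrontend(
                config.stft_duration_T, config.stft_pairs, config.stft_stride_s,
                rate=config.rate,
            )
            c_in = config.stft_pairs
        self.blocks: list[ResidualBlock] = []
        width = config.kernel_count
        for stack in range(config.tcn_blocks):
            separable = stack in config.separable_blocks
            for pos in range(config.residual_blocks_per_tcn):
                dilation = config.dilation_base**pos
                self.blocks.append(
                    ResidualBlock(c_in, width, config.kernel_size, dilation, separable, rng)
                )
                c_in = width
        self.head = Dense(width, config.n_classes, rng=rng)

    # ------------------------------------------------------------------
    def params(self):
        ps = list(self.frontend.params()) if self.frontend is not None else []
        for b in self.blocks:
            ps += b.params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    # ------------------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-softmax class scores at the (possibly downsampled) frame rate."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[-1] != self.config.channels:
            raise ValueError(
                f"expected {self.config.channels} channel(s), got {x.shape[-1]}"
            )
        h = self.frontend.forward(x, train) if self.frontend is not None else x
        skip = None
        for b in self.blocks:
            h, z = b.forward(h, train)
            skip = z if skip is None else skip + z
        return self.head.forward(skip, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-sample class probabilities, upsampled back to the audio rate."""
        probs = softmax(self.forward_logits(x, train))
        if self.frontend is not None:
            probs = upsample_repeat(probs, self.config.stft_stride_s)
        return probs

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop from grad wrt the frame-rate logits; accumulates grads."""
        dskip = self.head.backward(dlogits)
        do = np.zeros_like(dskip)
        for b in reversed(self.blocks):
            do = b.backward(do, dskip)
        if self.frontend is not None:
            self.frontend.backward(do)

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    # ------------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.v for i, p in enumerate(self.params())}
        for i, b in enumerate(self.blocks):
            state[f"norm{i}"] = b.norm.running
        return state

    def save(self, prefix) -> None:
        """Write ``<prefix>.yaml`` (config) and ``<prefix>.npz`` (weights)."""
        prefix = Path(prefix)
        self.config.save(prefix.with_suffix(".yaml"))
        np.savez(prefix.with_suffix(".npz"), **self.state_arrays())

    @classmethod
    def load(cls, prefix) -> "Network":
        prefix = Path(prefix)
        config = NetworkConfig.load(prefix.with_suffix(".yaml"))
        net = cls(config, rng=0)
        with np.load(prefix.with_suffix(".npz")) as data:
            for i, p in enumerate(net.params()):
                arr = data[f"p{i}"]
                if arr.shape != p.v.shape:
                    raise ValueError("checkpoint does not match configuration")
                p.v[...] = arr
            for i, b in enumerate(net.blocks):
                b.norm.running[...] = data[f"norm{i}"]
        return net


def build_network(config: NetworkConfig, rng=None) -> Network:
    """Construct a randomly initialized network from a configuration."""
    return Network(config, rng=rng)


def receptive_field(config: NetworkConfig) -> int:
    """Receptive field in input samples.

    Over the TCN body the span is ``1 + sum (kernel_size - 1) * dilation``
    frames; with a frontend this is carried through the stride and extended
    by the analysis window.
    """
    rf = 1
    for _ in range(config.tcn_blocks):
        for pos in range(config.residual_blocks_per_tcn):
            rf += (config.kernel_size - 1) * config.dilation_base**pos
    if config.use_stft:
        rf = rf * config.stft_stride_s + (config.stft_duration_T - config.stft_stride_s)
    return rf


def trim_margin(config: NetworkConfig) -> int:
    """Samples contaminated by chunk edges on each side (half receptive field
    with centered padding), rounded up to a frontend-stride multiple."""
    rf = 0
    for _ in range(config.tcn_blocks):
        for pos in range(config.residual_blocks_per_tcn):
            rf += (config.kernel_size - 1) * config.dilation_base**pos
    half = (rf + 1) // 2 + 1
    if config.use_stft:
        s = config.stft_stride_s
        half = half * s + config.stft_duration_T  # window looks T samples ahead
        half = -(-half // s) * s
    return half
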