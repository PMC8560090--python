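"""Network fitting: chunk sampling, categorical cross-entropy, Adam, early
stopping on the validation loss with best-weight restoration.

Training draws fixed-length chunks with random (seeded) offsets from the
training intervals so chunk boundaries do not align with annotation
boundaries; validation chunks tile their intervals deterministically.
For networks with an STFT frontend the full-rate targets are average-pooled
to the frame rate, which is mathematically identical to scoring the
repeat-upsampled output against the full-rate targets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig
from .io import AnnotationTable, Recording
from .nn import Adam, Network, softmax
from .splits import DatasetSplit
from .targets import DEFAULT_EVENT_SIGMA_MS, DEFAULT_SYLLABLE_GAP_MS, encode_targets

__all__ = ["TrainConfig", "train", "cross_entropy"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 400
    patience: int = 20
    event_sigma_ms: float = DEFAULT_EVENT_SIGMA_MS
    syllable_gap_ms: float = DEFAULT_SYLLABLE_GAP_MS
    seed: int = 0
    chunks_per_epoch: int | None = None  # default: train samples // chunk
    class_weights: np.ndarray | None = None  # optional inverse-frequency weights

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def cross_entropy(probs: np.ndarray, targets: np.ndarray,
                  weights: np.ndarray | None = None) -> float:
    """Mean categorical cross-entropy over all samples."""
    logp = np.log(np.clip(probs, 1e-12, None))
    per_sample = -(targets * logp)
    if weights is not None:
        per_sample = per_sample * weights
    return float(per_sample.sum(axis=-1).mean())


def _pool_targets(y: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return y
    n = (y.shape[0] // factor) * factor
    return y[:n].reshape(-1, factor, y.shape[1]).mean(axis=1)


def _gather_chunks(intervals, chunk: int):
    """Intervals long enough to hold one chunk, with their usable lengths."""
    usable = [(rid, a, b) for rid, a, b in intervals if b - a >= chunk]
    if not usable:
        raise ValueError("no interval is long enough for one chunk")
    return usable


def _tile_starts(intervals, chunk: int):
    starts = []
    for rid, a, b in intervals:
        for s in range(a, b - chunk + 1, chunk):
            starts.append((rid, s))
    return starts


def train(
    network: Network,
    recordings: dict[str, Recording],
    annotations: dict[str, "AnnotationTable"],
    split: DatasetSplit,
    config: TrainConfig | None = None,
) -> tuple[Network, TrainHistory]:
    """Fit ``network`` on the training split; returns (network, history).

    Early stopping: training ends after ``max_epochs`` or when the
    validation loss has not improved for ``patience`` consecutive epochs;
    the best-validation-loss weights are restored.
    """
    config = config or TrainConfig()
    cfg: NetworkConfig = network.config
    chunk = cfg.chunk_samples
    factor = cfg.stft_stride_s if cfg.use_stft else 1
    rng = np.random.default_rng(config.seed)

    targets: dict[str, np.ndarray] = {}
    for rid, rec in recordings.items():
        tm = encode_targets(
            annotations[rid], cfg.rate, cfg.classes, rec.n_samples,
            event_sigma_ms=config.event_sigma_ms,
            syllable_gap_ms=config.syllable_gap_ms,
        )
        targets[rid] = tm.values

    train_ivs = _gather_chunks(split.train, chunk)
    if not train_ivs:
        raise ValueError("empty training split")
    lengths = np.array([b - a - chunk + 1 for _, a, b in train_ivs], dtype=float)
    n_train_samples = sum(b - a for _, a, b in train_ivs)
    n_chunks = config.chunks_per_epoch or max(n_train_samples // chunk, 1)
    val_starts = _tile_starts(split.val, chunk) if split.val else []

    optimizer = Adam(network.params(), lr=config.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_state = None
    since_best = 0

    def batch_arrays(items):
        xs = np.stack([recordings[rid].samples[s : s + chunk] for rid, s in items])
        ys = np.stack([_pool_targets(targets[rid][s : s + chunk], factor) for rid, s in items])
        return xs, ys

    def evaluate(starts) -> float:
        if not starts:
            return np.nan
        losses = []
        for i in range(0, len(starts), config.batch_size):
            xs, ys = batch_arrays(starts[i : i + config.batch_size])
            probs = softmax(network.forward_logits(xs, train=False))
            losses.append(cross_entropy(probs, ys, config.class_weights))
        return float(np.mean(losses))

    for epoch in range(config.max_epochs):
        # seeded random chunk offsets, weighted by interval length
        iv_idx = rng.choice(len(train_ivs), size=n_chunks, p=lengths / lengths.sum())
        items = []
        for i in iv_idx:
            rid, a, b = train_ivs[i]
            items.append((rid, int(rng.integers(a, b - chunk + 1))))
        epoch_losses = []
        for i in range(0, len(items), config.batch_size):
            xs, ys = batch_arrays(items[i : i + config.batch_size])
            logits = network.forward_logits(xs, train=True)
            probs = softmax(logits)
            loss = cross_entropy(probs, ys, config.class_weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            epoch_losses.append(loss)
            n = probs.shape[0] * probs.shape[1]
            if config.class_weights is None:
                dlogits = (probs - ys) / n
            else:
                w = np.asarray(config.class_weights)
                wy = ys * w
                dlogits = (probs * wy.sum(axis=-1, keepdims=True) - wy) / n
            network.zero_grad()
            network.backward(dlogits)
            optimizer.step()
        history.train_loss.append(float(np.mean(epoch_losses)))

        val = evaluate(val_starts)
        history.val_loss.append(val)
        monitor = val if np.isfinite(val) else history.train_loss[-1]
        if monitor < best_val - 1e-12:
            best_val = monitor
            best_state = copy.deepcopy(network.state_arrays())
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stopped_epoch = epoch
                break

    if best_state is not None:
        for key, arr in best_state.items():
            if key.startswith("p"):
                network.params()[int(key[1:])].v[...] = arr
            else:
                network.blocks[int(key[4:])].norm.running[...] = arr
    return network, history
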