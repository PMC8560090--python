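"""Sample-wise training targets from annotation tables.

Segments become binary vectors (1 on ``[start, stop)``); point events become
unit-peak Gaussian bumps (default sigma 1.6 ms, truncated at +-4 sigma) that
encode uncertainty in the annotated time; syllable-kind classes get short
'no song' gaps (default 6.25 ms; 200 samples at 32 kHz) carved between
adjacent syllables so on/offsets are unambiguous after inference.  The
'no song' row completes every sample to 1; where song rows would exceed 1
(e.g. a bump overlapping a segment) the song rows are proportionally
renormalized first, so rows always sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NO_SONG, ClassDef
from .io import AnnotationTable, seconds_to_sample

__all__ = ["TargetMatrix", "encode_targets"]

DEFAULT_EVENT_SIGMA_MS = 1.6
DEFAULT_SYLLABLE_GAP_MS = 6.25
BUMP_TRUNCATION_SIGMAS = 4.0


@dataclass
class TargetMatrix:
    """``[time x classes]`` probabilities; song classes first, no-song last."""

    values: np.ndarray
    class_names: list[str]
    rate: float


def _check_no_overlap(table: AnnotationTable) -> None:
    segs = table.segments()
    iv = sorted(zip(segs["start_seconds"], segs["stop_seconds"], segs["name"]))
    offenders = []
    for a, b in zip(iv, iv[1:]):
        if b[0] < a[1] - 1e-12:
            offenders.append((a, b))
    if offenders:
        lines = "; ".join(
            f"{a[2]} [{a[0]:.4f},{a[1]:.4f}) overlaps {b[2]} [{b[0]:.4f},{b[1]:.4f})"
            for a, b in offenders
        )
        raise ValueError(f"overlapping annotations: {lines}")


def encode_targets(
    annotations: AnnotationTable,
    rate: float,
    classes: list[ClassDef],
    n_samples: int,
    event_sigma_ms: float = DEFAULT_EVENT_SIGMA_MS,
    syllable_gap_ms: float = DEFAULT_SYLLABLE_GAP_MS,
) -> TargetMatrix:
    """Encode an annotation table as a ``[n_samples x (classes + 1)]`` target."""
    _check_no_overlap(annotations)
    names = [c.name for c in classes]
    kinds = {c.name: c.kind for c in classes}
    index = {n: i for i, n in enumerate(names)}
    song = np.zeros((n_samples, len(names)))

    sigma = event_sigma_ms / 1000.0 * rate  # samples
    half = int(np.ceil(BUMP_TRUNCATION_SIGMAS * sigma))

    for name, start, stop in zip(annotations.names, annotations.starts, annotations.stops):
        if name not in index:
            raise KeyError(f"annotation type {name!r} not in class vocabulary {names}")
        col = index[name]
        if kinds[name] == "event":
            center = int(seconds_to_sample(start, rate))
            lo, hi = max(center - half, 0), min(center + half + 1, n_samples)
            if hi <= lo:
                continue
            i = np.arange(lo, hi)
            bump = np.exp(-((i - center) ** 2) / (2 * sigma**2))
            song[lo:hi, col] = np.maximum(song[lo:hi, col], bump)
        else:
            a = int(seconds_to_sample(start, rate))
            b = int(seconds_to_sample(stop, rate))
            song[max(a, 0) : min(b, n_samples), col] = 1.0

    # carve inter-syllable gaps for syllable-kind classes
    syll_names = {n for n in names if kinds[n] == "syllable"}
    if syll_names:
        gap = int(round(syllable_gap_ms / 1000.0 * rate))
        segs = annotations.segments()
        segs = segs[segs["name"].isin(syll_names)].sort_values("start_seconds")
        starts = seconds_to_sample(segs["start_seconds"].to_numpy(), rate)
        stops = seconds_to_sample(segs["stop_seconds"].to_numpy(), rate)
        for prev_stop, next_start in zip(stops[:-1], starts[1:]):
            if next_start - prev_stop < gap:
                mid = (int(prev_stop) + int(next_start)) // 2
                lo = max(mid - gap // 2, 0)
                song[lo : min(lo + gap, n_samples), :] = 0.0

    sums = song.sum(axis=1)
    over = sums > 1.0
    if np.any(over):
        song[over] /= sums[over, None]
        sums = song.sum(axis=1)
    values = np.concatenate([song, np.clip(1.0 - sums, 0.0, None)[:, None]], axis=1)
    return TargetMatrix(values=values, class_names=names + [NO_SONG], rate=rate)
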