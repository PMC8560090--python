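"""Chunked prediction of confidence scores and their conversion into
discrete event times and labeled segments.

Confidences are computed over overlapping chunks whose contaminated margins
(half a receptive field per side, frontend-stride aligned) are discarded, so
the chunked output is identical to processing the whole recording at once.
Event times are local maxima of an event class's confidence above a
threshold, with greedy minimum-distance suppression (defaults: threshold
0.7, 10 ms).  Segments come from the per-sample argmax label track after
gap-filling and minimum-duration smoothing; multi-class syllables are
labeled by majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import NO_SONG
from .io import AnnotationTable, Recording
from .nn import Network, receptive_field, trim_margin

__all__ = [
    "ConfidenceTrack",
    "EventPredictions",
    "SegmentPredictions",
    "predict_confidence",
    "detect_events",
    "label_segments",
    "smooth_segments",
    "majority_vote",
    "predictions_to_table",
]


@dataclass
class ConfidenceTrack:
    """Per-sample, per-class probabilities aligned to the audio."""

    values: np.ndarray  # [time, classes]
    rate: float
    class_names: list[str]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.class_names.index(name)]


@dataclass
class EventPredictions:
    name: str
    times: np.ndarray  # seconds, strictly increasing
    confidences: np.ndarray


@dataclass
class SegmentPredictions:
    """Labeled segments plus the underlying per-sample label track."""

    segments: list[tuple[str, float, float]]  # (label, onset_s, offset_s)
    labels: np.ndarray  # per-sample class indices (smoothed)
    rate: float
    class_names: list[str] = field(default_factory=list)


def predict_confidence(
    network: Network,
    recording: Recording,
    chunk_samples: int | None = None,
    batch_size: int = 8,
) -> ConfidenceTrack:
    """Compute the full-recording confidence track with chunked inference.

    The chunk length defaults to the configured chunk but is enlarged when
    needed so that after trimming both contaminated margins a positive hop
    remains (the preset chunk lengths can be shorter than a receptive
    field; chunk length does not change any parameter).
    """
    cfg = network.config
    if abs(recording.rate - cfg.rate) > 1e-6:
        raise ValueError(
            f"recording rate {recording.rate} does not match model rate {cfg.rate}"
        )
    n = recording.n_samples
    if n < receptive_field(cfg):
        raise ValueError("recording shorter than one receptive field")
    s = cfg.stft_stride_s if cfg.use_stft else 1
    trim = trim_margin(cfg)
    if chunk_samples is None:
        # leave a generous hop so overlapping margins stay a small overhead
        chunk = max(cfg.chunk_samples, 2 * trim + 65536)
    else:
        chunk = max(chunk_samples, 2 * trim + 8 * s)
    chunk = -(-chunk // s) * s  # round up to a stride multiple
    n_pad = -(-n // s) * s

    samples = recording.samples
    if n_pad > n:
        samples = np.pad(samples, ((0, n_pad - n), (0, 0)))

    if n_pad <= chunk:
        starts = [0]
        chunk = n_pad
    else:
        hop = chunk - 2 * trim
        starts = list(range(0, n_pad - chunk, hop))
        starts.append(n_pad - chunk)

    out = np.empty((n_pad, cfg.n_classes))
    cursor = 0
    for i in range(0, len(starts), batch_size):
        batch_starts = starts[i : i + batch_size]
        xs = np.stack([samples[st : st + chunk] for st in batch_starts])
        probs = network.forward(xs, train=False)
        for st, p in zip(batch_starts, probs):
            lo = 0 if st == 0 else st + trim
            hi = n_pad if st == starts[-1] else st + chunk - trim
            lo = max(lo, cursor)
            out[lo:hi] = p[lo - st : hi - st]
            cursor = hi
    assert cursor == n_pad, "chunk assembly did not cover the recording"
    return ConfidenceTrack(values=out[:n], rate=cfg.rate, class_names=cfg.class_names)


def detect_events(
    track: ConfidenceTrack,
    name: str,
    threshold: float = 0.7,
    min_distance_s: float = 0.010,
    interpolate: bool = False,
) -> EventPredictions:
    """Confidence local maxima above ``threshold``, greedily suppressed so
    surviving peaks are >= ``min_distance_s`` apart (higher peaks kept
    first).  Plateaus (from repeat-upsampling) resolve to their first
    sample; ``interpolate`` refines times by quadratic peak interpolation."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    y = track.column(name)
    idx, props = find_peaks(y, height=threshold, plateau_size=1)
    lefts = props["left_edges"]
    heights = props["peak_heights"]
    order = np.argsort(-heights, kind="stable")
    min_dist = min_distance_s * track.rate
    kept: list[int] = []
    for j in order:
        if all(abs(lefts[j] - lefts[k]) >= min_dist for k in kept):
            kept.append(j)
    kept.sort(key=lambda j: lefts[j])
    times = lefts[kept].astype(float)
    if interpolate:
        for m, j in enumerate(kept):
            i = idx[j]
            if 0 < i < len(y) - 1:
                denom = y[i - 1] - 2 * y[i] + y[i + 1]
                if denom < 0:
                    times[m] = lefts[j] + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return EventPredictions(
        name=name, times=times / track.rate, confidences=heights[kept]
    )


def label_segments(track: ConfidenceTrack) -> np.ndarray:
    """Per-sample argmax labels; ties break toward the lowest class index."""
    return np.argmax(track.values, axis=1)


def _runs(labels: np.ndarray):
    """Yield (label, start, stop) for maximal constant runs (half-open)."""
    if len(labels) == 0:
        return
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield int(labels[a]), int(a), int(b)


def _segment_label(labels: np.ndarray, a: int, b: int, no_song: int) -> int:
    """Mode of the song labels in [a, b); ties -> earliest-occurring label."""
    window = labels[a:b]
    song = window[window != no_song]
    if len(song) == 0:
        return no_song
    vals, counts = np.unique(song, return_counts=True)
    best = counts.max()
    candidates = set(vals[counts == best])
    for lab in window:
        if lab in candidates:
            return int(lab)
    return int(vals[0])  # unreachable


def smooth_segments(
    labels: np.ndarray,
    rate: float,
    class_names: list[str],
    fill_gap_s: float = 0.020,
    min_duration_s: float = 0.020,
) -> SegmentPredictions:
    """Smooth a label track and emit segments at no-song <-> song changes.

    Step 1 fills 'no song' gaps shorter than ``fill_gap_s`` between runs of
    the same label; step 2 removes song runs shorter than
    ``min_duration_s``.  Order matters and follows that description; the two
    steps are then iterated until the track is stable (removal can expose a
    new fillable gap), which makes the operation idempotent without
    changing the first fill-then-remove pass.
    """
    if fill_gap_s < 0 or min_duration_s < 0:
        raise ValueError("fill_gap_s and min_duration_s must be >= 0")
    no_song = len(class_names) - 1
    labels = np.asarray(labels).copy()
    fill = fill_gap_s * rate
    min_dur = min_duration_s * rate
    while True:
        before = labels.copy()
        runs = list(_runs(labels))
        for i in range(1, len(runs) - 1):
            lab, a, b = runs[i]
            if lab == no_song and (b - a) < fill:
                prev_lab = runs[i - 1][0]
                next_lab = runs[i + 1][0]
                if prev_lab == next_lab and prev_lab != no_song:
                    labels[a:b] = prev_lab
        for lab, a, b in list(_runs(labels)):
            if lab != no_song and (b - a) < min_dur:
                labels[a:b] = no_song
        if np.array_equal(labels, before):
            break

    segments: list[tuple[str, float, float]] = []
    in_song = labels != no_song
    for val, a, b in _runs(in_song.astype(int)):
        if val:
            lab = _segment_label(labels, a, b, no_song)
            segments.append((class_names[lab], a / rate, b / rate))
    return SegmentPredictions(
        segments=segments, labels=labels, rate=rate, class_names=class_names
    )


def majority_vote(raw_labels: np.ndarray, segments: SegmentPredictions) -> SegmentPredictions:
    """Re-label each detected segment with the mode of the raw per-sample
    song labels it covers (ties -> earliest-occurring label)."""
    no_song = len(segments.class_names) - 1
    relabeled = []
    for _, on, off in segments.segments:
        a = int(round(on * segments.rate))
        b = int(round(off * segments.rate))
        lab = _segment_label(np.asarray(raw_labels), a, b, no_song)
        name = segments.class_names[lab] if lab != no_song else segments.class_names[no_song]
        relabeled.append((name, on, off))
    return SegmentPredictions(
        segments=relabeled,
        labels=segments.labels,
        rate=segments.rate,
        class_names=segments.class_names,
    )


def predictions_to_table(
    events: list[EventPredictions] | None = None,
    segments: SegmentPredictions | None = None,
) -> AnnotationTable:
    """Collect event and segment predictions into one annotation table."""
    rows: list[tuple[str, float, float]] = []
    for ev in events or []:
        rows += [(ev.name, t, t) for t in ev.times]
    if segments is not None:
        rows += [(name, on, off) for name, on, off in segments.segments if name != NO_SONG]
    return AnnotationTable.from_rows(rows)
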