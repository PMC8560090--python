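"""Evaluation metrics: tolerance-matched event detection, pseudo true
negatives, precision/recall/F1/accuracy, temporal precision, sample- and
syllable-wise confusion, and the sequence error rate.

Event matching pairs each prediction with a true event within a tolerance;
when several predictions share a nearest true event only the closest one is
a true positive and the rest are re-matched to remaining true events or
counted as false positives.  This is implemented as a greedy pass over
candidate pairs in ascending distance, which realises exactly that rule and
coincides with optimal bipartite matching whenever events are separated by
more than twice the tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalCounts",
    "MetricReport",
    "match_events",
    "pseudo_true_negatives",
    "event_metrics",
    "temporal_error",
    "segment_confusion",
    "sequence_error_rate",
]


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    matched_pairs: list[tuple[float, float]] = field(default_factory=list)  # (true, pred)


@dataclass
class MetricReport:
    precision: float = np.nan
    recall: float = np.nan
    f1: float = np.nan
    accuracy: float = np.nan
    temporal_error_median: float = np.nan
    sequence_error_rate: float = np.nan
    confusion: np.ndarray | None = None


def match_events(
    true_times: np.ndarray, predicted_times: np.ndarray, tolerance: float
) -> EvalCounts:
    """Greedy ascending-distance matching of predictions to true events.

    Each true event acquires at most one true-positive prediction;
    unmatched predictions are false positives, unmatched true events false
    negatives.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    true_times = np.sort(np.asarray(true_times, dtype=float))
    predicted_times = np.sort(np.asarray(predicted_times, dtype=float))
    pairs = []
    for j, p in enumerate(predicted_times):
        lo = np.searchsorted(true_times, p - tolerance)
        hi = np.searchsorted(true_times, p + tolerance, side="right")
        for i in range(lo, hi):
            pairs.append((abs(true_times[i] - p), i, j))
    pairs.sort()
    true_used = np.zeros(len(true_times), dtype=bool)
    pred_used = np.zeros(len(predicted_times), dtype=bool)
    matched = []
    for _, i, j in pairs:
        if not true_used[i] and not pred_used[j]:
            true_used[i] = pred_used[j] = True
            matched.append((float(true_times[i]), float(predicted_times[j])))
    tp = len(matched)
    return EvalCounts(
        tp=tp,
        fp=len(predicted_times) - tp,
        fn=len(true_times) - tp,
        matched_pairs=matched,
    )


def pseudo_true_negatives(duration: float, tolerance: float, n_true: int) -> int:
    """Number of 2x-tolerance windows fitting the recording minus the true
    events, clipped at zero; used only to complete confusion matrices."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return max(int(duration / (2 * tolerance)) - n_true, 0)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0, returning 0", stacklevel=3)
        return 0.0
    return num / den


def event_metrics(counts: EvalCounts) -> MetricReport:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); accuracy uses the
    (pseudo) true negatives when present in ``counts``."""
    p = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    r = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_div(2 * p * r, p + r, "f1")
    total = counts.tp + counts.tn + counts.fp + counts.fn
    acc = _safe_div(counts.tp + counts.tn, total, "accuracy")
    med = temporal_error(counts.matched_pairs) if counts.matched_pairs else np.nan
    return MetricReport(precision=p, recall=r, f1=f1, accuracy=acc,
                        temporal_error_median=med)


def temporal_error(matched_pairs) -> float:
    """Median absolute distance between matched true and predicted times."""
    if len(matched_pairs) == 0:
        return np.nan
    arr = np.asarray(matched_pairs, dtype=float)
    return float(np.median(np.abs(arr[:, 0] - arr[:, 1])))


def _mode(values: np.ndarray) -> int:
    vals, counts = np.unique(values, return_counts=True)
    return int(vals[np.argmax(counts)])


def segment_confusion(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    class_names: list[str],
    mode: str = "sample",
    segments: list[tuple[int, int]] | None = None,
    reference: str = "detected",
) -> tuple[np.ndarray, MetricReport]:
    """Confusion matrix plus summary metrics for segment annotations.

    ``sample`` mode counts per-sample (true, predicted) label pairs.
    ``syllable`` mode compares, for each detected (or true, per
    ``reference``) segment given as (start, stop) sample pairs, the mode of
    the true labels against the mode of the predicted labels within it.
    Precision/recall/F1 are micro-averaged over the song classes (the last
    class is 'no song').
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label tracks must have equal length")
    k = len(class_names)
    if true_labels.max(initial=0) >= k or predicted_labels.max(initial=0) >= k:
        raise ValueError("labels outside the class vocabulary")
    conf = np.zeros((k, k), dtype=int)
    if mode == "sample":
        np.add.at(conf, (true_labels, predicted_labels), 1)
    elif mode == "syllable":
        if segments is None:
            raise ValueError("syllable mode requires segments")
        for a, b in segments:
            t = _mode(true_labels[a:b])
            p = _mode(predicted_labels[a:b])
            conf[t, p] += 1
        if reference == "true":
            conf = conf  # segments supplied by caller define the reference
    else:
        raise ValueError(f"unknown mode {mode!r}")

    no_song = k - 1
    song = np.arange(k) != no_song
    tp = int(np.sum(np.diag(conf)[song]))
    fp = int(conf[:, song].sum() - np.sum(np.diag(conf)[song]))
    fn = int(conf[song, :].sum() - np.sum(np.diag(conf)[song]))
    p = _safe_div(tp, tp + fp, "precision")
    r = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * p * r, p + r, "f1")
    acc = _safe_div(int(np.trace(conf)), int(conf.sum()), "accuracy")
    return conf, MetricReport(precision=p, recall=r, f1=f1, accuracy=acc, confusion=conf)


def sequence_error_rate(true_seq, predicted_seq) -> float:
    """Levenshtein edit distance between label sequences, normalized by the
    length of the true sequence."""
    true_seq = list(true_seq)
    predicted_seq = list(predicted_seq)
    if len(true_seq) == 0:
        raise ValueError("true sequence must be non-empty")
    m, n = len(true_seq), len(predicted_seq)
    prev = np.arange(n + 1)
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=int)
        cur[0] = i
        for j in range(1, n + 1):
            cost = 0 if true_seq[i - 1] == predicted_seq[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return float(prev[n]) / m
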