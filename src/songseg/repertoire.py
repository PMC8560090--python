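"""Unsupervised classification of annotated events and segments.

Pipeline: fixed-size features (aligned pulse waveforms, or preprocessed
mel-spectrogram stacks for syllables) -> 2-D manifold embedding (UMAP) ->
clustering (hierarchical density-based by default; k-means for repertoires
without density structure, e.g. mouse USVs) -> entropy-based agreement
scores against manual labels (homogeneity, completeness, v-measure).

Spectrogram preprocessing follows the repertoire-atlas recipe: mel
spectrogram, per-band division by the frequency-specific noise floor (its
median over time), log transform, subtract-threshold-and-clip at zero,
log-resizing of the time axis (new width = round(ln(W) * scaling_factor))
to compress duration differences, zero-padding to the longest item, and
optionally retaining only the 40 bands around each item's peak frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import stft

from .io import Recording

__all__ = [
    "WaveformSet",
    "SpectrogramSet",
    "SpectrogramParams",
    "ClusterResult",
    "preprocess_waveforms",
    "preprocess_spectrograms",
    "mel_filterbank",
    "mel_spectrogram",
    "embed_2d",
    "cluster",
    "cluster_agreement",
]


@dataclass
class WaveformSet:
    """Aligned, unit-norm, sign-adjusted waveforms, one per row."""

    waveforms: np.ndarray  # [n, samples]
    window_ms: float
    times: np.ndarray  # event times that survived extraction


@dataclass
class SpectrogramParams:
    n_mels: int = 64
    n_fft: int = 1024
    hop: int = 128
    scaling_factor: float = 8.0
    threshold: float = 0.0  # on the log scale; 2 for marmosets/birds
    retained_bands: int | None = None  # e.g. 40 for mouse peak alignment
    fmin: float = 0.0
    fmax: float | None = None


@dataclass
class SpectrogramSet:
    spectrograms: np.ndarray  # [n, freq, time]
    labels: np.ndarray | None
    params: SpectrogramParams


@dataclass
class ClusterResult:
    embedding: np.ndarray | None
    labels: np.ndarray  # -1 = unassigned (density method)
    method: str


# ---------------------------------------------------------------------------
# waveform preprocessing (fly pulses / sine snippets)


def preprocess_waveforms(
    recording: Recording, event_times: np.ndarray, window_ms: float = 15.0
) -> WaveformSet:
    """Extract per-event windows, center on peak energy, unit-normalize and
    adjust the sign so the dominant lobe is positive."""
    rate = recording.rate
    half = int(round(window_ms / 2000.0 * rate))
    rows, kept = [], []
    for t in np.asarray(event_times, dtype=float):
        c = int(round(t * rate))
        if c - 2 * half < 0 or c + 2 * half > recording.n_samples:
            warnings.warn(f"event at {t:.4f} s too close to the edge; skipped")
            continue
        wide = recording.samples[c - 2 * half : c + 2 * half]
        energy = np.sum(wide**2, axis=1)
        peak = c - 2 * half + int(np.argmax(energy))
        wav = recording.samples[peak - half : peak + half]
        ch = int(np.argmax(np.sqrt(np.mean(wav**2, axis=0))))
        w = wav[:, ch].astype(float)
        norm = np.linalg.norm(w)
        if norm == 0:
            warnings.warn(f"all-zero window at {t:.4f} s; skipped")
            continue
        w = w / norm
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        rows.append(w)
        kept.append(t)
    return WaveformSet(
        waveforms=np.asarray(rows), window_ms=window_ms, times=np.asarray(kept)
    )


# ---------------------------------------------------------------------------
# mel spectrograms (no external audio-feature dependency)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(rate: float, n_fft: int, n_mels: int, fmin: float = 0.0,
                   fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, [n_mels x (n_fft//2 + 1)]."""
    fmax = fmax if fmax is not None else rate / 2
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.linspace(0, rate / 2, n_fft // 2 + 1)
    fb = np.zeros((n_mels, len(bins)))
    for m in range(n_mels):
        left, center, right = hz_pts[m : m + 3]
        up = (bins - left) / max(center - left, 1e-12)
        down = (right - bins) / max(right - center, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_spectrogram(x: np.ndarray, rate: float, params: SpectrogramParams):
    """Mel power spectrogram; returns (mel [n_mels x frames], frame_times)."""
    f, t, Z = stft(
        x, fs=rate, nperseg=params.n_fft, noverlap=params.n_fft - params.hop,
        boundary="zeros", padded=True,
    )
    power = np.abs(Z) ** 2
    fb = mel_filterbank(rate, params.n_fft, params.n_mels, params.fmin, params.fmax)
    return fb @ power, t


def _log_resize(spec: np.ndarray, scaling: float) -> np.ndarray:
    """Interpolate the time axis onto max(1, round(ln(W) * scaling)) frames."""
    w = spec.shape[1]
    new_w = max(1, int(round(np.log(w) * scaling)))
    if new_w == w:
        return spec
    src = np.linspace(0.0, w - 1.0, new_w)
    out = np.empty((spec.shape[0], new_w))
    for i in range(spec.shape[0]):
        out[i] = np.interp(src, np.arange(w), spec[i])
    return out


def preprocess_spectrograms(
    recording: Recording,
    segments,
    params: SpectrogramParams | None = None,
    labels=None,
) -> SpectrogramSet:
    """Per-segment preprocessed mel spectrograms (see module docstring).

    ``segments`` is an iterable of (onset_s, offset_s).
    """
    params = params or SpectrogramParams()
    mel, frame_times = mel_spectrogram(recording.samples[:, 0], recording.rate, params)
    floor = np.median(mel, axis=1, keepdims=True)
    floor = np.where(floor <= 0, np.finfo(float).tiny, floor)
    normed = mel / floor
    logged = np.log(np.clip(normed, np.finfo(float).tiny, None))
    feat = np.clip(logged - params.threshold, 0.0, None)

    items = []
    for on, off in segments:
        sel = (frame_times >= on) & (frame_times < off)
        if not np.any(sel):
            raise ValueError(f"segment [{on:.3f}, {off:.3f}) shorter than one frame")
        items.append(_log_resize(feat[:, sel], params.scaling_factor))

    width = max(s.shape[1] for s in items)
    stack = np.zeros((len(items), params.n_mels, width))
    for i, s in enumerate(items):
        stack[i, :, : s.shape[1]] = s

    if params.retained_bands is not None:
        nb = params.retained_bands
        out = np.zeros((len(items), nb, width))
        for i in range(len(items)):
            peak = int(np.argmax(stack[i].mean(axis=1)))
            lo = peak - nb // 2
            src_lo, src_hi = max(lo, 0), min(lo + nb, params.n_mels)
            out[i, src_lo - lo : src_hi - lo] = stack[i, src_lo:src_hi]
        stack = out
    return SpectrogramSet(
        spectrograms=stack,
        labels=None if labels is None else np.asarray(labels),
        params=params,
    )


# ---------------------------------------------------------------------------
# embedding + clustering + agreement


def embed_2d(
    features: np.ndarray,
    min_dist: float = 0.5,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """2-D neighbor-graph manifold embedding (UMAP), seeded."""
    features = np.asarray(features, dtype=float)
    if features.ndim > 2:
        features = features.reshape(features.shape[0], -1)
    if features.shape[0] <= n_neighbors:
        raise ValueError("need more items than n_neighbors")
    import umap  # deferred: heavy import

    reducer = umap.UMAP(
        n_components=2, min_dist=min_dist, n_neighbors=n_neighbors, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        return np.asarray(reducer.fit_transform(features))


def cluster(
    embedding: np.ndarray,
    method: str = "density",
    min_samples: int = 10,
    min_cluster_size: int = 20,
    k: int = 40,
    seed: int = 0,
) -> ClusterResult:
    """Cluster embedded points.

    ``density`` = hierarchical density-based clustering (min_samples=10,
    min_cluster_size=20 by default; label -1 marks noise points);
    ``kmeans`` = k-means with 40 groups by default, seeded.
    """
    embedding = np.asarray(embedding, dtype=float)
    if method == "density":
        if len(embedding) < min_cluster_size:
            warnings.warn("fewer points than min_cluster_size; all points unassigned")
            return ClusterResult(embedding, np.full(len(embedding), -1), method)
        from sklearn.cluster import HDBSCAN

        labels = HDBSCAN(min_samples=min_samples, min_cluster_size=min_cluster_size).fit_predict(embedding)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(embedding)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterResult(embedding, np.asarray(labels), method)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def cluster_agreement(manual_labels, cluster_labels) -> tuple[float, float, float]:
    """Homogeneity, completeness and v-measure from conditional entropies.

    homogeneity = 1 - H(manual | cluster) / H(manual);
    completeness = 1 - H(cluster | manual) / H(cluster);
    v = their harmonic mean.  Degenerate single-class partitions score 1
    on the corresponding axis.
    """
    manual = np.asarray(manual_labels)
    clust = np.asarray(cluster_labels)
    if manual.shape != clust.shape:
        raise ValueError("label arrays must have equal length")
    mu, mi = np.unique(manual, return_inverse=True)
    cu, ci = np.unique(clust, return_inverse=True)
    cont = np.zeros((len(mu), len(cu)))
    np.add.at(cont, (mi, ci), 1)
    n = cont.sum()
    h_m = _entropy(cont.sum(axis=1))
    h_c = _entropy(cont.sum(axis=0))
    # conditional entropies from the contingency table
    h_m_given_c = 0.0
    h_c_given_m = 0.0
    for j in range(cont.shape[1]):
        col = cont[:, j]
        h_m_given_c += col.sum() / n * _entropy(col)
    for i in range(cont.shape[0]):
        row = cont[i]
        h_c_given_m += row.sum() / n * _entropy(row)
    homogeneity = 1.0 if h_m == 0 else 1.0 - h_m_given_c / h_m
    completeness = 1.0 if h_c == 0 else 1.0 - h_c_given_m / h_c
    if homogeneity + completeness == 0:
        v = 0.0
    else:
        v = 2 * homogeneity * completeness / (homogeneity + completeness)
    return homogeneity, completeness, v
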