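"""Signal-to-noise ratio estimators.

Three variants matched to the signal types:

* **pulse** — per event: a 20 ms waveform centered on the peak of the pulse
  energy; SNR = RMS of the center (7.5-12.5 ms) over RMS of the margins
  (first and last 5 ms).  Multi-channel: the channel with the highest
  center RMS.
* **sine** — per segment: RMS inside the segment over the RMS of the 200 ms
  flanks before/after it (10 ms buffer), excluding samples annotated with
  given labels.  Multi-channel: the channel with the largest signal RMS.
* **mouse** — per-sample under an additive noise model: the squared signal
  averaged in 1 ms windows gives sigma_total^2(t); the noise floor is a
  robust low-percentile estimate over time (valid when the noise level
  changes little); SNR(t) = max(sigma_total^2 - floor, 0) / floor.

RMS is sqrt(mean(x^2)); all estimators are invariant to global gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AnnotationTable, Recording

__all__ = ["SNRReport", "snr_pulse", "snr_sine", "snr_mouse"]


@dataclass
class SNRReport:
    values: np.ndarray  # one per event/segment/window; may contain inf
    method: str
    times: np.ndarray | None = None  # event times / segment onsets / window starts


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if len(x) else np.nan


def snr_pulse(
    recording: Recording,
    event_times: np.ndarray,
    window_s: float = 0.020,
    margin_s: float = 0.005,
    center_s: tuple[float, float] = (0.0075, 0.0125),
) -> SNRReport:
    """Per-event SNR from 20 ms waveforms centered on the pulse energy peak."""
    rate = recording.rate
    half = int(round(window_s / 2 * rate))
    n_margin = int(round(margin_s * rate))
    c0 = int(round(center_s[0] * rate))
    c1 = int(round(center_s[1] * rate))
    values, times = [], []
    for t in np.asarray(event_times, dtype=float):
        c = int(round(t * rate))
        if c - half < 0 or c + half > recording.n_samples:
            warnings.warn(f"event at {t:.4f} s too close to the edge; skipped")
            continue
        # re-center on the peak of pulse energy within the window
        seg = recording.samples[c - half : c + half]
        peak = int(np.argmax(np.sum(seg**2, axis=1)))
        c = c - half + peak
        if c - half < 0 or c + half > recording.n_samples:
            warnings.warn(f"event at {t:.4f} s too close to the edge; skipped")
            continue
        wav = recording.samples[c - half : c + half]  # [2*half, channels]
        center_rms = np.sqrt(np.mean(wav[c0:c1] ** 2, axis=0))
        ch = int(np.argmax(center_rms))
        margins = np.concatenate([wav[:n_margin, ch], wav[-n_margin:, ch]])
        noise = _rms(margins)
        values.append(np.inf if noise == 0 else float(center_rms[ch]) / noise)
        times.append(t)
    return SNRReport(values=np.asarray(values), method="pulse", times=np.asarray(times))


def snr_sine(
    recording: Recording,
    segments,
    flank_s: float = 0.200,
    buffer_s: float = 0.010,
    exclude: AnnotationTable | None = None,
    exclusion_labels: tuple[str, ...] = ("sine", "pulse"),
    event_halfwidth_s: float = 0.005,
) -> SNRReport:
    """Per-segment SNR of sustained song against its flanking noise.

    ``segments`` is an iterable of (onset_s, offset_s).  Flank samples whose
    annotations (in ``exclude``) carry an exclusion label are removed:
    segment rows by their interval, event rows by a +-5 ms window (the
    intervals between pulses stay in the noise estimate).
    """
    rate = recording.rate
    n = recording.n_samples
    excluded = np.zeros(n, dtype=bool)
    if exclude is not None:
        for name, a, b in zip(exclude.names, exclude.starts, exclude.stops):
            if name not in exclusion_labels:
                continue
            if a == b:
                lo = int(round((a - event_halfwidth_s) * rate))
                hi = int(round((a + event_halfwidth_s) * rate))
            else:
                lo, hi = int(round(a * rate)), int(round(b * rate))
            excluded[max(lo, 0) : min(hi, n)] = True
    values, times = [], []
    for on, off in segments:
        a, b = int(round(on * rate)), int(round(off * rate))
        inside = recording.samples[max(a, 0) : min(b, n)]
        sig_rms = np.sqrt(np.mean(inside**2, axis=0))
        ch = int(np.argmax(sig_rms))
        lo1 = int(round((on - buffer_s - flank_s) * rate))
        hi1 = int(round((on - buffer_s) * rate))
        lo2 = int(round((off + buffer_s) * rate))
        hi2 = int(round((off + buffer_s + flank_s) * rate))
        keep = np.zeros(n, dtype=bool)
        keep[max(lo1, 0) : max(hi1, 0)] = True
        keep[min(lo2, n) : min(hi2, n)] = True
        keep &= ~excluded
        flank = recording.samples[keep, ch]
        if len(flank) == 0:
            values.append(np.nan)
            warnings.warn(f"segment at {on:.3f} s: empty flank after exclusions")
        else:
            noise = _rms(flank)
            values.append(np.inf if noise == 0 else float(sig_rms[ch]) / noise)
        times.append(on)
    return SNRReport(values=np.asarray(values), method="sine", times=np.asarray(times))


def snr_mouse(
    recording: Recording,
    window_s: float = 0.001,
    floor_percentile: float = 10.0,
) -> SNRReport:
    """Per-window SNR under the additive noise model
    sigma_total^2 = sigma_signal^2 + sigma_noise^2 with a constant noise
    floor estimated as a low percentile of the windowed power."""
    rate = recording.rate
    w = int(round(window_s * rate))
    n_win = recording.n_samples // w
    if n_win < 4:
        raise ValueError("recording must span several windows")
    x = recording.samples[: n_win * w, 0]
    power = np.mean(x.reshape(n_win, w) ** 2, axis=1)
    floor = float(np.percentile(power, floor_percentile))
    if floor == 0:
        return SNRReport(
            values=np.full(n_win, np.inf), method="mouse",
            times=np.arange(n_win) * w / rate,
        )
    snr = np.maximum(power - floor, 0.0) / floor
    return SNRReport(values=snr, method="mouse", times=np.arange(n_win) * w / rate)
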