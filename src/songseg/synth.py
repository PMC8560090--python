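"""Seeded generators of synthetic song with ground-truth annotations.

The generators emulate the statistical structure of the signals the tool is
built for, so that the whole pipeline (target encoding, training, inference,
evaluation, clustering) can be exercised without any recordings:

* fly **pulse song** — trains of short (5-10 ms) Gabor-like pulses
  (Gaussian-windowed cosines) with carrier frequencies between 180 and
  500 Hz, repeated at a species-specific inter-pulse interval
  (35-45 ms in D. melanogaster);
* fly **sine song** — sustained oscillation at a species-specific carrier
  (150 Hz) with on/offset ramps;
* bird-like **syllables** — labeled harmonic tones with distinct
  spectro-temporal contours, separated by silent gaps;
* additive Gaussian noise, pulsatile noise transients (isolated
  single-cycle clicks at Poisson times, mimicking fly interactions), and
  multi-channel projection with per-channel gains.

Ground-truth pulse times are the envelope peaks; segment annotations cover
the support of the placed component.  Identical seeds give bit-identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationTable, Recording

__all__ = [
    "PulseTrainParams",
    "SineSongParams",
    "SyllableTemplate",
    "NoiseParams",
    "PlacedComponent",
    "make_pulse_train",
    "make_sine_song",
    "make_syllable_sequence",
    "make_recording",
    "make_fly_corpus",
    "default_syllable_templates",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PulseTrainParams:
    """Parameters of one pulse train.

    ``pulse_duration_ms`` is the effective pulse support (~4 envelope sigma).
    Inter-pulse intervals are drawn uniformly from
    ``interval_mean_ms +- interval_jitter_ms``.
    """

    carrier_hz: float = 250.0
    pulse_duration_ms: float = 7.5
    interval_mean_ms: float = 40.0
    interval_jitter_ms: float = 5.0
    train_length: int = 5
    amplitude: float = 1.0

    def validate(self, rate: float) -> None:
        if self.carrier_hz >= rate / 2:
            raise ValueError("pulse carrier at or above Nyquist")
        if self.interval_mean_ms - self.interval_jitter_ms <= self.pulse_duration_ms:
            raise ValueError("inter-pulse interval must exceed pulse duration")
        if self.train_length < 1:
            raise ValueError("train_length must be >= 1")


@dataclass
class SineSongParams:
    carrier_hz: float = 150.0
    duration_ms: float = 300.0
    ramp_ms: float = 20.0
    amplitude: float = 1.0

    def validate(self, rate: float) -> None:
        if self.carrier_hz >= rate / 2:
            raise ValueError("sine carrier at or above Nyquist")
        if self.duration_ms <= 2 * self.ramp_ms:
            raise ValueError("duration must exceed twice the ramp")


@dataclass
class SyllableTemplate:
    """A labeled harmonic syllable with a piecewise-linear frequency contour.

    ``contour`` is a list of (time fraction in [0, 1], fundamental Hz);
    ``harmonics`` are amplitudes of the fundamental and overtones.
    """

    label: str
    duration_ms: float
    contour: list[tuple[float, float]]
    harmonics: list[float] = field(default_factory=lambda: [1.0])
    ramp_ms: float = 5.0
    amplitude: float = 1.0

    def validate(self, rate: float) -> None:
        if self.duration_ms <= 0:
            raise ValueError("syllable duration must be positive")
        max_f = max(f for _, f in self.contour) * len(self.harmonics)
        if max_f >= rate / 2:
            raise ValueError("syllable contour (incl. harmonics) above Nyquist")


@dataclass
class NoiseParams:
    gaussian_rms: float = 0.0
    pulsatile_rate: float = 0.0  # events per second
    pulsatile_amplitude: float = 0.0

    def validate(self) -> None:
        if min(self.gaussian_rms, self.pulsatile_rate, self.pulsatile_amplitude) < 0:
            raise ValueError("noise parameters must be non-negative")


def _gabor_pulse(rate: float, carrier_hz: float, duration_ms: float) -> np.ndarray:
    """Gaussian-windowed cosine, cosine phase (envelope peak = amplitude peak)."""
    sigma = duration_ms / 1000.0 / 4.0
    half = int(round(2 * sigma * rate))  # support +-2 sigma
    t = np.arange(-half, half + 1) / rate
    return np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * np.pi * carrier_hz * t)


def make_pulse_train(
    params: PulseTrainParams, rate: float, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one pulse train; returns (waveform, envelope-peak times in s).

    Event times fall exactly on the sample grid so that the peak of the
    squared waveform coincides with the annotated time.
    """
    params.validate(rate)
    rng = _rng(rng)
    intervals = params.interval_mean_ms + params.interval_jitter_ms * rng.uniform(
        -1, 1, size=max(params.train_length - 1, 0)
    )
    lead = params.pulse_duration_ms  # ms of silence before the first peak
    peaks_ms = lead + np.concatenate([[0.0], np.cumsum(intervals)])
    peak_samples = np.round(peaks_ms / 1000.0 * rate).astype(int)
    pulse = _gabor_pulse(rate, params.carrier_hz, params.pulse_duration_ms)
    half = (len(pulse) - 1) // 2
    n = peak_samples[-1] + half + int(round(lead / 1000.0 * rate)) + 1
    wav = np.zeros(n)
    for p in peak_samples:
        lo = p - half
        wav[lo : lo + len(pulse)] += params.amplitude * pulse
    return wav, peak_samples / rate


def make_sine_song(
    params: SineSongParams, rate: float, rng=None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Ramped sinusoid; returns (waveform, (onset_s, offset_s))."""
    params.validate(rate)
    n = int(round(params.duration_ms / 1000.0 * rate))
    t = np.arange(n) / rate
    wav = params.amplitude * np.sin(2 * np.pi * params.carrier_hz * t)
    n_ramp = int(round(params.ramp_ms / 1000.0 * rate))
    if n_ramp > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(n_ramp) / n_ramp)
        wav[:n_ramp] *= ramp
        wav[-n_ramp:] *= ramp[::-1]
    return wav, (0.0, n / rate)


def _render_syllable(tpl: SyllableTemplate, rate: float) -> np.ndarray:
    n = int(round(tpl.duration_ms / 1000.0 * rate))
    frac = np.arange(n) / max(n - 1, 1)
    xs = np.array([f for f, _ in tpl.contour])
    ys = np.array([hz for _, hz in tpl.contour])
    f0 = np.interp(frac, xs, ys)
    phase = 2 * np.pi * np.cumsum(f0) / rate
    wav = np.zeros(n)
    for h, amp in enumerate(tpl.harmonics, start=1):
        wav += amp * np.sin(h * phase)
    n_ramp = int(round(tpl.ramp_ms / 1000.0 * rate))
    if n_ramp > 0 and 2 * n_ramp < n:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(n_ramp) / n_ramp)
        wav[:n_ramp] *= ramp
        wav[-n_ramp:] *= ramp[::-1]
    peak = np.max(np.abs(wav))
    if peak > 0:
        wav *= tpl.amplitude / peak
    return wav


def make_syllable_sequence(
    templates: list[SyllableTemplate],
    n: int,
    gap_ms: tuple[float, float],
    rate: float,
    rng=None,
    label_sequence: list[str] | None = None,
    duration_jitter_frac: float = 0.1,
    frequency_jitter_frac: float = 0.05,
) -> tuple[np.ndarray, AnnotationTable]:
    """Concatenate ``n`` randomly drawn syllables separated by silent gaps.

    ``label_sequence`` overrides the random template draws (its length must
    equal ``n``), e.g. to build sequences with exact per-type counts.
    Each rendered syllable's duration and pitch are jittered by up to
    ``duration_jitter_frac`` / ``frequency_jitter_frac`` (natural syllables
    vary continuously in length and pitch).
    """
    if not templates:
        raise ValueError("need at least one template")
    for tpl in templates:
        tpl.validate(rate)
    by_label = {t.label: t for t in templates}
    if label_sequence is not None and len(label_sequence) != n:
        raise ValueError("label_sequence length must equal n")
    rng = _rng(rng)
    pieces: list[np.ndarray] = []
    rows: list[tuple[str, float, float]] = []
    cursor = 0
    for i in range(n):
        gap = rng.uniform(*gap_ms) / 1000.0
        n_gap = int(round(gap * rate))
        pieces.append(np.zeros(n_gap))
        cursor += n_gap
        if label_sequence is not None:
            tpl = by_label[label_sequence[i]]
        else:
            tpl = templates[rng.integers(len(templates))]
        dur = tpl.duration_ms * rng.uniform(1 - duration_jitter_frac,
                                            1 + duration_jitter_frac)
        pitch = rng.uniform(1 - frequency_jitter_frac, 1 + frequency_jitter_frac)
        tpl = dataclasses.replace(
            tpl, duration_ms=dur,
            contour=[(f, hz * pitch) for f, hz in tpl.contour],
        )
        wav = _render_syllable(tpl, rate)
        pieces.append(wav)
        rows.append((tpl.label, cursor / rate, (cursor + len(wav)) / rate))
        cursor += len(wav)
    pieces.append(np.zeros(int(round(np.mean(gap_ms) / 1000.0 * rate))))
    waveform = np.concatenate(pieces) if pieces else np.zeros(0)
    return waveform, AnnotationTable.from_rows(rows)


@dataclass
class PlacedComponent:
    """A waveform placed at ``start_s`` with its annotations (times relative
    to the component's own start)."""

    waveform: np.ndarray
    start_s: float
    annotations: AnnotationTable


def _check_exclusive(table: AnnotationTable) -> None:
    segs = table.segments()
    iv = sorted(zip(segs["start_seconds"], segs["stop_seconds"], segs["name"]))
    for (a0, a1, na), (b0, b1, nb) in zip(iv, iv[1:]):
        if b0 < a1 - 1e-12:
            raise ValueError(
                f"overlapping labeled segments: {na} [{a0:.4f}, {a1:.4f}) and "
                f"{nb} [{b0:.4f}, {b1:.4f})"
            )


def make_recording(
    components: list[PlacedComponent],
    duration_s: float,
    rate: float,
    noise: NoiseParams | None = None,
    channel_gains: np.ndarray | None = None,
    rng=None,
    id: str = "synthetic",
) -> tuple[Recording, AnnotationTable]:
    """Mix placed components into a (possibly multi-channel) Recording.

    ``channel_gains`` is a vector of per-channel gains applied to the summed
    mono mixture (default ``[1.0]``: single channel).  Gaussian and pulsatile
    noise are added independently per channel.
    """
    noise = noise or NoiseParams()
    noise.validate()
    rng = _rng(rng)
    n = int(round(duration_s * rate))
    mono = np.zeros(n)
    table = AnnotationTable()
    for comp in components:
        start = int(round(comp.start_s * rate))
        stop = start + len(comp.waveform)
        if start < 0 or stop > n:
            raise ValueError("component extends beyond the requested duration")
        mono[start:stop] += comp.waveform
        shifted = comp.annotations.df.copy()
        shifted["start_seconds"] += comp.start_s
        shifted["stop_seconds"] += comp.start_s
        table = table.concat(AnnotationTable(shifted))
    _check_exclusive(table)

    gains = np.atleast_1d(np.asarray(channel_gains if channel_gains is not None else [1.0]))
    samples = mono[:, None] * gains[None, :]
    if noise.gaussian_rms > 0:
        samples = samples + noise.gaussian_rms * rng.standard_normal(samples.shape)
    if noise.pulsatile_rate > 0 and noise.pulsatile_amplitude > 0:
        n_clicks = rng.poisson(noise.pulsatile_rate * duration_s)
        for _ in range(n_clicks):
            f = rng.uniform(100.0, min(1000.0, 0.45 * rate))
            cyc = int(round(rate / f))
            pos = rng.integers(0, max(n - cyc, 1))
            click = noise.pulsatile_amplitude * np.sin(
                2 * np.pi * np.arange(cyc) / cyc
            )
            ch = rng.integers(0, samples.shape[1])
            samples[pos : pos + cyc, ch] += click[: n - pos]
    return Recording(samples=samples, rate=rate, id=id), table


def default_syllable_templates(rate: float, n: int = 3) -> list[SyllableTemplate]:
    """Distinct spectro-temporal contours for multi-class fixtures.

    Frequencies scale with the sample rate so the templates stay below
    Nyquist at any rate >= 2 kHz.
    """
    base = rate / 16.0
    bank = [
        SyllableTemplate("upsweep", 80.0, [(0.0, base), (1.0, base * 2.5)], [1.0]),
        SyllableTemplate("downsweep", 80.0, [(0.0, base * 2.5), (1.0, base)], [1.0]),
        SyllableTemplate("tone", 120.0, [(0.0, base * 1.5), (1.0, base * 1.5)], [1.0, 0.5]),
        SyllableTemplate("chevron", 100.0, [(0.0, base), (0.5, base * 3.0), (1.0, base)], [1.0]),
        SyllableTemplate("warble", 140.0, [(0.0, base * 2), (0.25, base), (0.5, base * 2), (0.75, base), (1.0, base * 2)], [1.0]),
        SyllableTemplate("low_tone", 100.0, [(0.0, base * 0.6), (1.0, base * 0.6)], [1.0, 0.3, 0.2]),
    ]
    if n > len(bank):
        raise ValueError(f"at most {len(bank)} default templates available")
    return bank[:n]


def make_fly_corpus(
    duration_s: float,
    rate: float,
    rng=None,
    noise: NoiseParams | None = None,
    pulse_amplitude: float = 1.0,
    sine_amplitude: float = 0.5,
    carrier_range_hz: tuple[float, float] = (180.0, 350.0),
    channel_gains: np.ndarray | None = None,
    id: str = "fly_corpus",
) -> tuple[Recording, AnnotationTable]:
    """Fly-like corpus: alternating pulse trains and sine songs with pauses.

    Bouts are drawn until the requested duration is filled: pulse trains of
    4-12 pulses (interval 35-45 ms, duration 5-10 ms, carrier drawn per train
    from ``carrier_range_hz``) alternate randomly with 200-600 ms sine songs
    at 150 Hz, separated by 100-400 ms pauses.
    """
    rng = _rng(rng)
    noise = noise or NoiseParams(gaussian_rms=0.02)
    components: list[PlacedComponent] = []
    cursor = 0.15
    while True:
        cursor += rng.uniform(0.1, 0.4)
        if rng.uniform() < 0.5:
            params = PulseTrainParams(
                carrier_hz=float(rng.uniform(*carrier_range_hz)),
                pulse_duration_ms=float(rng.uniform(5.0, 10.0)),
                interval_mean_ms=40.0,
                interval_jitter_ms=5.0,
                train_length=int(rng.integers(4, 13)),
                amplitude=pulse_amplitude,
            )
            wav, events = make_pulse_train(params, rate, rng)
            ann = AnnotationTable.from_rows([("pulse", t, t) for t in events])
        else:
            params = SineSongParams(
                carrier_hz=150.0,
                duration_ms=float(rng.uniform(200.0, 600.0)),
                ramp_ms=20.0,
                amplitude=sine_amplitude,
            )
            wav, (on, off) = make_sine_song(params, rate, rng)
            ann = AnnotationTable.from_rows([("sine", on, off)])
        if cursor + len(wav) / rate > duration_s - 0.15:
            break
        components.append(PlacedComponent(wav, cursor, ann))
        cursor += len(wav) / rate
    return make_recording(
        components, duration_s, rate, noise=noise, channel_gains=channel_gains, rng=rng, id=id
    )
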