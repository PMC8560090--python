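"""Audio and annotation containers plus readers/writers.

A :class:`Recording` holds a ``[time x channels]`` waveform with its sample
rate.  An :class:`AnnotationTable` holds typed intervals in seconds; events
(e.g. fly song pulses) are encoded as rows with ``start == stop``, segments
(e.g. sine song, syllables) with ``stop > start``.  Sample indexing is
0-based and intervals are half-open ``[start, stop)`` in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "AnnotationTable",
    "load_audio",
    "save_audio",
    "read_annotations",
    "write_annotations",
    "seconds_to_sample",
    "sample_to_seconds",
]

ANNOTATION_COLUMNS = ("name", "start_seconds", "stop_seconds")


def seconds_to_sample(seconds, rate: float):
    """Convert time in seconds to the nearest sample index: round(t * rate)."""
    return np.asarray(np.round(np.asarray(seconds) * rate), dtype=int)


def sample_to_seconds(sample, rate: float):
    """Convert sample index back to seconds (inverse within 0.5 / rate s)."""
    return np.asarray(sample, dtype=float) / rate


@dataclass
class Recording:
    """Multi-channel waveform with sample rate.

    ``samples`` is float, shaped ``[time, channels]``; integer PCM input is
    rescaled to [-1, 1] by the reader.
    """

    samples: np.ndarray
    rate: float
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be [time x channels]")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.shape[0] == 0:
            raise ValueError("zero-length audio")

    @property
    def channel_count(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class AnnotationTable:
    """Typed event/segment intervals in seconds, sorted by start time."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(ANNOTATION_COLUMNS))
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        missing = set(ANNOTATION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        extra = set(df.columns) - set(ANNOTATION_COLUMNS)
        if extra:
            raise ValueError(f"unknown annotation columns: {sorted(extra)}")
        df = df.astype({"start_seconds": float, "stop_seconds": float})
        bad = df.index[df["stop_seconds"] < df["start_seconds"]]
        if len(bad):
            raise ValueError(f"stop < start in annotation rows {list(bad)}")
        order = np.lexsort((df["stop_seconds"].to_numpy(), df["start_seconds"].to_numpy()))
        self.df = df.iloc[order].reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows) -> "AnnotationTable":
        """Build from an iterable of (name, start_seconds, stop_seconds)."""
        return cls(pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def names(self) -> np.ndarray:
        return self.df["name"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start_seconds"].to_numpy()

    @property
    def stops(self) -> np.ndarray:
        return self.df["stop_seconds"].to_numpy()

    def is_event(self) -> np.ndarray:
        """Boolean mask of rows encoding point events (start == stop)."""
        return self.starts == self.stops

    def events(self, name: str | None = None) -> np.ndarray:
        """Event times in seconds, optionally restricted to one type."""
        mask = self.is_event()
        if name is not None:
            mask &= self.names == name
        return self.starts[mask]

    def segments(self, name: str | None = None) -> pd.DataFrame:
        mask = ~self.is_event()
        if name is not None:
            mask &= self.names == name
        return self.df[mask].reset_index(drop=True)

    def select(self, t0: float, t1: float, shift: bool = True) -> "AnnotationTable":
        """Rows intersecting [t0, t1), clipped; optionally re-referenced to t0."""
        df = self.df
        keep = (df["stop_seconds"] > t0) & (df["start_seconds"] < t1)
        keep |= (df["start_seconds"] == df["stop_seconds"]) & (
            (df["start_seconds"] >= t0) & (df["start_seconds"] < t1)
        )
        out = df[keep].copy()
        ev = out["start_seconds"] == out["stop_seconds"]
        out.loc[~ev, "start_seconds"] = out.loc[~ev, "start_seconds"].clip(lower=t0)
        out.loc[~ev, "stop_seconds"] = out.loc[~ev, "stop_seconds"].clip(upper=t1)
        if shift:
            out["start_seconds"] -= t0
            out["stop_seconds"] -= t0
        return AnnotationTable(out.reset_index(drop=True))

    def concat(self, other: "AnnotationTable") -> "AnnotationTable":
        return AnnotationTable(pd.concat([self.df, other.df], ignore_index=True))


_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): 2**7}


def load_audio(path) -> Recording:
    """Read a PCM/float WAV file into a :class:`Recording`.

    Integer PCM is rescaled to [-1, 1]; unsigned 8-bit is centered first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # pragma: no cover - corrupt file branch
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"zero-length audio in {path}")
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.uint8:
            data = data.astype(np.float64) - 128.0
        samples = np.asarray(data, dtype=np.float64) / scale
    else:
        samples = np.asarray(data, dtype=np.float64)
    return Recording(samples=samples, rate=float(rate), id=path.stem)


def save_audio(path, recording: Recording, dtype: str = "float32") -> None:
    """Write a Recording to WAV (``float32`` or ``int16``)."""
    data = recording.samples
    if dtype == "int16":
        data = np.clip(np.round(data * 2**15), -(2**15), 2**15 - 1).astype(np.int16)
    elif dtype == "float32":
        data = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    wavfile.write(str(path), int(round(recording.rate)), data)


def read_annotations(path) -> AnnotationTable:
    """Read a (name, start_seconds, stop_seconds) CSV into a sorted table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return AnnotationTable(df)


def write_annotations(path, table: AnnotationTable) -> None:
    table.df.to_csv(path, index=False)
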