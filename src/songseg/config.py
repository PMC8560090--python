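"""Structural network configuration and species presets.

``NetworkConfig`` collects every structural hyperparameter of the model:
input rate and chunk length, the optional trainable STFT frontend (number of
cos/sin filter pairs, window duration ``T`` and stride ``s``), and the TCN
body (number of stacks, residual blocks per stack, kernel count/size,
dilation base, which stacks use time-channel separable convolutions).

Presets mirror the structural parameters used for each tested species
(fly single/multi channel, mouse, marmoset, Bengalese and zebra finch),
together with the per-species post-processing defaults (event threshold and
minimum peak distance, segment gap-fill and minimum duration, evaluation
tolerance).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ClassDef", "NetworkConfig", "PostProcessing", "load_preset", "preset_names"]


@dataclass
class ClassDef:
    """One output class: a name plus its kind.

    kind is ``"event"`` (annotated by a point time, trained as a Gaussian
    bump), ``"segment"`` (interval, trained as a binary vector) or
    ``"syllable"`` (segment that additionally receives inter-syllable
    training gaps, bird-style).
    """

    name: str
    kind: str = "segment"

    def __post_init__(self) -> None:
        if self.kind not in ("event", "segment", "syllable"):
            raise ValueError(f"unknown class kind {self.kind!r}")


NO_SONG = "no_song"


@dataclass
class PostProcessing:
    """Per-species annotation-generation and evaluation defaults."""

    event_threshold: float = 0.7
    event_min_distance_s: float = 0.010
    fill_gap_s: float = 0.020
    min_duration_s: float = 0.020
    event_tolerance_s: float = 0.010
    segment_boundary_tolerance_s: float = 0.040


@dataclass
class NetworkConfig:
    rate: float = 10_000.0
    chunk_samples: int = 2048
    channels: int = 1
    use_stft: bool = False
    stft_pairs: int = 33
    stft_duration_T: int = 64
    stft_stride_s: int = 16
    kernel_count: int = 32
    kernel_size: int = 32
    tcn_blocks: int = 3
    residual_blocks_per_tcn: int = 5
    dilation_base: int = 2
    separable_blocks: list[int] = field(default_factory=list)  # 0-based stack indices
    classes: list[ClassDef] = field(default_factory=list)
    postprocessing: PostProcessing = field(default_factory=PostProcessing)
    name: str = ""

    def __post_init__(self) -> None:
        self.classes = [
            c if isinstance(c, ClassDef) else ClassDef(**c) for c in self.classes
        ]
        if isinstance(self.postprocessing, dict):
            self.postprocessing = PostProcessing(**self.postprocessing)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.residual_blocks_per_tcn < 1:
            raise ValueError("residual_blocks_per_tcn must be >= 1")
        if self.use_stft:
            if self.channels != 1:
                raise ValueError("STFT frontend supports single-channel input only")
            if self.chunk_samples % self.stft_stride_s != 0 or self.chunk_samples <= 0:
                raise ValueError("chunk_samples must be a positive multiple of stft_stride_s")
            if self.stft_pairs > self.stft_duration_T // 2 + 1:
                raise ValueError("stft_pairs must be <= T/2 + 1")
        if any(b < 0 or b >= self.tcn_blocks for b in self.separable_blocks):
            raise ValueError("separable_blocks indices out of range")
        if self.separable_blocks and self.channels < 1:
            raise ValueError("separable blocks require at least one channel")

    # -- class bookkeeping -------------------------------------------------
    @property
    def class_names(self) -> list[str]:
        """Song classes in declared order, with the implicit no-song class last."""
        return [c.name for c in self.classes] + [NO_SONG]

    @property
    def n_classes(self) -> int:
        return len(self.classes) + 1

    def class_kind(self, name: str) -> str:
        for c in self.classes:
            if c.name == name:
                return c.kind
        if name == NO_SONG:
            return "segment"
        raise KeyError(name)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def preset_names() -> list[str]:
    root = resources.files("songseg") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> NetworkConfig:
    """Load a named species preset (e.g. ``fly_single``, ``mouse``)."""
    root = resources.files("songseg") / "presets"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError as exc:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}") from exc
    return NetworkConfig.from_dict(yaml.safe_load(text))
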