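"""Train/validation/test splitting of recordings.

Each recording is split into contiguous blocks: validation and test blocks
are drawn (seeded) from the first, middle or last portion of the recording
and the training set is the remainder.  Default fractions are 80:10:10;
60:20:20 is available for datasets with unevenly distributed call types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording

__all__ = ["DatasetSplit", "split_dataset"]

_POSITIONS = ("first", "middle", "last")


@dataclass
class DatasetSplit:
    """Per-recording lists of (recording id, start_sample, stop_sample)."""

    train: list[tuple[str, int, int]] = field(default_factory=list)
    val: list[tuple[str, int, int]] = field(default_factory=list)
    test: list[tuple[str, int, int]] = field(default_factory=list)
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def intervals(self, part: str) -> list[tuple[str, int, int]]:
        return getattr(self, part)


def _block(position: str, n: int, size: int) -> tuple[int, int]:
    if position == "first":
        return 0, size
    if position == "last":
        return n - size, n
    start = (n - size) // 2
    return start, start + size


def split_dataset(
    recordings: list[Recording],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    position_seed: int | None = 0,
    shared_positions: bool = False,
) -> DatasetSplit:
    """Split each recording into contiguous train/val/test blocks.

    Parameters
    ----------
    fractions
        (train, val, test) fractions; must be non-negative and sum to 1.
    position_seed
        Seed for the choice of val/test block positions among
        {first, middle, last}.
    shared_positions
        If True, one position draw is shared by all recordings; by default
        positions are re-drawn per recording.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(position_seed)
    split = DatasetSplit(fractions=fractions)

    shared_draw: tuple[str, str] | None = None
    if shared_positions:
        val_pos, test_pos = rng.choice(len(_POSITIONS), size=2, replace=False)
        shared_draw = (_POSITIONS[val_pos], _POSITIONS[test_pos])

    for rec in recordings:
        n = rec.n_samples
        n_val = int(round(fractions[1] * n))
        n_test = int(round(fractions[2] * n))
        if (fractions[1] > 0 and n_val == 0) or (fractions[2] > 0 and n_test == 0):
            raise ValueError(f"recording {rec.id!r} shorter than the smallest block")
        if shared_draw is not None:
            val_pos, test_pos = shared_draw
        else:
            i, j = rng.choice(len(_POSITIONS), size=2, replace=False)
            val_pos, test_pos = _POSITIONS[i], _POSITIONS[j]

        blocks: list[tuple[int, int, str]] = []
        if n_val > 0:
            a, b = _block(val_pos, n, n_val)
            blocks.append((a, b, "val"))
        if n_test > 0:
            a, b = _block(test_pos, n, n_test)
            blocks.append((a, b, "test"))
        blocks.sort()
        # resolve overlap between middle blocks of different sizes by shifting
        for k in range(1, len(blocks)):
            if blocks[k][0] < blocks[k - 1][1]:
                a, b, part = blocks[k]
                shift = blocks[k - 1][1] - a
                blocks[k] = (a + shift, b + shift, part)
        if blocks and blocks[-1][1] > n:
            raise ValueError(f"recording {rec.id!r} too short for requested blocks")

        cursor = 0
        for a, b, part in blocks:
            if a > cursor:
                split.train.append((rec.id, cursor, a))
            split.intervals(part).append((rec.id, a, b))
            cursor = b
        if cursor < n:
            split.train.append((rec.id, cursor, n))
    return split
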