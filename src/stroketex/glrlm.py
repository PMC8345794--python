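"""Gray-level run-length matrices and the 11 classic run-length features.

A run is a maximal set of consecutive, collinear pixels sharing one gray
level.  r(i, l) counts runs of level i and length l along one direction;
the 11 features follow the Galloway / Chu / Dasarathy-Holder definitions
with 1-based gray-level indexing in the low/high-gray emphasis weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .preprocess import CONTINUOUS, ValidationError
from .glcm import FeatureBlock

DIRECTIONS = (0, 45, 90, 135)

GLRLM_FEATURES = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
)


@dataclass
class RunLengthMatrix:
    """Run counts r(i, l): rows are gray levels 0..L-1, columns run lengths
    1..max_run (column index l-1)."""

    R: np.ndarray
    levels: int
    max_run: int
    direction: object  # one of DIRECTIONS or "averaged"
    pixel_total: int

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64)
        if self.R.shape != (self.levels, self.max_run):
            raise ValidationError("run-length matrix shape mismatch")
        if self.R.min() < 0:
            raise ValidationError("negative run counts")


def _lines(arr: np.ndarray, direction: int) -> List[np.ndarray]:
    """The scan lines of ``arr`` along one of the four directions."""
    h, w = arr.shape
    if direction == 0:
        return [arr[r, :] for r in range(h)]
    if direction == 90:
        return [arr[:, c] for c in range(w)]
    if direction == 45:   # up-right anti-diagonals
        fl = np.flipud(arr)
        return [np.diagonal(fl, offset=k) for k in range(-(h - 1), w)]
    if direction == 135:  # down-right diagonals
        return [np.diagonal(arr, offset=k) for k in range(-(h - 1), w)]
    raise ValidationError(f"unsupported direction {direction}; choose from {DIRECTIONS}")


def _run_lengths(line: np.ndarray) -> List[Tuple[int, int]]:
    """(level, run length) pairs of the maximal runs of one scan line."""
    if line.size == 0:
        return []
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    return [(int(line[s]), int(e - s)) for s, e in zip(starts, ends)]


def glrlm_matrix(img, direction: int = 0) -> RunLengthMatrix:
    """Count maximal equal-level runs of a quantized image along ``direction``."""
    if getattr(img, "levels", CONTINUOUS) == CONTINUOUS:
        raise ValidationError("glrlm_matrix expects a quantized image")
    arr = np.asarray(img.pixels, dtype=np.int64)
    L = int(img.levels)
    max_run = max(arr.shape)  # safe upper bound for every direction
    R = np.zeros((L, max_run), dtype=np.float64)
    for line in _lines(arr, direction):
        for level, length in _run_lengths(np.asarray(line)):
            R[level, length - 1] += 1
    return RunLengthMatrix(R, L, max_run, direction, int(arr.size))


def glrlm_feature_set(R: RunLengthMatrix, source: str = "orig") -> FeatureBlock:
    """The 11 run-length features of one run-length matrix."""
    M = R.R
    N = M.sum()
    if N <= 0:
        raise ValidationError("empty run-length matrix (no runs)")
    i = np.arange(1, R.levels + 1, dtype=np.float64)[:, None]   # 1-based level
    l = np.arange(1, R.max_run + 1, dtype=np.float64)[None, :]  # run length
    vals = {
        "sre": (M / l ** 2).sum() / N,
        "lre": (M * l ** 2).sum() / N,
        "gln": (M.sum(axis=1) ** 2).sum() / N,
        "rln": (M.sum(axis=0) ** 2).sum() / N,
        "rp": N / R.pixel_total,
        "lgre": (M / i ** 2).sum() / N,
        "hgre": (M * i ** 2).sum() / N,
        "srlge": (M / (i ** 2 * l ** 2)).sum() / N,
        "srhge": (M * i ** 2 / l ** 2).sum() / N,
        "lrlge": (M * l ** 2 / i ** 2).sum() / N,
        "lrhge": (M * i ** 2 * l ** 2).sum() / N,
    }
    return FeatureBlock([f"glrlm_{k}" for k in GLRLM_FEATURES],
                        [float(vals[k]) for k in GLRLM_FEATURES], source)


def glrlm_features_averaged(img, directions: Sequence[int] = DIRECTIONS,
                            source: str = "orig") -> FeatureBlock:
    """Per-direction features averaged over ``directions`` (rotation-robust)."""
    blocks = [glrlm_feature_set(glrlm_matrix(img, d), source) for d in directions]
    values = np.mean([b.values for b in blocks], axis=0)
    return FeatureBlock(blocks[0].names, [float(v) for v in values], source)
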