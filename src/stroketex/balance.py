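"""Adaptive synthetic (ADASYN) oversampling for imbalanced classes.

Minority classes are oversampled toward the majority count.  Each minority
seed point receives a share of the synthetic budget proportional to its
learning difficulty — the fraction of majority-class members among its k
nearest neighbors — and synthetics are drawn uniformly on segments between
the seed and one of its k nearest same-class neighbors, so every synthetic
vector is a convex combination of two same-class originals.  The multiclass
case balances each minority class one-vs-rest against the largest class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .preprocess import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class LabeledSet:
    """Fixed-length vectors (flattened images or feature rows) with labels."""

    items: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.items.ndim != 2 or self.items.shape[0] == 0:
            raise ValidationError("items must be a nonempty 2-D array")
        if self.labels.shape[0] != self.items.shape[0]:
            raise ValidationError("labels length must match item count")

    @property
    def class_counts(self) -> Dict[str, int]:
        return dict(Counter(self.labels.tolist()))


def adasyn_oversample(data: LabeledSet, k: int = 5, beta: float = 1.0,
                      seed: int = 0) -> LabeledSet:
    """Balance all minority classes up to the majority count.

    Parameters
    ----------
    k
        Neighborhood size for both the difficulty estimate and the synthesis
        neighbors; truncated (with a warning) when a class is too small.
    beta
        Fraction of the class deficit to synthesize (1.0 = full balance).
    seed
        Seed of the interpolation randomness.  The number of synthetics per
        class is deterministic, so different seeds give identical counts.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    counts = data.class_counts
    if len(counts) < 2:
        raise ValidationError("need at least 2 classes to balance")
    for cls, n in counts.items():
        if n < 2:
            raise ValidationError(
                f"minority class {cls!r} has {n} member(s); need at least 2")
    rng = np.random.default_rng(seed)
    majority = max(counts, key=lambda c: (counts[c], str(c)))
    m_major = counts[majority]
    X, y = data.items, data.labels

    new_items = [X]
    new_labels = [y]
    # minority classes processed ascending by size (ties by label) for
    # a deterministic order
    minorities = sorted((c for c in counts if c != majority),
                        key=lambda c: (counts[c], str(c)))
    for cls in minorities:
        G = int(round((m_major - counts[cls]) * beta))
        if G <= 0:
            continue
        idx_min = np.flatnonzero(y == cls)
        Xc = X[idx_min]
        m_min = len(idx_min)

        # difficulty: majority members among k nearest neighbors in the full set
        k_full = min(k, X.shape[0] - 1)
        if k_full < k:
            logger.warning("k=%d exceeds available neighbors; truncated to %d",
                           k, k_full)
        nn_full = NearestNeighbors(n_neighbors=k_full + 1).fit(X)
        _, nbrs = nn_full.kneighbors(Xc)
        nbrs = nbrs[:, 1:]  # drop self
        r = (y[nbrs] == majority).sum(axis=1) / k_full
        if r.sum() <= 0:
            # no majority neighbors anywhere: spread the budget uniformly
            r_hat = np.full(m_min, 1.0 / m_min)
        else:
            r_hat = r / r.sum()
        # largest-remainder apportionment: sum(g) == G exactly, instead of
        # per-seed rounding which can drift by up to half the class size
        quota = r_hat * G
        g = np.floor(quota).astype(int)
        leftover = G - int(g.sum())
        if leftover > 0:
            order = np.argsort(-(quota - g), kind="stable")
            g[order[:leftover]] += 1

        # synthesis neighbors: k nearest within the class
        k_min = min(k, m_min - 1)
        if k_min < k:
            logger.warning("class %r: k=%d exceeds class size; truncated to %d",
                           cls, k, k_min)
        nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(Xc)
        _, nbrs_min = nn_min.kneighbors(Xc)
        nbrs_min = nbrs_min[:, 1:]

        synth = []
        for i in range(m_min):
            for _ in range(g[i]):
                z = nbrs_min[i, rng.integers(0, k_min)]
                lam = rng.uniform(0.0, 1.0)
                synth.append(Xc[i] + lam * (Xc[z] - Xc[i]))
        if synth:
            new_items.append(np.asarray(synth))
            new_labels.append(np.full(len(synth), cls, dtype=y.dtype))
    return LabeledSet(np.vstack(new_items), np.concatenate(new_labels))
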