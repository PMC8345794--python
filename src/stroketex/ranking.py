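"""One-way ANOVA feature ranking.

Each feature is scored by the F ratio of between-class to within-class mean
squares across the three stroke classes; features are ordered by F
descending (equivalently p ascending, by monotonicity of the F tail), with
ties broken by original column index.  The F value is used purely for
ordering, so no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .preprocess import ValidationError


@dataclass
class RankedFeatures:
    order: np.ndarray      # permutation of column indices, best first
    f_values: np.ndarray   # per-column F
    p_values: np.ndarray   # per-column p


def _group_stats(matrix: np.ndarray, labels: np.ndarray):
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("need at least 2 groups")
    groups = []
    for c in classes:
        g = matrix[labels == c]
        if g.shape[0] < 2:
            raise ValidationError(f"group {c!r} has fewer than 2 members")
        groups.append(g)
    return classes, groups


def f_values(matrix: np.ndarray, labels: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA over the columns of ``matrix``.

    Returns per-column (F, p).  Columns with zero within-group variance but
    nonzero between-group variance get F = inf, p = 0; columns with zero
    total variance get F = 0, p = 1.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    labels = np.asarray(labels)
    classes, groups = _group_stats(matrix, labels)
    n = matrix.shape[0]
    g = len(classes)
    grand = matrix.mean(axis=0)
    ssb = np.zeros(matrix.shape[1])
    ssw = np.zeros(matrix.shape[1])
    for grp in groups:
        m = grp.mean(axis=0)
        ssb += grp.shape[0] * (m - grand) ** 2
        ssw += ((grp - m) ** 2).sum(axis=0)
    dfb, dfw = g - 1, n - g
    # scale-relative tolerance for "zero" variance
    sst = ssb + ssw
    tol = 1e-12 * np.maximum(sst, 1.0)
    F = np.empty(matrix.shape[1])
    p = np.empty(matrix.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        Fr = (ssb / dfb) / (ssw / dfw)
    zero_tot = sst <= tol
    zero_within = (ssw <= tol) & ~zero_tot
    regular = ~zero_tot & ~zero_within
    F[regular] = Fr[regular]
    p[regular] = stats.f.sf(Fr[regular], dfb, dfw)
    F[zero_within] = np.inf
    p[zero_within] = 0.0
    F[zero_tot] = 0.0
    p[zero_tot] = 1.0
    return F, p


def anova_f(values: Sequence[float], labels: Sequence) -> Tuple[float, float]:
    """One-way ANOVA F and p for a single feature."""
    F, p = f_values(np.asarray(values, dtype=np.float64)[:, None], labels)
    return float(F[0]), float(p[0])


def rank_features(matrix: np.ndarray, labels: Sequence,
                  expected_columns: int | None = None) -> RankedFeatures:
    """Full ranking of feature columns: F descending, ties by column index."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if expected_columns is not None and matrix.shape[1] != expected_columns:
        raise ValidationError(
            f"feature matrix has {matrix.shape[1]} columns, catalog expects "
            f"{expected_columns}")
    F, p = f_values(matrix, labels)
    # stable sort on -F keeps original-index order within ties
    order = np.argsort(-F, kind="stable")
    return RankedFeatures(order=order, f_values=F, p_values=p)
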