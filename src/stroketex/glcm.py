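"""Gray-level co-occurrence matrices and Haralick-style texture features.

The co-occurrence matrix p(i, j) is the joint probability of observing gray
levels i and j at a fixed pixel offset; second-order statistics of p capture
the texture of the image.  The default feature set holds 14 features: the 12
named linear/nonlinear features (autocorrelation, maximum probability,
dissimilarity, entropy, cluster shade, sum average, sum entropy, sum
variance, difference variance, difference entropy and the two information
measures of correlation) completed with cluster prominence and homogeneity.
Contrast is kept in the registry so an alternative completion can be swapped
in via ``feature_set``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from skimage.feature import graycomatrix

from .preprocess import CONTINUOUS, GrayImage, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities p(i, j) over L gray levels."""

    P: np.ndarray
    levels: int
    offsets: Tuple[Tuple[int, int], ...]
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.shape != (self.levels, self.levels):
            raise ValidationError("GLCM shape does not match level count")
        if self.P.min() < 0 or abs(self.P.sum() - 1.0) > 1e-12:
            raise ValidationError("GLCM must be a probability distribution")


@dataclass
class FeatureBlock:
    """Named feature values extracted from one sub-image."""

    names: List[str]
    values: List[float]
    source: str = "orig"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValidationError("names and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))


def quantize(img, levels: int = 8) -> GrayImage:
    """Uniformly bin [0, 1] intensities into ``levels`` discrete gray levels.

    Bin b = floor(v * levels), with v == 1 clamped into the top bin.
    """
    if levels < 2:
        raise ValidationError(f"levels must be >= 2, got {levels}")
    arr = np.asarray(img.pixels, dtype=np.float64)
    q = np.floor(arr * levels).astype(np.int64)
    np.clip(q, 0, levels - 1, out=q)
    out = GrayImage.__new__(GrayImage)
    out.pixels = q
    out.levels = levels
    return out


# angle -> (row-shift, col-shift) at unit distance, standard GLCM convention
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix(img, distance: int = 1,
                angles: Sequence[int] = (0, 45, 90, 135),
                symmetric: bool = True, averaged: bool = True):
    """Co-occurrence matrix (or per-angle matrices) of a quantized image.

    Counts of co-occurring level pairs at each offset are symmetrized,
    averaged over the requested angles and normalized to probabilities.
    With ``averaged=False`` a list of per-angle matrices is returned.
    """
    if getattr(img, "levels", CONTINUOUS) == CONTINUOUS:
        raise ValidationError("glcm_matrix expects a quantized image")
    L = int(img.levels)
    arr = np.asarray(img.pixels, dtype=np.uint8 if L <= 256 else np.int64)
    for a in angles:
        if a not in _ANGLE_OFFSETS:
            raise ValidationError(f"unsupported angle {a}; choose from 0/45/90/135")
    dr_dc = [(_ANGLE_OFFSETS[a][0] * distance, _ANGLE_OFFSETS[a][1] * distance)
             for a in angles]
    for dr, dc in dr_dc:
        if abs(dr) >= img.pixels.shape[0] or abs(dc) >= img.pixels.shape[1]:
            raise ValidationError(
                f"offset ({dr},{dc}) exceeds image {img.pixels.shape}")
    rad = [np.deg2rad(a) for a in angles]
    counts = graycomatrix(arr, distances=[distance], angles=rad, levels=L,
                          symmetric=symmetric, normed=False).astype(np.float64)
    offsets = tuple(dr_dc)
    mats = []
    for k in range(len(angles)):
        C = counts[:, :, 0, k]
        total = C.sum()
        if total == 0:
            raise ValidationError("no co-occurring pixel pairs at this offset")
        mats.append(GLCMatrix(C / total, L, (offsets[k],), symmetric))
    if not averaged:
        return mats
    C = counts[:, :, 0, :].sum(axis=2)
    return GLCMatrix(C / C.sum(), L, offsets, symmetric)


# ---------------------------------------------------------------------------
# Haralick feature registry
# ---------------------------------------------------------------------------

def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log(p) with the 0*log(0) = 0 convention; natural log."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def _marginals(P: np.ndarray):
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    return i, px, py, mu_x, mu_y


def _p_sum(P: np.ndarray) -> np.ndarray:
    """Distribution of i+j, indexed k = 0 .. 2(L-1)."""
    L = P.shape[0]
    out = np.zeros(2 * L - 1)
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    np.add.at(out, (ii + jj).ravel(), P.ravel())
    return out


def _p_diff(P: np.ndarray) -> np.ndarray:
    """Distribution of |i-j|, indexed k = 0 .. L-1."""
    L = P.shape[0]
    out = np.zeros(L)
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    np.add.at(out, np.abs(ii - jj).ravel(), P.ravel())
    return out


def _f_autocorrelation(P, ctx):
    ii, jj = ctx["ii"], ctx["jj"]
    return float((ii * jj * P).sum())


def _f_max_probability(P, ctx):
    return float(P.max())


def _f_dissimilarity(P, ctx):
    return float((np.abs(ctx["ii"] - ctx["jj"]) * P).sum())


def _f_entropy(P, ctx):
    return float(-_xlogx(P).sum())


def _f_cluster_shade(P, ctx):
    s = ctx["ii"] + ctx["jj"] - ctx["mu_x"] - ctx["mu_y"]
    return float((s ** 3 * P).sum())


def _f_cluster_prominence(P, ctx):
    s = ctx["ii"] + ctx["jj"] - ctx["mu_x"] - ctx["mu_y"]
    return float((s ** 4 * P).sum())


def _f_homogeneity(P, ctx):
    return float((P / (1.0 + (ctx["ii"] - ctx["jj"]) ** 2)).sum())


def _f_contrast(P, ctx):
    return float(((ctx["ii"] - ctx["jj"]) ** 2 * P).sum())


def _f_sum_average(P, ctx):
    k = np.arange(len(ctx["p_sum"]), dtype=np.float64)
    return float(k @ ctx["p_sum"])


def _f_sum_entropy(P, ctx):
    return float(-_xlogx(ctx["p_sum"]).sum())


def _f_sum_variance(P, ctx):
    # Haralick's original definition centers on the sum-entropy value
    se = _f_sum_entropy(P, ctx)
    k = np.arange(len(ctx["p_sum"]), dtype=np.float64)
    return float(((k - se) ** 2 @ ctx["p_sum"]))


def _f_difference_variance(P, ctx):
    pd = ctx["p_diff"]
    k = np.arange(len(pd), dtype=np.float64)
    mu = float(k @ pd)
    return float(((k - mu) ** 2 @ pd))


def _f_difference_entropy(P, ctx):
    return float(-_xlogx(ctx["p_diff"]).sum())


def _info_measures(P, ctx):
    px, py = ctx["px"], ctx["py"]
    hxy = -_xlogx(P).sum()
    pxpy = np.outer(px, py)
    # HXY1 = -sum p(i,j) log(px(i)py(j)); HXY2 = entropy of the product measure
    mask = (P > 0) & (pxpy > 0)
    hxy1 = -float((P[mask] * np.log(pxpy[mask])).sum())
    hxy2 = -float(_xlogx(pxpy).sum())
    hx = -float(_xlogx(px).sum())
    hy = -float(_xlogx(py).sum())
    return hxy, hxy1, hxy2, hx, hy


def _f_imc1(P, ctx):
    hxy, hxy1, _, hx, hy = _info_measures(P, ctx)
    denom = max(hx, hy)
    if denom <= 0:
        logger.warning("degenerate GLCM marginal: IMC1 denominator is 0, returning 0")
        return 0.0
    return float((hxy - hxy1) / denom)


def _f_imc2(P, ctx):
    hxy, _, hxy2, _, _ = _info_measures(P, ctx)
    return float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))


FEATURE_REGISTRY = {
    "autocorrelation": _f_autocorrelation,
    "max_probability": _f_max_probability,
    "dissimilarity": _f_dissimilarity,
    "entropy": _f_entropy,
    "cluster_shade": _f_cluster_shade,
    "cluster_prominence": _f_cluster_prominence,
    "homogeneity": _f_homogeneity,
    "contrast": _f_contrast,
    "sum_average": _f_sum_average,
    "sum_entropy": _f_sum_entropy,
    "sum_variance": _f_sum_variance,
    "difference_variance": _f_difference_variance,
    "difference_entropy": _f_difference_entropy,
    "imc1": _f_imc1,
    "imc2": _f_imc2,
}

#: the fixed 14-feature default: the 12 named features plus cluster
#: prominence and homogeneity as the completion of the set of fourteen.
DEFAULT_FEATURES: Tuple[str, ...] = (
    "autocorrelation", "max_probability", "dissimilarity", "entropy",
    "cluster_shade", "cluster_prominence", "homogeneity", "sum_average",
    "sum_entropy", "sum_variance", "difference_variance",
    "difference_entropy", "imc1", "imc2",
)


def glcm_feature_set(M: GLCMatrix,
                     feature_set: Iterable[str] = DEFAULT_FEATURES,
                     source: str = "orig") -> FeatureBlock:
    """Evaluate the configured co-occurrence features on a GLCM."""
    P = M.P
    ii, jj = np.meshgrid(np.arange(M.levels, dtype=np.float64),
                         np.arange(M.levels, dtype=np.float64), indexing="ij")
    _, px, py, mu_x, mu_y = _marginals(P)
    ctx = {"ii": ii, "jj": jj, "px": px, "py": py,
           "mu_x": mu_x, "mu_y": mu_y,
           "p_sum": _p_sum(P), "p_diff": _p_diff(P)}
    names, values = [], []
    for name in feature_set:
        if name not in FEATURE_REGISTRY:
            raise ValidationError(f"unknown GLCM feature {name!r}")
        names.append(f"glcm_{name}")
        values.append(FEATURE_REGISTRY[name](P, ctx))
    return FeatureBlock(names, values, source)
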