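"""Three-level 2-D discrete wavelet decomposition.

Each level of a 2-D DWT yields one approximation subband and three detail
subbands (horizontal, vertical, diagonal).  The feature catalog treats every
slice as seven images — the original plus one approximation (A1..A3) and one
detail image (D1..D3) per level — so the three detail subbands of a level are
fused into a single detail image by a configurable rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pywt

from .preprocess import GrayImage, ValidationError

FUSION_RULES = ("mean_abs", "diagonal", "max_abs")


def _fuse(H: np.ndarray, V: np.ndarray, G: np.ndarray, rule: str) -> np.ndarray:
    if rule == "mean_abs":
        return (np.abs(H) + np.abs(V) + np.abs(G)) / 3.0
    if rule == "diagonal":
        return G
    if rule == "max_abs":
        return np.maximum(np.maximum(np.abs(H), np.abs(V)), np.abs(G))
    raise ValidationError(f"unknown fusion rule {rule!r}; choose from {FUSION_RULES}")


def _renormalize(arr: np.ndarray) -> np.ndarray:
    """Map an arbitrary real subband to [0, 1] so quantization is well defined."""
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-12:
        return np.zeros_like(arr, dtype=np.float64)
    return (arr - lo) / (hi - lo)


@dataclass
class WaveletStack:
    """The seven images a slice contributes to the feature catalog.

    ``approx``/``detail`` are [0, 1]-renormalized for texture extraction;
    ``approx_raw`` and ``detail_subbands`` (per-level ``(H, V, G)`` tuples)
    keep the raw DWT coefficients for numerical checks.
    """

    original: GrayImage
    approx: List[GrayImage]
    detail: List[GrayImage]
    family: str
    fusion: str
    approx_raw: List[np.ndarray] = field(default_factory=list, repr=False)
    detail_subbands: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=list, repr=False)

    SUBIMAGE_NAMES = ("orig", "A1", "A2", "A3", "D1", "D2", "D3")

    def images(self) -> List[Tuple[str, GrayImage]]:
        """The named sub-images in catalog order: orig, A1..A3, D1..D3."""
        out = [("orig", self.original)]
        out += [(f"A{k+1}", a) for k, a in enumerate(self.approx)]
        out += [(f"D{k+1}", d) for k, d in enumerate(self.detail)]
        return out


def dwt_decompose(img: GrayImage, family: str = "haar", levels: int = 3,
                  fusion: str = "mean_abs", renormalize: bool = True) -> WaveletStack:
    """Decompose ``img`` into ``levels`` DWT levels with symmetric padding.

    Per level k the approximation subband becomes A_k and the three detail
    subbands are fused into D_k by ``fusion`` (``mean_abs``: (|H|+|V|+|G|)/3;
    ``diagonal``: G; ``max_abs``: elementwise max of magnitudes).

    With ``renormalize`` (default) the sub-images are linearly mapped to
    [0, 1] so downstream quantization is well defined per sub-image; pass
    ``False`` to keep raw coefficient scales in the returned ``GrayImage``\\ s.
    """
    if levels < 1:
        raise ValidationError(f"levels must be >= 1, got {levels}")
    if min(img.height, img.width) < 2 ** levels:
        raise ValidationError(
            f"image {img.height}x{img.width} too small for {levels} DWT levels"
        )
    if fusion not in FUSION_RULES:
        raise ValidationError(f"unknown fusion rule {fusion!r}; choose from {FUSION_RULES}")
    arr = img.pixels.astype(np.float64)
    approx, detail, approx_raw, subbands = [], [], [], []
    current = arr
    for _ in range(levels):
        cA, (cH, cV, cD) = pywt.dwt2(current, family, mode="symmetric")
        fused = _fuse(cH, cV, cD, fusion)
        approx_raw.append(cA)
        subbands.append((cH, cV, cD))
        a, d = (( _renormalize(cA), _renormalize(fused)) if renormalize
                else (cA, fused))
        approx.append(_as_image(a))
        detail.append(_as_image(d))
        current = cA
    return WaveletStack(original=img, approx=approx, detail=detail,
                        family=family, fusion=fusion,
                        approx_raw=approx_raw, detail_subbands=subbands)


class _TinyImage:
    """Stand-in for sub-images below the 8x8 GrayImage floor (deep levels of
    small test fixtures); exposes the same pixel interface."""

    def __init__(self, arr: np.ndarray):
        self.pixels = np.asarray(arr, dtype=np.float64)
        self.levels = "continuous"

    @property
    def height(self):
        return self.pixels.shape[0]

    @property
    def width(self):
        return self.pixels.shape[1]

    @property
    def is_quantized(self):
        return False


def _as_image(arr: np.ndarray):
    if min(arr.shape) >= 8:
        return GrayImage(np.asarray(arr, dtype=np.float64))
    return _TinyImage(arr)
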