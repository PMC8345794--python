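"""Assembly of the fused feature catalog.

Per image: a 3-level DWT yields 7 sub-images (orig, A1..A3, D1..D3); each
contributes 14 co-occurrence features, 11 run-length features and
5 x len(angles) bispectral features.  At the default 1..180-degree angle
grid the catalog holds 25 x 7 + 5 x 180 x 7 = 175 + 6300 = 6475 columns.
Column order is fixed: the GLCM block, then GLRLM, then HOS, each iterating
sub-images in the order orig, A1, A2, A3, D1, D2, D3.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import GrayImage, ValidationError
from .wavelets import dwt_decompose
from . import glcm as _glcm
from . import glrlm as _glrlm
from . import hos as _hos


def catalog_size(n_angles: int = 180, n_glcm: int = 14, n_glrlm: int = 11,
                 n_hos: int = 5, n_subimages: int = 7) -> int:
    return (n_glcm + n_glrlm) * n_subimages + n_hos * n_angles * n_subimages


def extract_features(img: GrayImage, *,
                     family: str = "haar", levels: int = 3,
                     fusion: str = "mean_abs",
                     glcm_levels: int = 8, glcm_distance: int = 1,
                     glcm_angles: Sequence[int] = (0, 45, 90, 135),
                     glcm_features: Sequence[str] = _glcm.DEFAULT_FEATURES,
                     glrlm_levels: int = 8,
                     glrlm_directions: Sequence[int] = _glrlm.DIRECTIONS,
                     hos_angles: Sequence[float] = _hos.DEFAULT_ANGLES,
                     nfft: int = 256, phase_bins: int = 64) -> pd.Series:
    """The full fused feature vector of one preprocessed image.

    Returns a Series indexed by ``<extractor>_<feature>[_theta<k>]_<subimage>``.
    """
    stack = dwt_decompose(img, family=family, levels=levels, fusion=fusion)
    subimages = stack.images()

    names: List[str] = []
    values: List[float] = []
    # GLCM block
    for sub_name, sub in subimages:
        q = _glcm.quantize(sub, glcm_levels)
        M = _glcm.glcm_matrix(q, distance=glcm_distance, angles=glcm_angles)
        blk = _glcm.glcm_feature_set(M, glcm_features, source=sub_name)
        names.extend(f"{n}_{sub_name}" for n in blk.names)
        values.extend(blk.values)
    # GLRLM block
    for sub_name, sub in subimages:
        q = _glcm.quantize(sub, glrlm_levels)
        blk = _glrlm.glrlm_features_averaged(q, glrlm_directions, source=sub_name)
        names.extend(f"{n}_{sub_name}" for n in blk.names)
        values.extend(blk.values)
    # HOS block
    for sub_name, sub in subimages:
        blk = _hos.hos_block(sub, angles=hos_angles, nfft=nfft,
                             phase_bins=phase_bins, source=sub_name)
        names.extend(f"{n}_{sub_name}" for n in blk.names)
        values.extend(blk.values)

    expected = catalog_size(n_angles=len(hos_angles),
                            n_glcm=len(tuple(glcm_features)))
    if len(values) != expected:
        raise ValidationError(
            f"catalog arithmetic violated: {len(values)} != {expected}")
    return pd.Series(values, index=names, dtype=np.float64)


def extract_feature_matrix(images: Sequence[GrayImage],
                           **kwargs) -> pd.DataFrame:
    """Feature rows for a sequence of preprocessed images."""
    rows = [extract_features(img, **kwargs) for img in images]
    return pd.DataFrame(rows).reset_index(drop=True)
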