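"""Image loading, resizing and contrast-limited adaptive histogram equalization.

All downstream texture extractors consume :class:`GrayImage`, a thin wrapper
around a 2-D float array normalized to [0, 1].  Quantization to discrete gray
levels is deferred to the extractors (see :mod:`stroketex.glcm`), so a
``GrayImage`` is either *continuous* (``levels == "continuous"``) or carries
the number of discrete levels it was binned to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.transform import resize as _sk_resize


class ValidationError(ValueError):
    """An input violates a documented precondition."""


CONTINUOUS = "continuous"

_RESIZE_ORDERS = {"nearest": 0, "bilinear": 1, "bicubic": 3}


@dataclass
class GrayImage:
    """A 2-D grayscale image with quantization metadata.

    Parameters
    ----------
    pixels
        2-D array.  Continuous images hold floats in [0, 1]; quantized images
        hold integers in {0, ..., levels-1}.
    levels
        ``"continuous"`` or the number of discrete gray levels.
    """

    pixels: np.ndarray
    levels: Union[int, str] = CONTINUOUS

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.height < 8 or self.width < 8:
            raise ValidationError(
                f"image must be at least 8x8, got {self.height}x{self.width}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("image contains non-finite intensities")
        if self.levels != CONTINUOUS:
            lv = int(self.levels)
            if not (np.issubdtype(self.pixels.dtype, np.integer)
                    or np.all(self.pixels == np.round(self.pixels))):
                raise ValidationError("quantized image must hold integer levels")
            if self.pixels.min() < 0 or self.pixels.max() > lv - 1:
                raise ValidationError("quantized values outside {0..levels-1}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_quantized(self) -> bool:
        return self.levels != CONTINUOUS


def load_gray(path: Union[str, Path]) -> GrayImage:
    """Load a raster image as a [0, 1] grayscale :class:`GrayImage`.

    Multi-channel inputs are collapsed by the per-pixel channel mean;
    integer images are scaled by the dtype maximum (255 for 8-bit,
    65535 for 16-bit), floats are clipped to [0, 1].
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise IOError(f"could not read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    scale = np.iinfo(arr.dtype).max if np.issubdtype(arr.dtype, np.integer) else None
    if arr.ndim == 3:
        # luminance by channel average; drop a trailing alpha channel first
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64).mean(axis=2)
    elif arr.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {arr.ndim}: {path}")
    if scale is not None:
        arr = arr.astype(np.float64) / scale
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return GrayImage(arr)


def resize_to_square(img: GrayImage, size: int = 200,
                     interpolation: str = "bilinear") -> GrayImage:
    """Resize to ``size`` x ``size``, keeping intensities in [0, 1].

    A no-op when the image already has the target shape, which makes the
    operation idempotent at fixed size.
    """
    if size < 8:
        raise ValidationError(f"target size must be >= 8, got {size}")
    if interpolation not in _RESIZE_ORDERS:
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    if img.pixels.shape == (size, size):
        return GrayImage(img.pixels.copy(), img.levels)
    shrinking = size < max(img.height, img.width)
    out = _sk_resize(
        img.pixels.astype(np.float64), (size, size),
        order=_RESIZE_ORDERS[interpolation],
        anti_aliasing=shrinking and _RESIZE_ORDERS[interpolation] > 0,
        preserve_range=True,
    )
    return GrayImage(np.clip(out, 0.0, 1.0))


def clahe(img: GrayImage, tile: int = 8, clip: float = 0.01,
          nbins: int = 256, tile_mode: str = "pixels") -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    Parameters
    ----------
    tile
        With ``tile_mode="pixels"`` (default) the side length in pixels of the
        non-overlapping tiles (8 gives a 25x25 tile grid on a 200x200 image);
        with ``tile_mode="grid"`` the number of tiles per axis.
    clip
        Normalized clip limit (fraction of the per-tile histogram), preventing
        over-saturation in uniform regions.
    """
    if img.is_quantized:
        raise ValidationError("clahe expects a continuous [0,1] image")
    if tile_mode == "pixels":
        kernel = int(tile)
    elif tile_mode == "grid":
        kernel = (max(1, img.height // int(tile)), max(1, img.width // int(tile)))
        kernel = tuple(kernel)
    else:
        raise ValidationError(f"unknown tile_mode {tile_mode!r}")
    ksz = kernel if isinstance(kernel, int) else max(kernel)
    if ksz > min(img.height, img.width):
        raise ValidationError(
            f"tile size {ksz} exceeds image extent {img.height}x{img.width}"
        )
    out = equalize_adapthist(img.pixels, kernel_size=kernel, clip_limit=clip,
                             nbins=nbins)
    return GrayImage(np.clip(out, 0.0, 1.0))
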