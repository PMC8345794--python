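"""Higher-order-spectra features from Radon projections of an image.

The image is projected onto 1-D signals at angles 1..180 degrees; each
projection's bispectrum B(f1, f2) = X(f1) X(f2) X*(f1+f2) is estimated by a
direct single-segment FFT product and summarized over the non-redundant
triangular region Omega = {0 <= f2 <= f1, f1 + f2 <= fs/2} by five features:
three normalized bispectral entropies (on |B|, |B|^2, |B|^3), a phase
entropy, and the mean bispectral magnitude.  Quadratic phase coupling in the
underlying texture concentrates |B| at the coupled frequency pair, which the
entropies pick up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from skimage.transform import radon

from .preprocess import ValidationError
from .glcm import FeatureBlock

HOS_FEATURES = ("ent1", "ent2", "ent3", "phase_ent", "mean_mag")
DEFAULT_ANGLES = tuple(range(1, 181))


@dataclass
class ProjectionSignal:
    """A 1-D line-integral projection of a mean-subtracted image."""

    samples: np.ndarray
    angle: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size < 8:
            raise ValidationError("projection must have at least 8 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("projection contains non-finite samples")

    @property
    def length(self) -> int:
        return self.samples.size


@dataclass
class BispectrumEstimate:
    """Direct bispectrum estimate on the quarter-plane grid 0..fs/2.

    ``B[f1, f2]`` covers 0 <= f1, f2 <= nfft/2 (symmetric by construction);
    ``omega`` masks the non-redundant triangle f2 <= f1, f1 + f2 <= nfft/2.
    """

    B: np.ndarray
    nfft: int
    omega: np.ndarray

    def region(self) -> np.ndarray:
        """The complex bispectrum values on Omega (flattened)."""
        return self.B[self.omega]


def _circle_mask(shape) -> np.ndarray:
    # inscribed circle with the same center/radius convention as the radon
    # transform's reconstruction circle
    h, w = shape
    r = min(h, w) // 2
    yy, xx = np.ogrid[:h, :w]
    return (yy - h // 2) ** 2 + (xx - w // 2) ** 2 <= r * r


def radon_projection(img, angle: float) -> ProjectionSignal:
    """Project the mean-subtracted image onto the axis at ``angle`` degrees.

    The projection integrates over the inscribed circle of the image (values
    outside are zeroed), so its length equals the shorter image side.  The
    angle follows the axis convention in which a vertical structure projects
    most sharply at 90 degrees.
    """
    return _projections(img, [angle])[0]


def _projections(img, angles: Sequence[float]) -> List[ProjectionSignal]:
    """All projections in one sinogram call (faster than per-angle radon)."""
    arr = np.asarray(img.pixels, dtype=np.float64)
    mask = _circle_mask(arr.shape)
    centered = np.where(mask, arr - arr[mask].mean(), 0.0)
    # +90: the library's theta=0 integrates along columns; our angle measures
    # the projection axis so that a vertical bar peaks at 90 degrees
    sino = radon(centered, theta=[float(a) + 90.0 for a in angles], circle=True)
    return [ProjectionSignal(sino[:, k], float(a)) for k, a in enumerate(angles)]


def bispectrum_direct(sig: ProjectionSignal, nfft: int = 256) -> BispectrumEstimate:
    """Single-segment direct bispectrum of a projection (rectangular window).

    The signal is zero-padded to ``nfft``; B(f1,f2) = X(f1) X(f2) X*(f1+f2)
    is evaluated on the quarter-plane 0..nfft/2 per axis.
    """
    if sig.length > nfft:
        raise ValidationError(
            f"signal length {sig.length} exceeds nfft {nfft}")
    X = np.fft.fft(sig.samples, nfft)
    half = nfft // 2
    f1 = np.arange(half + 1)[:, None]
    f2 = np.arange(half + 1)[None, :]
    B = X[f1] * X[f2] * np.conj(X[(f1 + f2) % nfft])
    omega = (f2 <= f1) & (f1 + f2 <= half)
    return BispectrumEstimate(B, nfft, omega)


def _norm_entropy(weights: np.ndarray) -> float:
    """Shannon entropy (nats) of weights normalized to a distribution."""
    total = weights.sum()
    if total <= 0:
        return 0.0
    p = weights / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def hos_feature_set(B: BispectrumEstimate, phase_bins: int = 64,
                    source: str = "orig", angle_tag: str = "") -> FeatureBlock:
    """The five bispectral features over the non-redundant region.

    An all-zero bispectrum yields (0, 0, 0, 0, 0) by convention; the phase
    histogram excludes zero-magnitude points (their phase is undefined).
    """
    vals = B.region()
    mag = np.abs(vals)
    ent1 = _norm_entropy(mag)
    ent2 = _norm_entropy(mag ** 2)
    ent3 = _norm_entropy(mag ** 3)
    nz = mag > 0
    if nz.any():
        phases = np.angle(vals[nz])  # in (-pi, pi]
        edges = np.linspace(-np.pi, np.pi, phase_bins + 1)
        hist, _ = np.histogram(phases, bins=edges)
        phase_ent = _norm_entropy(hist.astype(np.float64))
        mean_mag = float(mag.mean())
    else:
        phase_ent = 0.0
        mean_mag = 0.0
    names = [f"hos_{f}{angle_tag}" for f in HOS_FEATURES]
    return FeatureBlock(names, [ent1, ent2, ent3, phase_ent, mean_mag], source)


def hos_block(img, angles: Sequence[float] = DEFAULT_ANGLES, nfft: int = 256,
              phase_bins: int = 64, source: str = "orig") -> FeatureBlock:
    """All five HOS features at every projection angle: 5 x len(angles) values.

    With the default 1..180 degree grid this is 900 features per sub-image,
    named ``hos_<feature>_theta<k>``.
    """
    names: List[str] = []
    values: List[float] = []
    for sig in _projections(img, angles):
        blk = hos_feature_set(bispectrum_direct(sig, nfft), phase_bins,
                              source, angle_tag=f"_theta{int(sig.angle)}")
        names.extend(blk.names)
        values.extend(blk.values)
    return FeatureBlock(names, values, source)
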