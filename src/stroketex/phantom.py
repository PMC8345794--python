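"""Synthetic three-class stroke phantoms.

Stands in for clinical diffusion-weighted MRI slices, which cannot be
redistributed: each phantom is a smoothed Gaussian random-field background
inside an elliptical "brain" mask plus one elliptical lesion.  Class
identity is encoded in texture statistics rather than global intensity —
the background correlation length and the lesion size/contrast/location
differ by class (LACS: small high-contrast deep lesion; PACS: medium
off-center cortical lesion; TACS: large lesion covering a quarter or more
of the brain mask) — so the co-occurrence, run-length and bispectral
extractors are genuinely exercised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import GrayImage, ValidationError
from .balance import LabeledSet

CLASSES = ("LACS", "PACS", "TACS")


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom image."""

    cls: str = "PACS"
    size: int = 200
    corr_length: float = 4.0     # background correlation length, pixels
    lesion_radius: float = 20.0  # mean lesion semi-axis, pixels
    lesion_contrast: float = 0.25
    lesion_eccentricity: float = 0.3
    lesion_offset: float = 0.25  # lesion center offset, fraction of size
    noise_std: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValidationError(f"unknown class {self.cls!r}")
        if self.lesion_radius >= self.size / 2:
            raise ValidationError("lesion radius must be < size/2")
        if self.noise_std < 0:
            raise ValidationError("noise std must be >= 0")


#: class-specific defaults: texture correlation length and lesion geometry
CLASS_DEFAULTS: Dict[str, Dict[str, float]] = {
    # small, high-contrast, deep (central) lesion; fine background texture
    "LACS": dict(corr_length=2.0, lesion_radius=8.0, lesion_contrast=0.35,
                 lesion_eccentricity=0.15, lesion_offset=0.06),
    # medium, moderate-contrast, off-center lesion; medium texture scale
    "PACS": dict(corr_length=4.0, lesion_radius=20.0, lesion_contrast=0.25,
                 lesion_eccentricity=0.3, lesion_offset=0.22),
    # large hemispheric lesion covering >= 25% of the brain mask
    "TACS": dict(corr_length=6.0, lesion_radius=48.0, lesion_contrast=0.20,
                 lesion_eccentricity=0.35, lesion_offset=0.10),
}


def default_spec(cls: str, seed: int = 0, size: int = 200) -> PhantomSpec:
    """Class defaults at the working resolution; lesion geometry and texture
    scale are defined on a 200-pixel canvas and scale with ``size``."""
    if cls not in CLASS_DEFAULTS:
        raise ValidationError(f"unknown class {cls!r}")
    params = dict(CLASS_DEFAULTS[cls])
    scale = size / 200.0
    params["lesion_radius"] *= scale
    params["corr_length"] = max(1.0, params["corr_length"] * scale)
    return PhantomSpec(cls=cls, size=size, seed=seed, **params)


def _brain_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size]
    cy = cx = (size - 1) / 2.0
    a, b = 0.45 * size, 0.38 * size  # semi-axes of the "brain" ellipse
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def lesion_mask(spec: PhantomSpec) -> np.ndarray:
    """The elliptical lesion support of a spec (thresholded geometry)."""
    size = spec.size
    rng = np.random.default_rng(spec.seed + 7919)  # placement substream
    yy, xx = np.mgrid[:size, :size]
    cy = cx = (size - 1) / 2.0
    ang = rng.uniform(0, np.pi)
    off = spec.lesion_offset * size
    ly = cy + off * np.sin(ang)
    lx = cx + off * np.cos(ang)
    ecc = spec.lesion_eccentricity
    ra = spec.lesion_radius * (1 + ecc)
    rb = spec.lesion_radius * (1 - ecc)
    rot = rng.uniform(0, np.pi)
    u = (yy - ly) * np.cos(rot) + (xx - lx) * np.sin(rot)
    v = -(yy - ly) * np.sin(rot) + (xx - lx) * np.cos(rot)
    return ((u / ra) ** 2 + (v / rb) ** 2 <= 1.0) & _brain_mask(size)


def make_phantom(spec: PhantomSpec, with_lesion: bool = True) -> GrayImage:
    """Deterministic phantom image for a spec (same spec+seed => identical)."""
    size = spec.size
    rng = np.random.default_rng(spec.seed)
    field = rng.standard_normal((size, size))
    if spec.corr_length > 0:
        field = gaussian_filter(field, spec.corr_length)
    sd = field.std()
    if sd > 0:
        field = field / sd
    brain = _brain_mask(size)
    img = np.where(brain, 0.45 + 0.12 * field, 0.02)
    if with_lesion:
        lm = lesion_mask(spec)
        # soften the lesion edge so it blends like a diffusion hyperintensity
        soft = gaussian_filter(lm.astype(np.float64), 2.0)
        img = img + spec.lesion_contrast * soft
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, (size, size))
    return GrayImage(np.clip(img, 0.0, 1.0))


def make_dataset(n_per_class: Sequence[int], base_seed: int = 42,
                 out_dir=None, size: int = 200
                 ) -> Tuple[LabeledSet, List[Dict[str, str]]]:
    """Generate phantoms for (LACS, PACS, TACS) counts.

    Returns the flattened-image :class:`LabeledSet` plus manifest rows
    ``{"path", "label"}``.  When ``out_dir`` is given, 8-bit PNGs and a
    ``manifest.csv`` with columns ``path,label`` are written there.
    """
    if len(n_per_class) != len(CLASSES):
        raise ValidationError(f"need one count per class {CLASSES}")
    if any(n < 1 for n in n_per_class):
        raise ValidationError("counts must be >= 1")
    items, labels, rows = [], [], []
    images: List[GrayImage] = []
    idx = 0
    for cls, n in zip(CLASSES, n_per_class):
        for j in range(n):
            spec = default_spec(cls, seed=base_seed * 100003 + idx, size=size)
            img = make_phantom(spec)
            images.append(img)
            items.append(img.pixels.ravel())
            labels.append(cls)
            rows.append({"path": f"{cls}_{j:04d}.png", "label": cls})
            idx += 1
    data = LabeledSet(np.asarray(items), np.asarray(labels))
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            for img, row in zip(images, rows):
                arr8 = np.round(img.pixels * 255).astype(np.uint8)
                iio.imwrite(out / row["path"], arr8)
            with open(out / "manifest.csv", "w", newline="") as fh:
                w = csv.DictWriter(fh, fieldnames=["path", "label"])
                w.writeheader()
                w.writerows(rows)
        except OSError as exc:
            raise IOError(f"cannot write dataset to {out}: {exc}") from exc
    return data, rows


def class_shares(rows: Sequence[Dict[str, str]]) -> Dict[str, float]:
    """Percentage share of each class in a manifest, 2-decimal rounding."""
    total = len(rows)
    shares = {}
    for cls in CLASSES:
        n = sum(1 for r in rows if r["label"] == cls)
        shares[cls] = round(100.0 * n / total + 1e-12, 2)
    return shares
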