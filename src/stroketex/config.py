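"""Pipeline configuration: nested keys, YAML round-trip, seed substreams."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from .preprocess import ValidationError

#: defaults for every stage, keyed exactly as the YAML config file
DEFAULTS: Dict[str, Any] = {
    "preprocess": {"size": 200, "tile_pixels": 8, "clip_limit": 0.01},
    "wavelets": {"family": "haar", "levels": 3, "fusion": "mean_abs"},
    "glcm": {"levels": 8, "distance": 1, "angles": [0, 45, 90, 135],
             "feature_set": None},  # None -> the default 14-feature set
    "glrlm": {"levels": 8, "directions": [0, 45, 90, 135]},
    "hos": {"nfft": 256, "phase_bins": 64, "angles": None},  # None -> 1..180
    "balance": {"k": 5, "beta": 1.0, "space": "images", "enabled": True},
    "ranking": {"mode": "per_fold"},
    "svm": {"kernels": ["linear", "poly2", "poly3", "rbf"], "c": 1.0,
            "gamma": "scale"},
    "cv": {"folds": 10, "collapse": "majority_ref", "reference_class": None},
    "sfs": {"max_features": 50, "patience": 5, "internal_folds": 5},
    "seed": 42,
    "out_dir": "stroketex_out",
}


def _merge(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k not in out:
            raise ValidationError(f"unknown config key {k!r}")
        if isinstance(out[k], dict) and isinstance(v, dict):
            for kk, vv in v.items():
                if kk not in out[k]:
                    raise ValidationError(f"unknown config key {k}.{kk}")
                out[k][kk] = vv
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Validated, serializable configuration of the whole pipeline."""

    values: Dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_dict(cls, d: Optional[Dict[str, Any]] = None) -> "PipelineConfig":
        return cls(_merge(DEFAULTS, d or {}))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def seed_for(self, stream: str) -> int:
        """A named deterministic substream of the run seed (below 2^31)."""
        streams = {"phantom": 1, "balance": 2, "cv": 3, "sfs": 4}
        if stream not in streams:
            raise ValidationError(f"unknown seed stream {stream!r}")
        return (int(self.values["seed"]) * 7919 + streams[stream]) % (2 ** 31)

    @property
    def hos_angles(self) -> List[float]:
        angles = self.values["hos"]["angles"]
        if angles is None:
            return list(range(1, 181))
        return list(angles)
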