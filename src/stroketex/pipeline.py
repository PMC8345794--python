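"""End-to-end orchestration: manifest -> preprocess -> balance -> features
-> ranking -> cross-validated SVM evaluation -> reports on disk."""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import glcm as _glcm
from .balance import LabeledSet, adasyn_oversample
from .config import PipelineConfig
from .features import extract_feature_matrix
from .model_eval import CVReport, KernelSpec, cross_validate
from .preprocess import GrayImage, ValidationError, clahe, load_gray, resize_to_square
from .ranking import rank_features

logger = logging.getLogger(__name__)


def read_manifest(path) -> List[Tuple[Path, str]]:
    """Read a `path,label` manifest CSV; paths are relative to the CSV."""
    path = Path(path)
    rows: List[Tuple[Path, str]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
            raise ValidationError(f"manifest {path} needs columns path,label")
        for r in reader:
            rows.append((path.parent / r["path"], r["label"]))
    if not rows:
        raise ValidationError(f"manifest {path} is empty")
    return rows


def preprocess_image(img: GrayImage, cfg: PipelineConfig) -> GrayImage:
    pp = cfg["preprocess"]
    img = resize_to_square(img, pp["size"])
    return clahe(img, tile=pp["tile_pixels"], clip=pp["clip_limit"])


def _stage(name):
    """Wrap stage errors with the stage name for diagnosable failures."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def extract_for_config(images: Sequence[GrayImage],
                       cfg: PipelineConfig) -> pd.DataFrame:
    g, r, h, w = cfg["glcm"], cfg["glrlm"], cfg["hos"], cfg["wavelets"]
    return extract_feature_matrix(
        images,
        family=w["family"], levels=w["levels"], fusion=w["fusion"],
        glcm_levels=g["levels"], glcm_distance=g["distance"],
        glcm_angles=tuple(g["angles"]),
        glcm_features=tuple(g["feature_set"] or _glcm.DEFAULT_FEATURES),
        glrlm_levels=r["levels"],
        glrlm_directions=tuple(cfg["glrlm"]["directions"]),
        hos_angles=tuple(cfg.hos_angles),
        nfft=h["nfft"], phase_bins=h["phase_bins"],
    )


def run_pipeline(cfg: PipelineConfig, manifest: Optional[str] = None,
                 images: Optional[Sequence[GrayImage]] = None,
                 labels: Optional[Sequence[str]] = None,
                 out_dir=None) -> Dict:
    """Run the full pipeline and write feature/ranking/CV reports.

    Input is either a manifest CSV or in-memory images+labels.  Returns a
    run report with the per-kernel summaries and output file paths.
    """
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        if manifest is not None:
            rows = read_manifest(manifest)
            images = [load_gray(p) for p, _ in rows]
            labels = [lab for _, lab in rows]
        if images is None or labels is None:
            raise ValidationError("provide a manifest or images+labels")
        labels = np.asarray(labels)

    with _stage("preprocess"):
        pre = [preprocess_image(img, cfg) for img in images]

    bal = cfg["balance"]
    if bal["enabled"] and bal["space"] == "images":
        with _stage("balance"):
            size = cfg["preprocess"]["size"]
            flat = LabeledSet(np.stack([p.pixels.ravel() for p in pre]), labels)
            balanced = adasyn_oversample(flat, k=bal["k"], beta=bal["beta"],
                                         seed=cfg.seed_for("balance"))
            pre = [GrayImage(v.reshape(size, size)) for v in balanced.items]
            labels = balanced.labels

    with _stage("features"):
        feat = extract_for_config(pre, cfg)
        feat_path = out / "features.csv"
        feat.assign(label=labels).to_csv(feat_path, index=False)

    with _stage("ranking"):
        ranked = rank_features(feat.to_numpy(), labels)
        rank_path = out / "ranking.csv"
        pd.DataFrame({
            "feature": feat.columns[ranked.order],
            "f_value": ranked.f_values[ranked.order],
            "p_value": ranked.p_values[ranked.order],
            "rank": np.arange(1, len(ranked.order) + 1),
        }).to_csv(rank_path, index=False)

    oversample = None
    if bal["enabled"] and bal["space"] == "features":
        def oversample(X, y, fold_seed):
            res = adasyn_oversample(LabeledSet(X, y), k=bal["k"],
                                    beta=bal["beta"], seed=fold_seed)
            return res.items, res.labels

    reports: Dict[str, CVReport] = {}
    with _stage("evaluate"):
        for kind in cfg["svm"]["kernels"]:
            kernel = KernelSpec(kind=kind, C=cfg["svm"]["c"],
                                gamma=cfg["svm"]["gamma"])
            rep = cross_validate(
                feat.to_numpy(), labels, kernel,
                folds=cfg["cv"]["folds"], seed=cfg.seed_for("cv"),
                collapse=cfg["cv"]["collapse"],
                reference_class=cfg["cv"]["reference_class"],
                rank_mode=cfg["ranking"]["mode"], ranked=ranked,
                max_features=cfg["sfs"]["max_features"],
                patience=cfg["sfs"]["patience"],
                internal_folds=cfg["sfs"]["internal_folds"],
                oversample=oversample)
            reports[kind] = rep
            with open(out / f"cvreport_{kind}.json", "w") as fh:
                json.dump(rep.as_dict(), fh, indent=2)
            _write_fold_table(rep, out / f"folds_{kind}.csv")

    with _stage("compare"):
        cmp_path = out / "comparison.csv"
        with open(cmp_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["classifier", "acc", "ppv", "sen", "spe", "dice"])
            for kind, rep in reports.items():
                s = rep.summary
                w.writerow([kind, s.acc, s.ppv, s.sen, s.spe, s.dice])

    return {
        "n_images": int(len(labels)),
        "n_features": int(feat.shape[1]),
        "summaries": {k: r.summary.as_dict() for k, r in reports.items()},
        "outputs": {"features": str(feat_path), "ranking": str(rank_path),
                    "comparison": str(cmp_path)},
    }


def _write_fold_table(rep: CVReport, path) -> None:
    """Flat per-fold table: counts, metrics, and an averaged last row."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["TP", "TN", "FP", "FN", "ACC", "PPV", "SEN", "SPE", "Dice"])
        for c, m in rep.folds:
            w.writerow([c.TP, c.TN, c.FP, c.FN, m.acc, m.ppv, m.sen, m.spe, m.dice])
        t, s = rep.total_counts, rep.summary
        w.writerow([t.TP, t.TN, t.FP, t.FN, s.acc, s.ppv, s.sen, s.spe, s.dice])
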