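"""SVM evaluation: sequential forward selection, 10-fold CV and metric
arithmetic.

Per-fold binary confusion counts are obtained from the 3-class task by
micro-averaged one-vs-rest collapse (TP sums the per-class true positives,
and so on).  ACC, PPV, SEN and SPE are percentages; the Dice score
2TP/(2TP+FP+FN) is a ratio in [0, 1] and equals the harmonic mean of PPV
and SEN.  All reported values are rounded half-up to 2 decimals with exact
rational arithmetic, and fold averages are arithmetic means of the per-fold
rounded values, rounded the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import ValidationError
from .ranking import RankedFeatures, rank_features

logger = logging.getLogger(__name__)

KERNELS = ("linear", "poly2", "poly3", "rbf")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name} must be a non-negative integer")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValidationError("all confusion counts are zero")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class Metrics:
    """Percentages (2-decimal) for ACC/PPV/SEN/SPE and the Dice ratio.

    A metric whose denominator is zero is marked undefined (``None``)
    rather than silently reported as 0.
    """

    acc: Optional[float]
    ppv: Optional[float]
    sen: Optional[float]
    spe: Optional[float]
    dice: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {"acc": self.acc, "ppv": self.ppv, "sen": self.sen,
                "spe": self.spe, "dice": self.dice}


def _round2(x: Fraction) -> float:
    """Round a non-negative rational half-up to 2 decimals, exactly."""
    return float((x.numerator * 100 * 2 + x.denominator) // (2 * x.denominator)) / 100.0


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    """ACC/PPV/SEN/SPE as 2-decimal percentages and Dice as a 2-decimal ratio."""

    def pct(num: int, den: int) -> Optional[float]:
        if den == 0:
            return None
        return _round2(Fraction(100 * num, den))

    acc = pct(c.TP + c.TN, c.total)
    ppv = pct(c.TP, c.TP + c.FP)
    sen = pct(c.TP, c.TP + c.FN)
    spe = pct(c.TN, c.TN + c.FP)
    dice_den = 2 * c.TP + c.FP + c.FN
    dice = None if dice_den == 0 else _round2(Fraction(2 * c.TP, dice_den))
    return Metrics(acc, ppv, sen, spe, dice)


def _exact_metrics(c: ConfusionCounts) -> Dict[str, Optional[Fraction]]:
    """Unrounded rational metrics of one fold (None where undefined)."""

    def frac(num: int, den: int, scale: int) -> Optional[Fraction]:
        return None if den == 0 else Fraction(scale * num, den)

    return {
        "acc": frac(c.TP + c.TN, c.total, 100),
        "ppv": frac(c.TP, c.TP + c.FP, 100),
        "sen": frac(c.TP, c.TP + c.FN, 100),
        "spe": frac(c.TN, c.TN + c.FP, 100),
        "dice": frac(2 * c.TP, 2 * c.TP + c.FP + c.FN, 1),
    }


def aggregate_folds(folds: Sequence[Tuple[ConfusionCounts, Metrics]]
                    ) -> Tuple[Metrics, ConfusionCounts]:
    """Fold-averaged metrics and the summed confusion counts.

    The mean is taken over the exact (unrounded) per-fold metric values
    recomputed from the counts, then rounded half-up to 2 decimals — the
    per-fold display rounding does not propagate into the average.
    """
    if not folds:
        raise ValidationError("need at least one fold")
    exact = [_exact_metrics(c) for c, _ in folds]

    def mean2(key: str) -> Optional[float]:
        present = [e[key] for e in exact if e[key] is not None]
        if not present:
            return None
        return _round2(sum(present, Fraction(0)) / len(present))

    summary = Metrics(**{k: mean2(k) for k in ("acc", "ppv", "sen", "spe", "dice")})
    totals = ConfusionCounts(
        TP=sum(c.TP for c, _ in folds), TN=sum(c.TN for c, _ in folds),
        FP=sum(c.FP for c, _ in folds), FN=sum(c.FN for c, _ in folds))
    return summary, totals


@dataclass
class KernelSpec:
    """One of the four SVM kernels: linear, poly2, poly3 or rbf."""

    kind: str = "rbf"
    C: float = 1.0
    gamma: object = "scale"  # rbf/poly: 1/(n_features * X.var()) by default
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNELS:
            raise ValidationError(f"unknown kernel {self.kind!r}; choose from {KERNELS}")
        if self.C <= 0:
            raise ValidationError("C must be positive")

    @property
    def degree(self) -> int:
        return {"linear": 1, "poly2": 2, "poly3": 3, "rbf": 0}[self.kind]

    def make_svc(self) -> SVC:
        if self.kind == "linear":
            return SVC(kernel="linear", C=self.C)
        if self.kind in ("poly2", "poly3"):
            return SVC(kernel="poly", degree=self.degree, coef0=self.coef0,
                       gamma=self.gamma, C=self.C)
        return SVC(kernel="rbf", gamma=self.gamma, C=self.C)


def svm_fit_predict(train: np.ndarray, train_labels: Sequence,
                    test: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Standardize on the training split, fit the SVM, predict ``test``.

    Multiclass decisions use one-vs-one voting (the SVC default); the result
    is deterministic for fixed inputs and kernel.
    """
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValidationError("training data contains a single class")
    model = make_pipeline(StandardScaler(), kernel.make_svc())
    model.fit(np.asarray(train, dtype=np.float64), train_labels)
    return model.predict(np.asarray(test, dtype=np.float64))


def _internal_accuracy(X: np.ndarray, y: np.ndarray, cols: List[int],
                       kernel: KernelSpec, n_splits: int) -> float:
    """Stratified internal CV accuracy of the column subset ``cols``."""
    _, counts = np.unique(y, return_counts=True)
    k = min(n_splits, counts.min())
    if k < 2:
        # degenerate split: fall back to training accuracy
        pred = svm_fit_predict(X[:, cols], y, X[:, cols], kernel)
        return float((pred == y).mean())
    skf = StratifiedKFold(n_splits=k, shuffle=False)
    correct = 0
    for tr, va in skf.split(X, y):
        pred = svm_fit_predict(X[np.ix_(tr, cols)], y[tr],
                               X[np.ix_(va, cols)], kernel)
        correct += int((pred == y[va]).sum())
    return correct / len(y)


def sfs_select(train_matrix: np.ndarray, train_labels: Sequence,
               ranked: RankedFeatures, kernel: KernelSpec,
               max_features: int = 50, patience: int = 5,
               internal_folds: int = 5) -> List[int]:
    """Greedy sequential forward selection over the ranked feature list.

    Candidates are tried in rank order; one is kept when it strictly improves
    the internal stratified CV accuracy.  Scanning stops once the number of
    consecutive non-improvements exceeds ``patience`` (``patience=0`` stops
    at the first non-improvement, yielding the longest strictly-improving
    prefix of the ranked list) or when ``max_features`` are kept.
    """
    X = np.asarray(train_matrix, dtype=np.float64)
    y = np.asarray(train_labels)
    if X.shape[0] == 0:
        raise ValidationError("empty training split")
    if len(ranked.order) != X.shape[1]:
        raise ValidationError("ranking does not cover all feature columns")
    selected: List[int] = []
    best = -np.inf
    fails = 0
    for j in ranked.order:
        cand = selected + [int(j)]
        acc = _internal_accuracy(X, y, cand, kernel, internal_folds)
        if acc > best:
            best = acc
            selected = cand
            fails = 0
        else:
            fails += 1
            if fails > patience:
                break
        if len(selected) >= max_features:
            break
    return selected


def majority_ref_counts(y_true: Sequence, y_pred: Sequence,
                        reference_class) -> ConfusionCounts:
    """Collapse a multiclass confusion to binary counts with the reference
    (majority) class as the negative pole.

    TP: non-reference samples given exactly their correct label;
    FN: non-reference samples mislabeled (any way);
    TN: reference samples labeled as reference;
    FP: reference samples mislabeled.
    The counts sum to the number of test samples and ACC equals the plain
    multiclass accuracy.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true != reference_class
    TP = int((pos & (y_pred == y_true)).sum())
    FN = int(pos.sum()) - TP
    TN = int((~pos & (y_pred == y_true)).sum())
    FP = int((~pos).sum()) - TN
    return ConfusionCounts(TP, TN, FP, FN)


def micro_ovr_counts(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    """Collapse a multiclass confusion into binary counts by micro-averaged
    one-vs-rest: TP/FP/FN/TN are summed over the per-class binary tasks."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    n = len(y_true)
    TP = FP = FN = TN = 0
    for c in classes:
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        TP += tp
        FP += fp
        FN += fn
        TN += n - tp - fp - fn
    return ConfusionCounts(TP, TN, FP, FN)


@dataclass
class CVReport:
    """Per-fold counts/metrics, fold-averaged summary and selections."""

    classifier: str
    folds: List[Tuple[ConfusionCounts, Metrics]]
    summary: Metrics
    total_counts: ConfusionCounts
    selected_features: List[List[int]]
    test_indices: List[List[int]] = field(default_factory=list)

    def as_dict(self) -> Dict:
        return {
            "classifier": self.classifier,
            "folds": [
                {"counts": vars(c), "metrics": m.as_dict()}
                for c, m in self.folds
            ],
            "summary": self.summary.as_dict(),
            "total_counts": vars(self.total_counts),
            "selected_features": self.selected_features,
        }


def cross_validate(matrix: np.ndarray, labels: Sequence, kernel: KernelSpec,
                   folds: int = 10, seed: int = 0, *,
                   rank_mode: str = "per_fold",
                   ranked: Optional[RankedFeatures] = None,
                   max_features: int = 50, patience: int = 5,
                   internal_folds: int = 5,
                   collapse: str = "majority_ref",
                   reference_class=None,
                   oversample=None) -> CVReport:
    """Stratified k-fold evaluation with per-fold SFS.

    ``rank_mode="per_fold"`` (default) recomputes the ANOVA ranking on each
    training split to avoid selection leakage; ``rank_mode="global"`` uses
    ``ranked`` (or a ranking of the full matrix) for every fold, matching a
    pre-ranked protocol.  ``oversample`` may be a callable
    ``(X_train, y_train, fold_seed) -> (X, y)`` applied to each training
    split (per-fold feature-space balancing).

    ``collapse`` turns the per-fold multiclass confusion into binary counts:
    ``"majority_ref"`` (default) uses the most frequent class — or
    ``reference_class`` when given — as the negative pole, so the counts sum
    to the test-set size and ACC equals the multiclass accuracy;
    ``"micro_ovr"`` sums one-vs-rest counts over all classes.
    """
    X = np.asarray(matrix, dtype=np.float64)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValidationError(
            f"smallest class has {counts.min()} members, fewer than "
            f"{folds} folds; reduce the fold count")
    if rank_mode == "global" and ranked is None:
        ranked = rank_features(X, y)
    if collapse not in ("majority_ref", "micro_ovr"):
        raise ValidationError(f"unknown collapse {collapse!r}")
    if collapse == "majority_ref" and reference_class is None:
        classes, cls_counts = np.unique(y, return_counts=True)
        reference_class = classes[np.lexsort((classes, -cls_counts))][0]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_results: List[Tuple[ConfusionCounts, Metrics]] = []
    selections: List[List[int]] = []
    test_sets: List[List[int]] = []
    for fold_id, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        if oversample is not None:
            Xtr, ytr = oversample(Xtr, ytr, seed * 1000 + fold_id)
        fold_ranked = (ranked if rank_mode == "global"
                       else rank_features(Xtr, ytr))
        sel = sfs_select(Xtr, ytr, fold_ranked, kernel,
                         max_features=max_features, patience=patience,
                         internal_folds=internal_folds)
        pred = svm_fit_predict(Xtr[:, sel], ytr, X[np.ix_(te, sel)], kernel)
        c = (majority_ref_counts(y[te], pred, reference_class)
             if collapse == "majority_ref" else micro_ovr_counts(y[te], pred))
        fold_results.append((c, metrics_from_counts(c)))
        selections.append(sel)
        test_sets.append([int(i) for i in te])
    summary, totals = aggregate_folds(fold_results)
    return CVReport(classifier=kernel.kind, folds=fold_results,
                    summary=summary, total_counts=totals,
                    selected_features=selections, test_indices=test_sets)
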