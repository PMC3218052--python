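"""Dataset split protocol, RBF-SVM training, N-end-rule baseline, metrics.

The split protocol draws, per repeat, a balanced training set of 80% of
the positives plus the same number of negatives; everything else is the
test set (with 510 positives among 4838 proteins this gives 408/408
training and 102/3920 testing samples per repeat). Feature selection is
refit inside every training split to avoid test-set leakage. The SVM is
an RBF-kernel classifier tuned by grid search over (C, gamma) maximizing
mean stratified k-fold cross-validation accuracy.
"""

from __future__ import annotations

import json
import math
import pickle
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import selection as _selection
from .seqio import Label, ValidationError
from .selection import SelectionResult, minmax_scale, select_features

#: default libsvm-style parameter grids
C_GRID_DEFAULT = tuple(2.0 ** e for e in range(-5, 16, 2))
G_GRID_DEFAULT = tuple(2.0 ** e for e in range(-15, 4, 2))

#: N-end rule residue sets (13 destabilizing, 7 stabilizing)
DESTABILIZING = frozenset("FLWYIRKHDECNQ")
STABILIZING = frozenset("MPASTGV")


@dataclass
class SplitSet:
    repeats: List[Tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    seed: int
    fraction: float = 0.8


@dataclass
class TrainedModel:
    kept_features: List[str]
    scaling: Tuple[np.ndarray, np.ndarray]  # per-feature (min, max)
    c: float
    g: float
    cv_accuracy: float
    svc: SVC
    seed: int
    kernel: str = "rbf"

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class EvalReport:
    tp: int
    fn: int
    tn: int
    fp: int
    se: float
    sp: float
    acc: float
    mcc: float
    auc: float
    roc: List[Tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("tp", "fn", "tn", "fp", "se", "sp", "acc", "mcc", "auc")}


def make_splits(labels: Sequence[bool], n_repeats: int = 10,
                fraction: float = 0.8, seed: int = 0) -> SplitSet:
    """Balanced resampling protocol: per repeat, floor(fraction * n_pos)
    positives and the same number of negatives train; the rest test."""
    labels = np.asarray(labels, dtype=bool)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    n_train_pos = math.floor(fraction * len(pos_idx))
    if n_train_pos < 1 or n_train_pos >= len(pos_idx):
        raise ValidationError(
            f"fraction {fraction} leaves no positive train or test samples")
    if len(neg_idx) < n_train_pos:
        raise ValidationError(
            f"need >= {n_train_pos} negatives to balance, have {len(neg_idx)}")
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        tr_pos = rng.choice(pos_idx, size=n_train_pos, replace=False)
        tr_neg = rng.choice(neg_idx, size=n_train_pos, replace=False)
        train = np.sort(np.concatenate([tr_pos, tr_neg]))
        mask = np.ones(len(labels), dtype=bool)
        mask[train] = False
        repeats.append((train, np.flatnonzero(mask)))
    return SplitSet(repeats=repeats, seed=seed, fraction=fraction)


def train_svm(matrix: np.ndarray, labels: Sequence[bool],
              feature_names: Sequence[str],
              c_grid: Sequence[float] = C_GRID_DEFAULT,
              g_grid: Sequence[float] = G_GRID_DEFAULT,
              n_folds: int = 10, seed: int = 0) -> TrainedModel:
    """RBF-SVM with (C, gamma) grid search by stratified k-fold CV accuracy.

    Ties are broken toward smaller C, then smaller gamma. Min-max scaling
    is fitted on the training data only.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if min(n_pos, n_neg) < 2:
        raise ValidationError("need >= 2 samples per class")
    folds = min(n_folds, int(min(n_pos, n_neg)))
    scaled, bounds = minmax_scale(matrix)
    y = labels.astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(scaled, y))
    best = None  # (acc, c, g)
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            accs = []
            for tr, te in splits:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(scaled[tr], y[tr])
                accs.append((clf.predict(scaled[te]) == y[te]).mean())
            acc = float(np.mean(accs))
            if best is None or acc > best[0] + 1e-12:
                best = (acc, c, g)
    cv_acc, c, g = best
    svc = SVC(C=c, gamma=g, kernel="rbf")
    svc.fit(scaled, y)
    return TrainedModel(kept_features=list(feature_names), scaling=bounds,
                        c=c, g=g, cv_accuracy=cv_acc, svc=svc, seed=seed)


def predict(model: TrainedModel, matrix: np.ndarray,
            feature_names: Sequence[str]):
    """Predict labels and continuous decision scores.

    Columns are aligned to the model's feature names; values outside the
    training min/max are clipped to [0, 1] after scaling.
    """
    names = list(feature_names)
    missing = [n for n in model.kept_features if n not in names]
    extra = [n for n in names if n not in set(model.kept_features)]
    if missing:
        raise ValidationError(
            f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}")
    cols = [names.index(n) for n in model.kept_features]
    matrix = np.asarray(matrix, dtype=float)[:, cols]
    scaled, _ = minmax_scale(matrix, bounds=model.scaling)
    scores = model.svc.decision_function(scaled)
    return (scores > 0).astype(bool), scores


def nend_rule_predict(sequence: str) -> Label:
    """N-end rule: classify by the residue at position 1."""
    if not sequence:
        raise ValidationError("empty sequence")
    return Label.SHORT if sequence[0] in DESTABILIZING else Label.LONG


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> dict:
    """SE/SP/ACC/MCC from a confusion matrix (MCC = 0 on zero marginals)."""
    total = tp + fn + tn + fp
    se = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / total if total else float("nan")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"se": se, "sp": sp, "acc": acc, "mcc": mcc}


def evaluate(truth: Sequence[bool], labels: Sequence[bool],
             scores: Optional[Sequence[float]] = None) -> EvalReport:
    """Confusion counts, SE/SP/ACC/MCC, and trapezoidal ROC AUC."""
    truth = np.asarray(truth, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if len(truth) != len(labels):
        raise ValidationError("truth/labels length mismatch")
    tp = int(np.sum(truth & labels))
    fn = int(np.sum(truth & ~labels))
    tn = int(np.sum(~truth & ~labels))
    fp = int(np.sum(~truth & labels))
    m = metrics_from_counts(tp, fn, tn, fp)
    if math.isnan(m["se"]) or math.isnan(m["sp"]):
        import warnings
        warnings.warn("single-class truth: SE or SP undefined (NaN)")
    auc = float("nan")
    roc: List[Tuple[float, float]] = []
    if scores is not None and truth.any() and not truth.all():
        fpr, tpr, _ = roc_curve(truth.astype(int), np.asarray(scores, dtype=float))
        auc = float(np.trapezoid(tpr, fpr))
        roc = list(zip(fpr.tolist(), tpr.tolist()))
    return EvalReport(tp=tp, fn=fn, tn=tn, fp=fp, se=m["se"], sp=m["sp"],
                      acc=m["acc"], mcc=m["mcc"], auc=auc, roc=roc)


@dataclass
class ProtocolConfig:
    n_repeats: int = 10
    fraction: float = 0.8
    seed: int = 0
    n_folds: int = 10
    c_grid: Sequence[float] = C_GRID_DEFAULT
    g_grid: Sequence[float] = G_GRID_DEFAULT
    f_min: float = 0.1
    p_max: float = 0.001
    r_threshold: float = 0.5
    reduced11: bool = False  # run on the 11-slot reduced vectors only


@dataclass
class ProtocolResult:
    svm_reports: List[EvalReport]
    nend_reports: List[EvalReport]
    selections: List[SelectionResult]
    models: List[TrainedModel]

    def summary(self) -> dict:
        """Mean +- sd across repeats (mean-of-ratios), plus metrics
        recomputed from the mean confusion counts (ratio-of-means)."""
        out = {}
        for method, reports in (("svm", self.svm_reports),
                                ("nend", self.nend_reports)):
            metrics = {}
            for key in ("tp", "fn", "tn", "fp", "se", "sp", "acc", "mcc", "auc"):
                vals = np.array([getattr(r, key) for r in reports], dtype=float)
                finite = vals[~np.isnan(vals)]
                metrics[key] = {
                    "mean": float(finite.mean()) if finite.size else float("nan"),
                    "sd": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
                }
            mean_counts = {k: metrics[k]["mean"] for k in ("tp", "fn", "tn", "fp")}
            metrics["from_mean_counts"] = metrics_from_counts(**mean_counts)
            out[method] = metrics
        return out


def run_protocol(matrix: np.ndarray, labels: Sequence[bool],
                 feature_names: Sequence[str],
                 sequences: Optional[Sequence[str]] = None,
                 config: Optional[ProtocolConfig] = None) -> ProtocolResult:
    """End-to-end protocol: splits -> per-split selection -> SVM -> test eval,
    plus the N-end-rule baseline on the same test sets.

    ``sequences`` (aligned with rows) are needed for the N-end baseline;
    without them only the SVM arm runs.
    """
    if config is None:
        config = ProtocolConfig()
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    names = list(feature_names)
    splits = make_splits(labels, n_repeats=config.n_repeats,
                         fraction=config.fraction, seed=config.seed)
    svm_reports, nend_reports, selections, models = [], [], [], []
    for rep, (train, test) in enumerate(splits.repeats):
        try:
            sel = select_features(matrix[train], labels[train], names,
                                  f_min=config.f_min, p_max=config.p_max,
                                  r_threshold=config.r_threshold)
            kept = sel.kept
            cols = [names.index(n) for n in kept]
            mdl = train_svm(matrix[np.ix_(train, cols)], labels[train], kept,
                            c_grid=config.c_grid, g_grid=config.g_grid,
                            n_folds=config.n_folds, seed=config.seed + rep)
            pred, scores = predict(mdl, matrix[np.ix_(test, cols)], kept)
            svm_reports.append(evaluate(labels[test], pred, scores))
            selections.append(sel)
            models.append(mdl)
            if sequences is not None:
                npred = np.array([nend_rule_predict(sequences[i]) == Label.SHORT
                                  for i in test])
                nend_reports.append(evaluate(labels[test], npred))
        except ValidationError as exc:
            raise ValidationError(f"repeat {rep}: {exc}") from exc
    return ProtocolResult(svm_reports=svm_reports, nend_reports=nend_reports,
                          selections=selections, models=models)
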