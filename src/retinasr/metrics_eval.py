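"""Evaluation machinery: one-vs-rest confusion counts, the printed
classification metric formulas, image quality measures (MSE/PSNR/SSIM), and
per-class ROC/AUC via the rank statistic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import rankdata

from .fundus_io import GRADES, GrayImage

__all__ = [
    "ConfusionCounts", "QualityMetrics", "EvalReport",
    "confusion", "classification_metrics", "image_mse", "psnr", "ssim",
    "roc_auc",
]

N_CLASSES = 5


@dataclasses.dataclass
class ConfusionCounts:
    matrix: np.ndarray                     # (5, 5), rows = true class
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.matrix.sum())


@dataclasses.dataclass
class QualityMetrics:
    mse: float
    psnr: float        # +inf when mse == 0
    max_i: float


@dataclasses.dataclass
class EvalReport:
    per_class: dict                         # grade -> {acc, prc, rcl, f1, spc}
    macro: dict
    overall_accuracy: float
    per_class_auc: dict | None = None
    macro_auc: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 1:
        raise ValueError("need at least one sample")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() > 4:
            raise ValueError(f"{name} contains grades outside 0..4")
    matrix = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(matrix, (y_true, y_pred), 1)
    tp = np.diag(matrix).copy()
    fn = matrix.sum(axis=1) - tp
    fp = matrix.sum(axis=0) - tp
    tn = matrix.sum() - tp - fn - fp
    return ConfusionCounts(matrix=matrix, tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num: float, den: float, what: str, cls: int) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (0/0) for class {cls}; reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(counts: ConfusionCounts,
                           average: str = "macro") -> EvalReport:
    """Per-class Acc/Prc/Rcl/F1/Spc from one-vs-rest counts.

    Acc = (TP+TN)/(TP+TN+FP+FN); Prc = TP/(TP+FP); Rcl = TP/(TP+FN);
    F1 = 2*Prc*Rcl/(Prc+Rcl); Spc = TN/(TN+FP).  Undefined 0/0 cells are
    reported as NaN with a warning; the macro average is the unweighted mean
    over classes with defined values.
    """
    per_class = {}
    for c in range(N_CLASSES):
        tp, tn, fp, fn = (int(counts.tp[c]), int(counts.tn[c]),
                          int(counts.fp[c]), int(counts.fn[c]))
        prc = _safe_ratio(tp, tp + fp, "precision", c)
        rcl = _safe_ratio(tp, tp + fn, "recall", c)
        if np.isnan(prc) or np.isnan(rcl) or (prc + rcl) == 0:
            f1 = float("nan") if (np.isnan(prc) or np.isnan(rcl)) else 0.0
        else:
            f1 = 2 * prc * rcl / (prc + rcl)
        per_class[c] = {
            "acc": (tp + tn) / (tp + tn + fp + fn),
            "prc": prc,
            "rcl": rcl,
            "f1": f1,
            "spc": _safe_ratio(tn, tn + fp, "specificity", c),
        }
    if average == "weighted":
        w = counts.matrix.sum(axis=1).astype(np.float64)
        w = w / w.sum()
    elif average == "macro":
        w = None
    else:
        raise ValueError(f"unknown averaging scheme {average!r}")
    macro = {}
    for key in ("acc", "prc", "rcl", "f1", "spc"):
        vals = np.array([per_class[c][key] for c in range(N_CLASSES)])
        defined = ~np.isnan(vals)
        if w is None:
            macro[key] = float(vals[defined].mean()) if defined.any() \
                else float("nan")
        else:
            wd = w[defined]
            macro[key] = float((vals[defined] * wd).sum() / wd.sum()) \
                if defined.any() else float("nan")
    overall = float(np.trace(counts.matrix) / counts.n)
    return EvalReport(per_class=per_class, macro=macro,
                      overall_accuracy=overall)


# ---------------------------------------------------------------------------
# image quality
# ---------------------------------------------------------------------------

def _pixels(x) -> np.ndarray:
    return x.pixels if isinstance(x, GrayImage) else np.asarray(x)


def image_mse(x, y) -> float:
    xa, ya = _pixels(x).astype(np.float64), _pixels(y).astype(np.float64)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    return float(((xa - ya) ** 2).mean())


def psnr(x, y, max_i: float | None = None) -> QualityMetrics:
    """PSNR = 10 log10(MAX_I^2 / MSE); +inf sentinel when MSE == 0.

    MAX_I defaults to the declared dynamic-range maximum of ``x`` (never
    inferred from the data).
    """
    if max_i is None:
        if isinstance(x, GrayImage):
            max_i = x.dynamic_range[1]
        else:
            raise ValueError("max_i required when input carries no "
                             "dynamic range")
    mse = image_mse(x, y)
    value = float("inf") if mse == 0 else 10.0 * np.log10(max_i ** 2 / mse)
    return QualityMetrics(mse=mse, psnr=value, max_i=float(max_i))


def ssim(x, y, dynamic_range: float | None = None,
         windowed: bool = False) -> float:
    """Structural similarity from global image moments (default), with
    C1 = (0.01 L)^2 and C2 = (0.03 L)^2.

    ``windowed=True`` switches to the common sliding-window variant
    (scikit-image); the two give different values by design.
    """
    xa, ya = _pixels(x).astype(np.float64), _pixels(y).astype(np.float64)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 2:
        raise ValueError("need at least 2 pixels")
    if dynamic_range is None:
        if isinstance(x, GrayImage):
            lo, hi = x.dynamic_range
            dynamic_range = hi - lo
        else:
            raise ValueError("dynamic_range required for raw arrays")
    L = float(dynamic_range)
    if windowed:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(xa, ya, data_range=L))
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    mx, my = xa.mean(), ya.mean()
    vx, vy = xa.var(), ya.var()
    cov = ((xa - mx) * (ya - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2)) /
                 ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, y_true) -> tuple[dict, float]:
    """One-vs-rest AUC per class via the Mann-Whitney rank statistic
    (equivalent to trapezoidal ROC integration with tie handling).

    ``scores`` is (N, 5) class probabilities.  Classes lacking positives or
    negatives are skipped with a warning.  Returns (per-class dict, macro).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[1] != N_CLASSES:
        raise ValueError("scores must be (N, 5)")
    if scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores and labels disagree in length")
    aucs = {}
    for c in GRADES:
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {c} lacks positives or negatives; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        ranks = rankdata(scores[:, c])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs[c] = float(auc)
    macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return aucs, macro
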