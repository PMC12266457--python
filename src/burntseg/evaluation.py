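"""Segmentation evaluation: confusion counts, scalar metrics, ROC-AUC,
area statistics and error masks.

Burnt is the positive class everywhere. All scalar metrics derive from the
pixel confusion counts; ratios with a zero denominator are reported as NaN,
never silently as 0. ``iou_burnt`` (tp / (tp+fp+fn)) is the IoU variant
that reproduces the "Mean IoU" figures customarily printed for this task;
a true two-class macro IoU is reported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .raster import _check_binary

# error-mask category codes
TN_CODE, FP_CODE, FN_CODE, TP_CODE = 0, 1, 2, 3
ERROR_MASK_CATEGORIES = {TN_CODE: "TN", FP_CODE: "FP", FN_CODE: "FN", TP_CODE: "TP"}


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies with burnt as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _align(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = _check_binary(pred, "pred")
    ref = _check_binary(ref, "ref")
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    return pred, ref


def confusion(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Exhaustive pixel tally of a binary prediction against a reference."""
    pred, ref = _align(pred, ref)
    p = pred.astype(bool)
    r = ref.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
        tn=int(np.sum(~p & ~r)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(conf: ConfusionCounts) -> dict:
    """Scalar metric suite from confusion counts.

    precision, recall, f1, accuracy, iou_burnt, iou_macro, dice. f1 and
    dice are the same quantity algebraically; both are reported.
    """
    tp, fp, fn, tn = conf.tp, conf.fp, conf.fn, conf.tn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else float("nan"))
    iou_burnt = _ratio(tp, tp + fp + fn)
    iou_unburnt = _ratio(tn, tn + fp + fn)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": _ratio(tp + tn, conf.total),
        "iou_burnt": iou_burnt,
        "iou_macro": (iou_burnt + iou_unburnt) / 2.0,
        "dice": _ratio(2 * tp, 2 * tp + fp + fn),
    }


def normalized_confusion(conf: ConfusionCounts) -> dict:
    """Each count divided by the grand total; the four values sum to 1."""
    t = conf.total
    return {"tn": conf.tn / t, "fp": conf.fp / t, "fn": conf.fn / t, "tp": conf.tp / t}


def burnt_fraction(conf: ConfusionCounts, of: str = "reference") -> float:
    """Burnt share of the scene, as a percentage.

    ``of="reference"`` uses the reference mask ((tp+fn)/total);
    ``of="predicted"`` the prediction ((tp+fp)/total).
    """
    if of == "reference":
        return 100.0 * (conf.tp + conf.fn) / conf.total
    if of == "predicted":
        return 100.0 * (conf.tp + conf.fp) / conf.total
    raise ValueError("of must be 'reference' or 'predicted'")


def pixels_to_hectares(n_pixels: int, pixel_size_m: float = 3.0) -> float:
    """Area of ``n_pixels`` square pixels in hectares (1 ha = 10^4 m^2)."""
    return n_pixels * (pixel_size_m ** 2) / 10_000.0


def area_stats(mask: np.ndarray, pixel_size_m: float = 3.0) -> dict:
    """Burnt/unburnt pixel counts, hectares and burnt percentage of a mask."""
    mask = _check_binary(mask)
    burnt_px = int(mask.sum())
    unburnt_px = int(mask.size - burnt_px)
    return {
        "pixel_size_m": pixel_size_m,
        "burnt_pixels": burnt_px,
        "unburnt_pixels": unburnt_px,
        "burnt_ha": pixels_to_hectares(burnt_px, pixel_size_m),
        "unburnt_ha": pixels_to_hectares(unburnt_px, pixel_size_m),
        "burnt_pct": _ratio(100.0 * burnt_px, mask.size),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray, return_curve: bool = False):
    """Pixelwise ROC-AUC of burnt-probability scores against binary labels.

    Computed by the rank (concordance) formula: the probability that a
    random positive outscores a random negative, ties counted 1/2 —
    identical to the trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_binary(np.asarray(labels).ravel(), "labels")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present in labels")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    if return_curve:
        fpr, tpr, _ = _sk_roc_curve(labels, scores)
        return float(auc), (fpr, tpr)
    return float(auc)


def error_mask(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Categorical TP/FP/FN/TN raster; category counts equal ``confusion``."""
    pred, ref = _align(pred, ref)
    p = pred.astype(bool)
    r = ref.astype(bool)
    out = np.full(pred.shape, TN_CODE, dtype=np.uint8)
    out[p & ~r] = FP_CODE
    out[~p & r] = FN_CODE
    out[p & r] = TP_CODE
    return out


def probabilities_to_mask(probs: np.ndarray) -> np.ndarray:
    """Argmax of an (..., 2) softmax map with channels (unburnt, burnt).

    Ties break toward unburnt.
    """
    probs = np.asarray(probs)
    if probs.shape[-1] != 2:
        raise ValueError("expected a trailing 2-channel (unburnt, burnt) axis")
    return (probs[..., 1] > probs[..., 0]).astype(np.uint8)
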