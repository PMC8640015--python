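"""Evaluation metrics and the temporal median-filter baseline.

Provides per-class and mean Intersection over Union, confusion-matrix
tallying (square, or rectangular over confidence-binned observables), and the
1D per-site temporal median filter used as a simplistic post-processing
baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .params import (
    ConfusionMatrix,
    composite_labels,
    composite_observable,
    confidence_bin,
)

__all__ = ["IoUReport", "iou", "tally_confusion", "median_filter_time"]


@dataclass(frozen=True)
class IoUReport:
    """Per-class and mean Intersection over Union.

    ``mean_iou`` is the unweighted arithmetic mean over classes.  Classes
    absent from both prediction and truth score 1.0 by convention and are
    listed in ``absent_classes`` so the convention is visible.
    """

    per_class: dict[int, float]
    mean_iou: float
    n_images: int
    absent_classes: tuple[int, ...] = field(default=())

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "mean_iou": self.mean_iou,
            "n_images": self.n_images,
            "absent_classes": list(self.absent_classes),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_row(self, method: str = "") -> pd.DataFrame:
        """One table row: per-class IoU columns plus the mean."""
        cols = {f"iou_class{c}": v for c, v in self.per_class.items()}
        cols["mean_iou"] = self.mean_iou
        return pd.DataFrame(cols, index=[method] if method else [0])


def iou(
    pred: np.ndarray, truth: np.ndarray, n_classes: int, n_images: int | None = None
) -> IoUReport:
    """Per-class IoU ``|pred=c & truth=c| / |pred=c | truth=c|`` and its mean.

    ``n_images`` records how many 2D slice-images the comparison spans; when
    omitted it defaults to the product of all but the last two axes.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.size and (max(pred.max(), truth.max()) >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    per_class: dict[int, float] = {}
    absent: list[int] = []
    p = pred.ravel()
    t = truth.ravel()
    for c in range(n_classes):
        pc = p == c
        tc = t == c
        union = int(np.count_nonzero(pc | tc))
        if union == 0:
            per_class[c] = 1.0
            absent.append(c)
        else:
            per_class[c] = int(np.count_nonzero(pc & tc)) / union
    if n_images is None:
        n_images = int(np.prod(pred.shape[:-2])) if pred.ndim >= 2 else 1
    return IoUReport(
        per_class=per_class,
        mean_iou=float(np.mean(list(per_class.values()))),
        n_images=n_images,
        absent_classes=tuple(absent),
    )


def tally_confusion(
    pred: np.ndarray,
    conf: np.ndarray | None,
    truth: np.ndarray,
    n_classes: int,
    n_bins: int = 1,
    class_names: list[str] | None = None,
) -> ConfusionMatrix:
    """Tally a confusion matrix of truth classes against observables.

    With ``n_bins == 1`` the observable is the predicted class (square
    ``N x N`` matrix); with ``n_bins > 1`` each prediction is split by its
    confidence bin, yielding a rectangular ``N x bN`` matrix whose columns are
    the composite observables.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if n_bins > 1 and conf is None:
        raise ValueError("confidence values are required when n_bins > 1")
    if pred.size and max(pred.max(), truth.max()) >= n_classes:
        raise ValueError(f"labels out of range [0, {n_classes})")
    m = n_classes * n_bins
    if n_bins == 1:
        obs = pred.ravel().astype(np.int64)
    else:
        bins = confidence_bin(np.asarray(conf).ravel(), n_classes, n_bins)
        obs = composite_observable(pred.ravel().astype(np.int64), bins, n_bins)
    counts = np.bincount(
        truth.ravel().astype(np.int64) * m + obs, minlength=n_classes * m
    ).reshape(n_classes, m)
    names = class_names or [f"class{i}" for i in range(n_classes)]
    return ConfusionMatrix(
        counts=counts,
        row_labels=tuple(names),
        col_labels=tuple(composite_labels(n_classes, n_bins, names)),
    )


def median_filter_time(labels: np.ndarray, window: int = 5) -> np.ndarray:
    """1D temporal median filter, applied per spatial site.

    The baseline replaces each toxel's label by the median of the integer
    labels in a centred window along the time axis (default 5 time steps);
    sequence ends use nearest-edge padding.  Taking a median of categorical
    codes is order-dependent for more than two classes — a documented quirk
    of the baseline, reproduced deliberately.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    labels = np.asarray(labels)
    size = (window,) + (1,) * (labels.ndim - 1)
    return ndimage.median_filter(labels, size=size, mode="nearest")
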