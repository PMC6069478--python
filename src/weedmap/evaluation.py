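"""Segmentation metrics and the pixel-based SVM baseline.

Metrics follow the PASCAL-VOC conventions: per-class intersection over union
IU_c = TP_c / (TP_c + FP_c + FN_c), mean IU as the unweighted mean over
classes present in the ground truth, overall accuracy as the confusion-matrix
trace over the total, and Cohen's kappa as chance-corrected agreement.  All
metrics are pooled: label maps accumulate into a single global confusion
matrix (rows = ground truth, columns = predicted) rather than averaging
per-image scores.

The baseline classifies each pixel independently from its (R, G, B) triple
with an RBF-kernel C-SVC, the penalty C chosen by cross-validated grid
search on a stratified pixel subsample.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) int64, rows = GT, cols = predicted

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    mean_iu: float
    overall_accuracy: float
    kappa: float
    per_class_iu: np.ndarray
    normalized_confusion: np.ndarray
    excluded_classes: list = field(default_factory=list)
    empty_gt_rows: list = field(default_factory=list)


def confusion(gt, pred, n_classes: int = 3) -> ConfusionMatrix:
    """Accumulate a GT-by-predicted count matrix over one or more label maps."""
    gts = gt if isinstance(gt, (list, tuple)) else [gt]
    preds = pred if isinstance(pred, (list, tuple)) else [pred]
    if len(gts) != len(preds):
        raise ValueError(f"{len(gts)} GT maps vs {len(preds)} predictions")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for g, p in zip(gts, preds):
        g = np.asarray(g)
        p = np.asarray(p)
        if g.shape != p.shape:
            raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
        if g.min() < 0 or g.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
            raise ValueError(f"labels outside 0..{n_classes - 1}")
        counts += np.bincount(
            (g.astype(np.int64) * n_classes + p.astype(np.int64)).ravel(),
            minlength=n_classes * n_classes,
        ).reshape(n_classes, n_classes)
    return ConfusionMatrix(counts=counts)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Mean IU, overall accuracy and kappa from a confusion matrix.

    Classes absent from the ground truth are excluded from the mean IU (and
    reported in ``excluded_classes``); rows with zero GT pixels are flagged
    and left as zeros in the row-normalized matrix.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    row = counts.sum(axis=1)  # GT totals
    col = counts.sum(axis=0)  # prediction totals
    union = row + col - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        iu = np.where(union > 0, tp / union, np.nan)
    present = row > 0
    excluded = [int(c) for c in np.where(~present)[0]]
    if excluded:
        warnings.warn(f"classes {excluded} absent from ground truth; excluded from mean IU")
    mean_iu = float(np.nanmean(np.where(present, iu, np.nan)))
    oa = float(tp.sum() / total)
    pe = float((row * col).sum() / total**2)
    kappa = float((oa - pe) / (1.0 - pe)) if pe < 1.0 else 1.0
    norm = np.zeros_like(counts)
    nz = row > 0
    norm[nz] = counts[nz] / row[nz, None]
    return MetricsReport(
        mean_iu=mean_iu,
        overall_accuracy=oa,
        kappa=kappa,
        per_class_iu=iu,
        normalized_confusion=norm,
        excluded_classes=excluded,
        empty_gt_rows=[int(c) for c in np.where(~nz)[0]],
    )


# ---------------------------------------------------------------------------
# pixel-based SVM baseline
# ---------------------------------------------------------------------------

@dataclass
class PixelSVM:
    model: SVC
    scale: float = 255.0

    def predict_map(self, image: np.ndarray, chunk: int = 200_000) -> np.ndarray:
        """Independent per-pixel prediction over an (H, W, 3) image."""
        h, w = image.shape[:2]
        flat = image.reshape(-1, 3).astype(np.float64) / self.scale
        out = np.empty(h * w, dtype=np.int64)
        for start in range(0, flat.shape[0], chunk):
            out[start : start + chunk] = self.model.predict(flat[start : start + chunk])
        return out.reshape(h, w)


def fit_pixel_svm(
    images,
    gts,
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0),
    gamma: str | float = "scale",
    pixel_subsample: int = 50_000,
    seed: int = 0,
) -> PixelSVM:
    """Train an RBF C-SVC on RGB pixel features.

    Pixels are pooled over all training tiles and subsampled with per-class
    stratification (proportional, at least one pixel per present class); the
    penalty C is selected by 3-fold cross-validated grid search.
    """
    if pixel_subsample < 100:
        raise ValueError("pixel_subsample must be >= 100")
    xs, ys = [], []
    for img, g in zip(images, gts):
        xs.append(np.asarray(img).reshape(-1, 3))
        ys.append(np.asarray(g).ravel())
    x = np.concatenate(xs).astype(np.float64) / 255.0
    y = np.concatenate(ys).astype(np.int64)
    classes, class_counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data contains a single class; cannot fit a classifier")

    rng = np.random.default_rng(seed)
    n_take = min(pixel_subsample, y.size)
    take_idx = []
    for cls, cnt in zip(classes, class_counts):
        share = max(1, int(round(n_take * cnt / y.size)))
        idx = np.where(y == cls)[0]
        take_idx.append(rng.choice(idx, size=min(share, idx.size), replace=False))
    idx = np.concatenate(take_idx)
    rng.shuffle(idx)
    xs_sub, ys_sub = x[idx], y[idx]

    search = GridSearchCV(
        SVC(kernel="rbf", gamma=gamma, random_state=0),
        param_grid={"C": list(c_grid)},
        cv=3,
        n_jobs=1,
    )
    search.fit(xs_sub, ys_sub)
    return PixelSVM(model=search.best_estimator_)


def predict_pixel_svm(classifier: PixelSVM, image: np.ndarray) -> np.ndarray:
    return classifier.predict_map(image)


def compare_methods(methods: dict, dataset, n_classes: int = 3) -> pd.DataFrame:
    """Evaluate named predictors on a common validation set.

    ``methods`` maps a name to a callable image -> label map; ``dataset`` is a
    sequence of (image, gt) pairs.  Returns one row per method with the pooled
    metrics plus mean per-image wall time (informational only).
    """
    rows = []
    for name, fn in methods.items():
        preds, gts, times = [], [], []
        for image, gt in dataset:
            t0 = time.perf_counter()
            preds.append(fn(image))
            times.append(time.perf_counter() - t0)
            gts.append(gt)
        rep = metrics(confusion(gts, preds, n_classes))
        rows.append(
            {
                "method": name,
                "mean_iu": rep.mean_iu,
                "overall_accuracy": rep.overall_accuracy,
                "kappa": rep.kappa,
                "mean_seconds_per_image": float(np.mean(times)),
            }
        )
    return pd.DataFrame(rows)
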