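"""Segmentation evaluation: DSC, confusion-matrix metrics, ROC-AUC,
95th-percentile Hausdorff distance, and multi-run aggregation.

Conventions (degenerate cases are part of the contract):

* ``dsc``: both masks empty -> 1.0; exactly one empty -> 0.0.
* ``precision``/``recall``: zero denominator -> 0.0.
* ``roc_auc``: raises on single-class ground truth (AUC undefined).
* ``hd95``: raises on an empty mask; callers exclude such images from
  averaging and log the count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_bool(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise true/false positive/negative counts."""
    p = _as_bool(pred, "pred")
    t = _as_bool(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    p = _as_bool(pred, "pred")
    t = _as_bool(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(p & t)) / denom


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else 0.0


# ----------------------------------------------------------------- ROC / AUC

def roc_curve(probs: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points from a sweep over all distinct score thresholds.

    Returns an array of shape (k, 2) running from (0,0) to (1,1) with
    nondecreasing FPR.
    """
    t = _as_bool(truth, "truth").ravel()
    s = np.asarray(probs, dtype=np.float64).ravel()
    if s.shape != t.shape:
        raise ValueError("probability map and truth shapes differ")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined: ground truth contains a single class")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    # cumulative counts at each distinct threshold (predict positive if score >= thr)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, t_sorted.size - 1]
    tp = np.cumsum(t_sorted)[cut]
    fp = np.cumsum(~t_sorted)[cut]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return np.column_stack([fpr, tpr])


def roc_auc(probs: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve by the trapezoidal sum
    sum_i (FPR_i - FPR_{i-1}) * (TPR_i + TPR_{i-1}) / 2."""
    pts = roc_curve(probs, truth)
    fpr, tpr = pts[:, 0], pts[:, 1]
    return float(np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1]) / 2.0))


# ---------------------------------------------------------------------- HD95

def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-neighbour outside the mask (erosion diff)."""
    cross = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~eroded


def hd95(pred: np.ndarray, truth: np.ndarray) -> float:
    """Symmetrised 95th-percentile Hausdorff distance between mask boundaries.

    Directed distances are Euclidean from each boundary pixel of one mask to
    the nearest boundary pixel of the other; the per-direction 95th
    percentile uses linear interpolation, and the result is the max of the
    two directions.
    """
    p = _as_bool(pred, "pred")
    t = _as_bool(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not p.any():
        raise ValueError("hd95: predicted mask is empty")
    if not t.any():
        raise ValueError("hd95: ground-truth mask is empty")
    bp = _boundary(p)
    bt = _boundary(t)

    def directed(from_b: np.ndarray, to_b: np.ndarray) -> float:
        dt = ndimage.distance_transform_edt(~to_b)
        return float(np.percentile(dt[from_b], 95))

    return max(directed(bp, bt), directed(bt, bp))


# --------------------------------------------------------------- aggregation

def aggregate_runs(
    runs: pd.DataFrame | list[dict], ci: float = 0.95, method: str = "t"
) -> pd.DataFrame:
    """Per-metric mean, sample SD, and CI half-width over independent runs.

    ``runs`` is one row per run, one column per metric.  The default CI is
    Student-t based (appropriate for ~10 runs); ``method='bootstrap'`` uses
    a seeded percentile bootstrap instead.
    """
    df = pd.DataFrame(runs).astype(float)
    n = len(df)
    if n < 2:
        raise ValueError("aggregation requires >= 2 runs")
    mean = df.mean()
    sd = df.std(ddof=1)
    if method == "t":
        tq = stats.t.ppf(0.5 + ci / 2.0, df=n - 1)
        half = tq * sd / np.sqrt(n)
    elif method == "bootstrap":
        rng = np.random.default_rng(0)
        boots = np.array(
            [df.sample(n, replace=True, random_state=rng.integers(2**31)).mean() for _ in range(2000)]
        )
        lo = np.percentile(boots, 100 * (0.5 - ci / 2), axis=0)
        hi = np.percentile(boots, 100 * (0.5 + ci / 2), axis=0)
        half = pd.Series((hi - lo) / 2.0, index=df.columns)
    else:
        raise ValueError("method must be 't' or 'bootstrap'")
    return pd.DataFrame({"mean": mean, "sd": sd, "ci95_half_width": half})


def evaluate_masks(
    pred: np.ndarray, truth: np.ndarray, probs: np.ndarray | None = None
) -> dict[str, float]:
    """All per-image metrics for one predicted/true mask pair.

    HD95 is NaN when either mask is empty; AUC is NaN without a probability
    map or with single-class truth.
    """
    c = confusion(pred, truth)
    out = {
        "dsc": dsc(pred, truth),
        "precision": precision(c),
        "recall": recall(c),
        "accuracy": accuracy(c),
    }
    try:
        out["hd95"] = hd95(pred, truth)
    except ValueError:
        out["hd95"] = float("nan")
    if probs is not None:
        try:
            out["auc"] = roc_auc(probs, truth)
        except ValueError:
            out["auc"] = float("nan")
    return out
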