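"""Stent expansion index (SEI), under-expansion classification and the
evaluation suite.

The per-frame SEI is the post-stent lumen area divided by the mean of the
proximal and distal reference lumen areas, times 100.  The minimum SEI over
the stented segment (mSEI) grades the deployment: a stent with mSEI <= 80%
is under-expanded (the positive class throughout), > 80% well-expanded.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

UNDER_EXPANDED = "under_expanded"
WELL_EXPANDED = "well_expanded"

MSEI_THRESHOLD = 80.0  # percent; boundary belongs to the under-expanded class


@dataclasses.dataclass
class ExpansionResult:
    """SEI curve with its minimum, the frame achieving it, and the class."""

    sei_curve: pd.Series
    msei: float
    msei_frame: int
    label: str
    source: str  # "actual" | "predicted"


def sei(post_area, ref_prox: float, ref_dist: float):
    """Stent expansion index (%) of a post-stent lumen area (scalar or array)."""
    post = np.asarray(post_area, dtype=float)
    if ref_prox <= 0 or ref_dist <= 0 or np.any(post <= 0):
        raise ValueError("SEI requires positive areas")
    out = post / (0.5 * (ref_prox + ref_dist)) * 100.0
    return float(out) if np.isscalar(post_area) else out


def classify(msei: float) -> str:
    """Under-expanded iff mSEI <= 80% (boundary inclusive)."""
    if msei <= 0:
        raise ValueError("mSEI must be positive")
    return UNDER_EXPANDED if msei <= MSEI_THRESHOLD else WELL_EXPANDED


def min_sei(curve) -> tuple[float, int]:
    """Global minimum of an SEI curve and the frame where it occurs.

    Ties resolve to the smallest frame index.  Accepts a pandas Series
    (frame-indexed) or a plain sequence (positional indices).
    """
    if len(curve) == 0:
        raise ValueError("empty SEI curve")
    values = np.asarray(curve, dtype=float)
    pos = int(np.argmin(values))  # argmin returns the first minimum
    frame = int(curve.index[pos]) if isinstance(curve, pd.Series) else pos
    return float(values[pos]), frame


def compute_expansion(
    post_areas, ref_prox: float, ref_dist: float, frames=None, source: str = "actual"
) -> ExpansionResult:
    """Full expansion result from a per-frame post-stent area curve."""
    curve = sei(np.asarray(post_areas, dtype=float), ref_prox, ref_dist)
    idx = frames if frames is not None else range(len(curve))
    series = pd.Series(curve, index=list(idx), name="sei")
    value, frame = min_sei(series)
    return ExpansionResult(
        sei_curve=series,
        msei=value,
        msei_frame=frame,
        label=classify(value),
        source=source,
    )


def evaluate_regression(pred_areas, actual_areas) -> dict[str, float]:
    """RMSE, Pearson r, bias (mean of pred - actual) and residual SD."""
    pred = np.asarray(pred_areas, dtype=float)
    actual = np.asarray(actual_areas, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("prediction/actual length mismatch")
    if pred.size < 2:
        raise ValueError("need at least 2 paired values")
    resid = pred - actual
    if np.ptp(pred) == 0 or np.ptp(actual) == 0:
        r = 1.0 if np.allclose(pred, actual) else 0.0
    else:
        r = float(np.corrcoef(pred, actual)[0, 1])
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "pearson_r": r,
        "bias": float(np.mean(resid)),
        "residual_sd": float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0,
    }


def roc_curve_from_scores(scores, truth_under: np.ndarray):
    """ROC points (fpr, tpr) sweeping a threshold over continuous scores,
    where larger score means more likely under-expanded."""
    fpr, tpr, thresholds = skmetrics.roc_curve(truth_under, scores)
    return fpr, tpr, thresholds


def auc_from_scores(scores, truth_under) -> float:
    """Trapezoid-rule AUC of the threshold-swept ROC."""
    fpr, tpr, _ = roc_curve_from_scores(np.asarray(scores, float), np.asarray(truth_under))
    return float(skmetrics.auc(fpr, tpr))


def evaluate_classification(msei_pred, labels_actual) -> dict[str, object]:
    """Lesion-level under-expansion metrics from predicted mSEI values.

    Hard metrics apply the 80% cut to the predicted mSEI; the ROC sweeps the
    cut over the predicted mSEI (score = 100 - mSEI so that larger score
    means more likely under-expanded).  With a single-class truth the AUC is
    undefined and reported as NaN with a warning; the other metrics are
    still returned.
    """
    msei_pred = np.asarray(msei_pred, dtype=float)
    labels_actual = np.asarray(labels_actual)
    if len(msei_pred) != len(labels_actual) or len(msei_pred) < 2:
        raise ValueError("need >= 2 lesions with matching predictions and labels")
    truth = (labels_actual == UNDER_EXPANDED).astype(int)
    pred_under = (msei_pred <= MSEI_THRESHOLD).astype(int)
    tp = int(np.sum((pred_under == 1) & (truth == 1)))
    tn = int(np.sum((pred_under == 0) & (truth == 0)))
    fp = int(np.sum((pred_under == 1) & (truth == 0)))
    fn = int(np.sum((pred_under == 0) & (truth == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class truth: AUC undefined")
        auc = float("nan")
    else:
        auc = auc_from_scores(100.0 - msei_pred, truth)
    return {
        "accuracy": (tp + tn) / len(truth),
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
        "auc": auc,
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
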