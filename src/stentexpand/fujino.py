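"""The IVOCT calcium-score baseline and its machine-learning variant.

The calcium score grades a lesion 0-4 from three calcification measurements:
2 points for maximum calcium angle > 180 degrees, 1 point for maximum
calcium thickness > 0.5 mm, and 1 point for calcium length > 5 mm (strict
inequalities).  A score of 4 predicts poor stent expansion; 0-3 adequate
expansion.  The "ML variant" trains the pipeline's lesion-mode regression
model on exactly these three measurements, so the comparison isolates the
value of the richer feature set rather than the learning machinery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .expansion import UNDER_EXPANDED, auc_from_scores
from .features import FeatureMatrix, compute_frame_table
from .lesion_features import calc_features_3d
from .pullback import Pullback

FUJINO_FEATURES = ["calc_max_arc_angle_lesion", "calc_max_thickness_lesion", "calc_length"]


@dataclasses.dataclass(frozen=True)
class CalciumScore:
    """Component points and 0-4 total of the calcium score."""

    angle_points: int
    thickness_points: int
    length_points: int

    @property
    def total(self) -> int:
        return self.angle_points + self.thickness_points + self.length_points


def calcium_score(
    max_angle: float, max_thickness: float, calc_length: float
) -> CalciumScore:
    """Score a lesion from its maximum calcium angle (deg), maximum
    thickness (mm) and calcium length (mm); strict > on every criterion."""
    for name, v in (
        ("max_angle", max_angle),
        ("max_thickness", max_thickness),
        ("calc_length", calc_length),
    ):
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"{name} must be non-negative, got {v}")
    return CalciumScore(
        angle_points=2 if max_angle > 180.0 else 0,
        thickness_points=1 if max_thickness > 0.5 else 0,
        length_points=1 if calc_length > 5.0 else 0,
    )


def score_label(s: CalciumScore) -> str:
    """'poor' expansion predicted iff the total score is 4, else 'adequate'."""
    return "poor" if s.total == 4 else "adequate"


def fujino_lesion_features(
    p: Pullback, frame_table: pd.DataFrame | None = None
) -> dict[str, float]:
    """The three score inputs for one lesion: per-lesion maxima of the
    frame-wise calcium angle and thickness, and the 3D calcium length."""
    ft = compute_frame_table(p) if frame_table is None else frame_table
    return {
        "calc_max_arc_angle_lesion": float(ft["calc_max_arc_angle"].max()),
        "calc_max_thickness_lesion": float(ft["calc_max_thickness"].max()),
        "calc_length": calc_features_3d(p)["calc_length"],
    }


def fujino_feature_matrix(
    cohort: list[Pullback], frame_tables: dict[str, pd.DataFrame] | None = None
) -> FeatureMatrix:
    """Three-column lesion matrix (target = actual minimum SEI, %).

    The ML variant regresses the expansion index itself: the three calcium
    measurements carry no vessel-size information, so an area target would
    force a spurious division by an unseen reference at evaluation time.
    """
    rows = {}
    targets = {}
    for p in cohort:
        ft = frame_tables[p.lesion_id] if frame_tables is not None else None
        rows[p.lesion_id] = fujino_lesion_features(p, ft)
        if p.post_stent_area is not None:
            targets[p.lesion_id] = float(
                np.min(p.post_stent_area) / p.mean_ref_area * 100.0
            )
    X = pd.DataFrame.from_dict(rows, orient="index")[FUJINO_FEATURES]
    X.index.name = "lesion_id"
    y = (
        pd.Series(targets, name="msei").reindex(X.index)
        if len(targets) == len(rows)
        else None
    )
    return FeatureMatrix(X=X, y=y, groups=pd.Series(X.index, index=X.index))


def fujino_ml(
    train: FeatureMatrix,
    test: FeatureMatrix,
    test_labels: dict[str, str],
    kind: str = "gaussian_process",
    seed: int = 0,
):
    """Train the lesion-mode model family on the three score features and
    evaluate its under-expansion AUC on held-out lesions.

    ``train``/``test`` come from :func:`fujino_feature_matrix`;
    ``test_labels`` maps lesion_id to the actual expansion class.  Returns
    (fit result, predicted mSEI per test lesion, AUC).
    """
    from .regression import ModelSpec, fit, predict_matrix

    labels = np.asarray([test_labels[i] for i in test.X.index])
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: held-out lesions are single-class")
    spec = ModelSpec(kind=kind, feature_set="all", mode="lesion", seed=seed)
    fres = fit(train, spec)
    msei_pred = predict_matrix(fres, test.X)
    auc = auc_from_scores(100.0 - msei_pred, (labels == UNDER_EXPANDED).astype(int))
    return fres, msei_pred, auc


def score_auc(scores, labels) -> float:
    """AUC of the raw 0-4 calcium score as an ordinal classifier of
    under-expansion (thresholds swept between score levels)."""
    labels = np.asarray(labels)
    truth = (labels == UNDER_EXPANDED).astype(int)
    if truth.min() == truth.max():
        raise ValueError("AUC undefined for single-class truth")
    return auc_from_scores(np.asarray(scores, dtype=float), truth)
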