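"""High-level study harness: train/held-out evaluation of the three analysis
modes and the calcium-score baselines on a labeled cohort.

This module encodes the comparison protocol: lesions are split into a
training and a held-out set (78/32 by default); each analysis mode trains
its regression model on the training lesions, predicts held-out post-stent
area curves, converts them to SEI, extracts the minimum SEI, and is scored
against the actual expansion class.  Default feature sets per mode follow
the feature catalog: windowed CLE aggregates for the segmental mode, the 24
per-frame features for the frame mode, and the lesion-level (3D) feature
group for the lesion mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .expansion import compute_expansion, evaluate_classification, evaluate_regression
from .features import (
    WindowConfig,
    build_frame_matrix,
    build_lesion_matrix,
    build_segmental_matrix,
    compute_frame_table,
    stack_matrices,
)
from .fujino import (
    calcium_score,
    fujino_feature_matrix,
    fujino_lesion_features,
    fujino_ml,
    score_auc,
)
from .pullback import Pullback
from .regression import ModelSpec, fit, predict_area_curve, predict_matrix

DEFAULT_FEATURE_SETS = {"frame": "all", "segmental": "cle", "lesion": "lesion_3d"}

#: frames; median window applied to predicted area curves before SEI
#: extraction.  Per-frame prediction noise is uncorrelated while the true
#: area profile is smooth at the millimetre scale, so a short median filter
#: counters the downward bias of the minimum statistic.
CURVE_MEDIAN_WINDOW = 5


def split_cohort(
    lesion_ids: list[str], n_train: int = 78, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded lesion-level split into training and held-out sets."""
    ids = np.asarray(lesion_ids)
    if n_train >= len(ids):
        raise ValueError(f"cannot hold out lesions: n_train={n_train} >= {len(ids)}")
    perm = np.random.default_rng(seed).permutation(len(ids))
    return list(ids[perm[:n_train]]), list(ids[perm[n_train:]])


def frame_tables(cohort: list[Pullback]) -> dict[str, pd.DataFrame]:
    """Per-frame feature tables for every lesion (the expensive step, shared
    by all modes)."""
    return {p.lesion_id: compute_frame_table(p) for p in cohort}


def evaluate_mode(
    train_cohort: list[Pullback],
    test_cohort: list[Pullback],
    truth_labels: dict[str, str],
    mode: str = "segmental",
    kind: str = "gaussian_process",
    feature_set: str | None = None,
    window: WindowConfig | None = None,
    seed: int = 0,
    tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, object]:
    """Train one analysis mode and evaluate it on held-out lesions.

    Returns regression metrics on the held-out area curves (frame and
    segmental modes), per-lesion predicted mSEI values, and classification
    metrics against the actual labels.
    """
    if tables is None:
        tables = frame_tables(train_cohort + test_cohort)
    feature_set = feature_set or DEFAULT_FEATURE_SETS[mode]
    window = window or WindowConfig(31)
    if mode == "segmental":
        m = stack_matrices(
            [build_segmental_matrix(p, window, tables[p.lesion_id]) for p in train_cohort]
        )
    elif mode == "frame":
        m = stack_matrices(
            [build_frame_matrix(p, tables[p.lesion_id]) for p in train_cohort]
        )
    elif mode == "lesion":
        m = build_lesion_matrix(train_cohort, frame_tables=tables)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    spec = ModelSpec(
        kind=kind,
        feature_set=feature_set,
        mode=mode,
        window=window if mode == "segmental" else None,
        seed=seed,
    )
    fres = fit(m, spec)

    msei_pred, labels = [], []
    pred_areas, actual_areas = [], []
    for p in test_cohort:
        if mode == "lesion":
            mt = build_lesion_matrix([p], frame_tables=tables)
            area = float(predict_matrix(fres, mt.X)[0])
            mp = area / p.mean_ref_area * 100.0
        else:
            curve = predict_area_curve(fres, p, tables[p.lesion_id])
            if CURVE_MEDIAN_WINDOW > 1 and len(curve) >= CURVE_MEDIAN_WINDOW:
                curve = pd.Series(
                    median_filter(curve.to_numpy(), size=CURVE_MEDIAN_WINDOW, mode="nearest"),
                    index=curve.index,
                    name=curve.name,
                )
            res = compute_expansion(
                curve.to_numpy(),
                p.ref_proximal_area,
                p.ref_distal_area,
                frames=curve.index,
                source="predicted",
            )
            mp = res.msei
            actual = pd.Series(p.post_stent_area, index=list(p.stent_frames))
            pred_areas.extend(curve.to_numpy())
            actual_areas.extend(actual.loc[curve.index].to_numpy())
        msei_pred.append(mp)
        labels.append(truth_labels[p.lesion_id])
    out: dict[str, object] = {
        "mode": mode,
        "model": kind,
        "feature_set": feature_set,
        "msei_pred": np.asarray(msei_pred),
        "lesion_ids": [p.lesion_id for p in test_cohort],
        "classification": evaluate_classification(np.asarray(msei_pred), np.asarray(labels)),
        "fit": fres,
    }
    if pred_areas:
        out["regression"] = evaluate_regression(pred_areas, actual_areas)
    return out


def compare_methods(
    cohort: list[Pullback],
    truth: pd.DataFrame,
    seed: int = 0,
    n_train: int = 78,
    kind: str = "gaussian_process",
    window: WindowConfig | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Head-to-head AUC table: the three analysis modes, the calcium-score
    ML variant, and the raw calcium score, on one seeded 78/32 split."""
    truth_map = truth.set_index("lesion_id")
    train_ids, test_ids = split_cohort(list(truth.lesion_id), n_train, seed)
    by_id = {p.lesion_id: p for p in cohort}
    train_c = [by_id[i] for i in train_ids]
    test_c = [by_id[i] for i in test_ids]
    labels = {i: truth_map.loc[i, "label"] for i in truth_map.index}
    if tables is None:
        tables = frame_tables(cohort)

    rows = []
    for mode in ("segmental", "frame", "lesion"):
        res = evaluate_mode(
            train_c, test_c, labels, mode=mode, kind=kind, seed=seed,
            window=window, tables=tables,
        )
        row = {"method": mode, "auc": res["classification"]["auc"],
               "accuracy": res["classification"]["accuracy"],
               "sensitivity": res["classification"]["sensitivity"],
               "specificity": res["classification"]["specificity"]}
        if "regression" in res:
            row.update(rmse=res["regression"]["rmse"], pearson_r=res["regression"]["pearson_r"])
        rows.append(row)

    fm_train = fujino_feature_matrix(train_c, tables)
    fm_test = fujino_feature_matrix(test_c, tables)
    _, _, auc_ml = fujino_ml(fm_train, fm_test, labels, kind=kind, seed=seed)
    rows.append({"method": "fujino_ml", "auc": auc_ml})

    scores = [
        calcium_score(
            *(fujino_lesion_features(p, tables[p.lesion_id])[k] for k in (
                "calc_max_arc_angle_lesion", "calc_max_thickness_lesion", "calc_length"))
        ).total
        for p in test_c
    ]
    rows.append({
        "method": "calcium_score",
        "auc": score_auc(scores, [labels[p.lesion_id] for p in test_c]),
    })
    return pd.DataFrame(rows).set_index("method")


def compare_methods_mean(
    cohort: list[Pullback],
    truth: pd.DataFrame,
    split_seeds=(0, 1, 2),
    **kwargs,
) -> pd.DataFrame:
    """Mean metrics of :func:`compare_methods` over several train/held-out
    splits, the split-averaged form in which comparative performance of the
    approaches is reported."""
    tables = kwargs.pop("tables", None) or frame_tables(cohort)
    frames = [
        compare_methods(cohort, truth, seed=s, tables=tables, **kwargs)
        for s in split_seeds
    ]
    return sum(frames[1:], frames[0]) / len(frames)
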