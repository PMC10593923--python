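"""Regression models predicting post-stent lumen area, with LASSO feature
ranking and lesion-grouped cross-validation.

All rows belonging to one lesion always share a cross-validation fold, since
neighbouring frames of a lesion are strongly correlated and would otherwise
leak between training and validation.  Feature normalization and LASSO
selection are refit inside every fold on the training lesions only.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LassoCV, LinearRegression, lasso_path
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .features import FeatureMatrix, WindowConfig, apply_normalization, normalize, select_cle

MODEL_KINDS = ("linear", "gaussian_process", "tree", "svr", "ensemble")
FEATURE_SETS = ("all", "lasso_all", "cle", "lasso_cle_top20", "lesion_3d")

#: rows above which Gaussian-process training uses a seeded subsample
#: (cubic-cost kernel solves; see the methods note)
MAX_GPR_ROWS = 1500

AREA_FLOOR = 0.1  # mm^2; predictions are floored here


@dataclasses.dataclass
class ModelSpec:
    """What to train: model family, feature subset, analysis mode, seed."""

    kind: str = "gaussian_process"
    feature_set: str = "cle"
    mode: str = "segmental"  # frame | segmental | lesion
    window: WindowConfig | None = dataclasses.field(default_factory=WindowConfig)
    seed: int = 0
    n_top: int = 20

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.mode not in ("frame", "segmental", "lesion"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "segmental":
            self.window = None
        elif self.window is None:
            self.window = WindowConfig()


@dataclasses.dataclass
class FitResult:
    """A trained model with everything needed to apply it to new lesions."""

    model: object
    feature_names: list[str]
    normalization: dict[str, object]
    spec: ModelSpec
    cv_metrics: pd.DataFrame | None = None


def _make_model(kind: str, seed: int):
    if kind == "linear":
        return LinearRegression()
    if kind == "gaussian_process":
        kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(
            length_scale=1.0, length_scale_bounds=(1e-2, 1e3)
        ) + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-8, 1e2))
        gpr = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=2,
            random_state=seed,
        )
        # inputs standardized for kernel conditioning; the min-max policy of
        # the feature matrix is about interpretability, this is numerics
        return make_pipeline(StandardScaler(), gpr)
    if kind == "tree":
        return DecisionTreeRegressor(random_state=seed)
    if kind == "svr":
        return make_pipeline(StandardScaler(), SVR())
    if kind == "ensemble":
        return RandomForestRegressor(n_estimators=200, random_state=seed)
    raise ValueError(kind)


def lasso_rank(
    m: FeatureMatrix, seed: int = 0, cv: int = 5
) -> list[tuple[str, float]]:
    """Rank features by LASSO on internally standardized data.

    The penalty is chosen by lesion-grouped cross-validation minimizing RMSE
    along the regularization path.  Features are ranked by the absolute
    standardized coefficient at the chosen penalty; exact zeros are dropped;
    ties break by earlier entry on the path (larger penalty at first
    activation).
    """
    if m.y is None:
        raise ValueError("lasso_rank requires a labeled matrix")
    y = m.y.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant; LASSO ranking undefined")
    groups = m.groups.to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("lasso_rank requires at least 2 lesions")
    scaler = StandardScaler()
    X = scaler.fit_transform(m.X.to_numpy(dtype=float))
    X = np.nan_to_num(X)  # zero-variance columns standardize to 0
    n_splits = min(cv, len(np.unique(groups)))
    folds = list(GroupKFold(n_splits=n_splits).split(X, y, groups))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(cv=folds, random_state=seed, max_iter=5000).fit(X, y)
        alphas, coef_paths, _ = lasso_path(X, y, alphas=model.alphas_)
    coefs = model.coef_
    # first path index (largest alpha) at which each feature becomes active
    entry = np.full(X.shape[1], np.inf)
    for j in range(X.shape[1]):
        nz = np.nonzero(np.abs(coef_paths[j]) > 0)[0]
        if nz.size:
            entry[j] = nz[0]
    order = sorted(
        (j for j in range(X.shape[1]) if coefs[j] != 0.0),
        key=lambda j: (-abs(coefs[j]), entry[j], j),
    )
    names = list(m.X.columns)
    return [(names[j], float(coefs[j])) for j in order]


def _resolve_features(m: FeatureMatrix, spec: ModelSpec) -> list[str]:
    if spec.feature_set == "all":
        return list(m.X.columns)
    if spec.feature_set == "cle":
        return list(select_cle(m).X.columns)
    if spec.feature_set == "lesion_3d":
        from .lesion_features import LESION_FEATURE_NAMES

        missing = [c for c in LESION_FEATURE_NAMES if c not in m.X.columns]
        if missing:
            raise KeyError(f"matrix lacks lesion-level column(s) {missing}")
        return list(LESION_FEATURE_NAMES)
    if spec.feature_set == "lasso_all":
        ranked = lasso_rank(m, seed=spec.seed)
        return [name for name, _ in ranked] or list(m.X.columns)
    if spec.feature_set == "lasso_cle_top20":
        ranked = lasso_rank(select_cle(m), seed=spec.seed)
        return [name for name, _ in ranked[: spec.n_top]]
    raise ValueError(spec.feature_set)


def _subsample_rows(n: int, cap: int, seed: int) -> np.ndarray:
    """Systematic thinning to at most ``cap`` rows.

    Rows of frame/segmental matrices are consecutive (stride-1) windows and
    therefore almost entirely redundant with their neighbours; taking every
    k-th row preserves lesion coverage far better than a uniform random
    subsample of the same size.  Deterministic; ``seed`` is unused but kept
    for signature stability.
    """
    if n <= cap:
        return np.arange(n)
    k = int(np.ceil(n / cap))
    return np.arange(0, n, k)


def fit(m: FeatureMatrix, spec: ModelSpec) -> FitResult:
    """Normalize, resolve the feature subset and train on all rows of ``m``."""
    if m.y is None:
        raise ValueError("fit requires a labeled matrix")
    norm = normalize(m)
    feats = _resolve_features(norm, spec)
    X = norm.X[feats].to_numpy(dtype=float)
    y = norm.y.to_numpy(dtype=float)
    model = _make_model(spec.kind, spec.seed)
    if spec.kind == "gaussian_process":
        keep = _subsample_rows(len(X), MAX_GPR_ROWS, spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[keep], y[keep])
    else:
        model.fit(X, y)
    return FitResult(
        model=model, feature_names=feats, normalization=norm.normalization, spec=spec
    )


def _regression_metrics(pred: np.ndarray, actual: np.ndarray) -> dict[str, float]:
    resid = pred - actual
    r = (
        float(np.corrcoef(pred, actual)[0, 1])
        if np.ptp(pred) > 0 and np.ptp(actual) > 0
        else 0.0
    )
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "pearson_r": r,
        "bias": float(np.mean(resid)),
    }


def _lesion_folds(groups: np.ndarray, k: int, seed: int, lesion_labels=None):
    """Lesion-grouped folds, stratified by expansion class when given."""
    lesions = np.unique(groups)
    if len(lesions) < k:
        raise ValueError(f"{len(lesions)} lesions cannot form {k} folds")
    if lesion_labels is not None:
        strat = np.asarray([lesion_labels[g] for g in groups])
        classes, counts = np.unique(
            [lesion_labels[les] for les in lesions], return_counts=True
        )
        if len(classes) >= 2 and counts.min() >= k:
            cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
            return list(cv.split(np.zeros(len(groups)), strat, groups))
        warnings.warn("cannot stratify folds by class; falling back to unstratified")
    cv = GroupKFold(n_splits=k)
    return list(cv.split(np.zeros(len(groups)), groups=groups))


def cross_validate(
    m: FeatureMatrix,
    spec: ModelSpec,
    k: int = 5,
    lesion_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """k-fold lesion-grouped CV; normalization and LASSO refit per fold.

    Returns one row of metrics (RMSE, Pearson r, bias) per fold.
    """
    if m.y is None:
        raise ValueError("cross_validate requires a labeled matrix")
    groups = m.groups.to_numpy()
    folds = _lesion_folds(groups, k, spec.seed, lesion_labels)
    records = []
    for i, (tr, te) in enumerate(folds):
        train = FeatureMatrix(
            X=m.X.iloc[tr], y=m.y.iloc[tr], groups=m.groups.iloc[tr]
        )
        fres = fit(train, spec)
        pred = predict_matrix(fres, m.X.iloc[te])
        rec = _regression_metrics(pred, m.y.iloc[te].to_numpy(dtype=float))
        rec["fold"] = i
        rec["n_test_rows"] = len(te)
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("fold")


def predict_matrix(fres: FitResult, X_raw: pd.DataFrame) -> np.ndarray:
    """Apply a fit (normalization + feature subset + model) to raw rows."""
    Xn = apply_normalization(X_raw, fres.normalization)
    pred = np.asarray(fres.model.predict(Xn[fres.feature_names].to_numpy(dtype=float)))
    if (pred < AREA_FLOOR).any():
        warnings.warn(
            f"{int((pred < AREA_FLOOR).sum())} prediction(s) below "
            f"{AREA_FLOOR} mm^2 floored"
        )
        pred = np.maximum(pred, AREA_FLOOR)
    return pred


def predict_area_curve(fres: FitResult, p, frame_table=None) -> pd.Series:
    """Per-frame predicted post-stent lumen area (mm^2) for one pullback.

    In segmental mode predictions exist for full-window center frames only;
    in frame mode every stented frame is predicted.  Lesion mode has no
    per-frame curve and is rejected.
    """
    from .features import build_frame_matrix, build_segmental_matrix

    spec = fres.spec
    if spec.mode == "frame":
        fm = build_frame_matrix(p, frame_table)
    elif spec.mode == "segmental":
        fm = build_segmental_matrix(p, spec.window, frame_table)
        if len(fm) == 0:
            raise ValueError(
                f"lesion {p.lesion_id}: stented segment shorter than the "
                f"{spec.window.length}-frame window"
            )
    else:
        raise ValueError("per-frame area curves require frame or segmental mode")
    pred = predict_matrix(fres, fm.X)
    frames = fm.X.index.get_level_values("frame")
    return pd.Series(pred, index=frames, name="predicted_post_stent_area")
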