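"""Feature-matrix assembly: frame, segmental and lesion designs.

Three designs feed the regression models:

* frame — the 24 per-frame features, one row per stented frame;
* segmental — a moving window of odd length L (3/7/15/31/63 frames, stride 1)
  slides across the stented segment; each of the 24 per-frame features is
  summarized by 7 first-order statistics (min, max, mean, median, SD,
  skewness, kurtosis), giving 168 aggregated columns per center frame, plus
  window-level lumen volume, calcification volume and calcification
  percentage; the regression target is the post-stent lumen area at the
  window's center frame;
* lesion — one row per lesion: the volumetric features plus whole-segment
  aggregates of the 2D features (and optionally a one-hot calcification
  phenotype); the target is the minimum post-stent area in the segment.

Normalization is min–max to [0, 1] fitted on training rows only; features
carrying absolute physical magnitude (areas, volumes, lengths, diameters,
thickness, depth, perimeters) are deliberately left on their physical scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .frame_features import FRAME_FEATURE_NAMES, compute_frame_features
from .lesion_features import compute_lesion_features
from .pullback import Pullback, PullbackError

STAT_NAMES = ["min", "max", "mean", "median", "sd", "skewness", "kurtosis"]

WINDOW_LENGTHS = (3, 7, 15, 31, 63)

PHENOTYPES = ("nodule", "protrusion", "sheet")


@dataclasses.dataclass(frozen=True)
class WindowConfig:
    """Moving-window configuration: odd length in frames, stride in frames."""

    length: int = 31
    stride: int = 1

    def __post_init__(self) -> None:
        if self.length < 1 or self.length % 2 == 0:
            raise ValueError(f"window length must be odd and >= 1, got {self.length}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclasses.dataclass
class FeatureMatrix:
    """Named feature columns x instances, with optional target and the
    min–max normalization record ('absolute' marks unscaled columns)."""

    X: pd.DataFrame
    y: pd.Series | None = None
    groups: pd.Series | None = None  # lesion_id per row
    normalization: dict[str, object] | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)


def aggregate_stats(values) -> dict[str, float]:
    """Seven first-order statistics of a sequence.

    SD is the sample standard deviation; skewness and kurtosis are
    moment-based with kurtosis on the non-excess (normal = 3) convention.
    Constant sequences return 0 for SD, skewness and kurtosis (the latter two
    as a defined-as-zero sentinel for the otherwise indeterminate ratio).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("aggregate_stats requires at least one value")
    constant = v.size == 1 or np.ptp(v) == 0
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": 0.0 if constant else float(v.std(ddof=1)),
        "skewness": 0.0 if constant else float(stats.skew(v, bias=True)),
        "kurtosis": 0.0 if constant else float(stats.kurtosis(v, fisher=False, bias=True)),
    }


def compute_frame_table(p: Pullback) -> pd.DataFrame:
    """Per-frame 24-feature table over the stented segment, indexed by frame."""
    rows = {
        f: compute_frame_features(p.frames[f], p.ref_proximal_area, p.ref_distal_area)
        for f in p.stent_frames
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "frame"
    return df[FRAME_FEATURE_NAMES]


def _row_index(p: Pullback, frames) -> pd.MultiIndex:
    return pd.MultiIndex.from_arrays(
        [[p.lesion_id] * len(frames), list(frames)], names=["lesion_id", "frame"]
    )


def build_frame_matrix(p: Pullback, frame_table: pd.DataFrame | None = None) -> FeatureMatrix:
    """One row per stented frame with the raw 24 per-frame features."""
    ft = compute_frame_table(p) if frame_table is None else frame_table
    X = ft.copy()
    X.index = _row_index(p, ft.index)
    y = None
    if p.post_stent_area is not None:
        y = pd.Series(p.post_stent_area, index=X.index, name="post_stent_area")
    groups = pd.Series(p.lesion_id, index=X.index, name="lesion_id")
    return FeatureMatrix(X=X, y=y, groups=groups)


def build_segmental_matrix(
    p: Pullback, w: WindowConfig, frame_table: pd.DataFrame | None = None
) -> FeatureMatrix:
    """Moving-window aggregated matrix; one row per full-window center frame.

    Only windows lying entirely inside the stented segment produce rows (no
    edge padding), so a segment of n frames yields n - L + 1 rows at stride 1.
    """
    ft = compute_frame_table(p) if frame_table is None else frame_table
    n = len(ft)
    L = w.length
    half = L // 2
    if n < L:
        warnings.warn(
            f"lesion {p.lesion_id}: stented segment ({n} frames) shorter than "
            f"window ({L}); empty matrix"
        )
        empty_cols = [f"{f}__{s}" for f in FRAME_FEATURE_NAMES for s in STAT_NAMES]
        idx = _row_index(p, [])
        return FeatureMatrix(
            X=pd.DataFrame(columns=empty_cols, index=idx),
            y=pd.Series(dtype=float, index=idx) if p.post_stent_area is not None else None,
            groups=pd.Series(dtype=object, index=idx),
        )
    vals = ft.to_numpy()  # n x 24
    windows = np.lib.stride_tricks.sliding_window_view(vals, L, axis=0)  # (n-L+1, 24, L)
    windows = windows[:: w.stride]
    centers = np.asarray(ft.index)[half : n - half : w.stride]

    mean = windows.mean(axis=2)
    sd = windows.std(axis=2, ddof=1)
    ptp = windows.max(axis=2) - windows.min(axis=2)
    m2 = windows.var(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        m3 = ((windows - mean[..., None]) ** 3).mean(axis=2)
        m4 = ((windows - mean[..., None]) ** 4).mean(axis=2)
        skew = np.where(ptp == 0, 0.0, m3 / np.where(m2 == 0, 1.0, m2) ** 1.5)
        kurt = np.where(ptp == 0, 0.0, m4 / np.where(m2 == 0, 1.0, m2) ** 2)
    stat_arrays = {
        "min": windows.min(axis=2),
        "max": windows.max(axis=2),
        "mean": mean,
        "median": np.median(windows, axis=2),
        "sd": np.where(ptp == 0, 0.0, sd),
        "skewness": skew,
        "kurtosis": kurt,
    }
    data = {}
    for j, feat in enumerate(FRAME_FEATURE_NAMES):
        for s in STAT_NAMES:
            data[f"{feat}__{s}"] = stat_arrays[s][:, j]

    # window-level volumetric summaries (used by the CLE feature subset)
    fs = p.frame_spacing
    area_w = np.lib.stride_tricks.sliding_window_view(
        ft["lumen_area"].to_numpy(), L
    )[:: w.stride]
    carea_w = np.lib.stride_tricks.sliding_window_view(
        ft["calc_area"].to_numpy(), L
    )[:: w.stride]
    data["lumen_volume"] = area_w.sum(axis=1) * fs
    data["calc_volume"] = carea_w.sum(axis=1) * fs
    data["calc_percent"] = 100.0 * (carea_w > 0).mean(axis=1)

    X = pd.DataFrame(data, index=_row_index(p, centers))
    y = None
    if p.post_stent_area is not None:
        post = pd.Series(p.post_stent_area, index=list(p.stent_frames))
        y = pd.Series(post.loc[centers].to_numpy(), index=X.index, name="post_stent_area")
    groups = pd.Series(p.lesion_id, index=X.index, name="lesion_id")
    return FeatureMatrix(X=X, y=y, groups=groups)


def build_lesion_matrix(
    cohort: list[Pullback],
    include_phenotype: bool = False,
    frame_tables: dict[str, pd.DataFrame] | None = None,
) -> FeatureMatrix:
    """One row per lesion: volumetric features + whole-segment aggregates of
    the per-frame features (+ optional one-hot phenotype)."""
    rows = {}
    targets = {}
    for p in cohort:
        feats = dict(compute_lesion_features(p))
        ft = (
            frame_tables[p.lesion_id]
            if frame_tables is not None
            else compute_frame_table(p)
        )
        for feat in FRAME_FEATURE_NAMES:
            for s, val in aggregate_stats(ft[feat].to_numpy()).items():
                feats[f"{feat}__{s}"] = val
        if include_phenotype:
            if p.phenotype is None:
                raise PullbackError(
                    f"lesion {p.lesion_id}: phenotype covariate requested but missing"
                )
            for ph in PHENOTYPES:
                feats[f"phenotype_{ph}"] = float(p.phenotype == ph)
        rows[p.lesion_id] = feats
        if p.post_stent_area is not None:
            targets[p.lesion_id] = float(np.min(p.post_stent_area))
    X = pd.DataFrame.from_dict(rows, orient="index")
    X.index.name = "lesion_id"
    y = None
    if targets and len(targets) == len(rows):
        y = pd.Series(targets, name="post_stent_area").reindex(X.index)
    groups = pd.Series(X.index, index=X.index, name="lesion_id")
    return FeatureMatrix(X=X, y=y, groups=groups)


# Base features whose absolute physical magnitude matters; these stay on
# their native scale (mm, mm^2, mm^3) rather than being min-max scaled.
ABSOLUTE_BASES = frozenset(
    {
        "lumen_area",
        "lumen_major_axis",
        "lumen_minor_axis",
        "lumen_perimeter",
        "calc_max_thickness",
        "calc_max_depth",
        "calc_area",
        "calc_major_axis",
        "calc_minor_axis",
        "calc_perimeter",
        "lumen_volume",
        "lumen_equivalent_diameter",
        "lumen_convex_volume",
        "lumen_surface_area",
        "calc_volume",
        "calc_volume_index",
        "calc_length",
        "calc_equivalent_diameter",
        "calc_convex_volume",
        "calc_surface_area",
    }
)


def _base_name(column: str) -> str:
    return column.split("__", 1)[0]


def normalize(m: FeatureMatrix, fit_rows=None) -> FeatureMatrix:
    """Min–max scale the relative-valued columns to [0, 1].

    Scaling parameters are fitted on ``fit_rows`` (training subset; default
    all rows) and applied to every row — values outside the training range
    are passed through unclipped and may fall outside [0, 1].  Columns whose
    base feature is in :data:`ABSOLUTE_BASES` are recorded as ``'absolute'``
    and left untouched.  Zero-range columns map to 0 with a warning.
    """
    fit = m.X if fit_rows is None else m.X.loc[fit_rows]
    if len(fit) == 0:
        raise ValueError("normalization requires a non-empty training subset")
    record: dict[str, object] = {}
    X = m.X.copy()
    for col in X.columns:
        if _base_name(col) in ABSOLUTE_BASES:
            record[col] = "absolute"
            continue
        lo, hi = float(fit[col].min()), float(fit[col].max())
        if hi == lo:
            warnings.warn(f"column {col!r} has zero range on training rows; set to 0")
            X[col] = 0.0
            record[col] = ("minmax", lo, lo + 1.0)
        else:
            X[col] = (X[col] - lo) / (hi - lo)
            record[col] = ("minmax", lo, hi)
    return FeatureMatrix(X=X, y=m.y, groups=m.groups, normalization=record)


def apply_normalization(X: pd.DataFrame, record: dict[str, object]) -> pd.DataFrame:
    """Apply a previously fitted normalization record to new rows."""
    X = X.copy()
    for col, rec in record.items():
        if rec == "absolute" or col not in X.columns:
            continue
        _, lo, hi = rec
        X[col] = (X[col] - lo) / (hi - lo)
    return X


# The hand-picked calcification lesion expansion (CLE) subset: the 20
# aggregate features covering calcification angle/area/thickness/depth and
# lumen area / percent area stenosis (mean, median, SD as applicable) plus
# lumen volume, calcification volume and calcification percentage, listed in
# decreasing LASSO importance.
CLE_COLUMNS = [
    "calc_max_arc_angle__mean",
    "lumen_area__mean",
    "lumen_pct_area_stenosis__median",
    "lumen_pct_area_stenosis__mean",
    "calc_area__mean",
    "calc_max_arc_angle__sd",
    "lumen_pct_area_stenosis__sd",
    "calc_percent",
    "calc_area__sd",
    "lumen_area__sd",
    "calc_max_thickness__median",
    "calc_max_depth__mean",
    "calc_max_thickness__sd",
    "lumen_volume",
    "calc_max_depth__median",
    "calc_max_thickness__mean",
    "calc_max_arc_angle__median",
    "calc_area__median",
    "calc_volume",
    "calc_max_depth__sd",
]


def select_cle(m: FeatureMatrix) -> FeatureMatrix:
    """Restrict a matrix to the 20-column CLE subset."""
    missing = [c for c in CLE_COLUMNS if c not in m.X.columns]
    if missing:
        raise KeyError(
            f"matrix lacks CLE column(s) {missing}; segmental or lesion "
            "aggregation is required"
        )
    return FeatureMatrix(
        X=m.X[CLE_COLUMNS].copy(),
        y=m.y,
        groups=m.groups,
        normalization=(
            {c: m.normalization[c] for c in CLE_COLUMNS} if m.normalization else None
        ),
    )


def stack_matrices(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate per-lesion matrices (rows) into one cohort matrix."""
    nonempty = [m for m in matrices if len(m) > 0]
    if not nonempty:
        raise ValueError("no rows to stack")
    X = pd.concat([m.X for m in nonempty])
    ys = [m.y for m in nonempty]
    y = pd.concat(ys) if all(y is not None for y in ys) else None
    groups = pd.concat([m.groups for m in nonempty])
    return FeatureMatrix(X=X, y=y, groups=groups)
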