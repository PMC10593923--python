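"""Data model and I/O for labeled IVOCT pullbacks.

A pullback is the ordered stack of cross-sectional frames acquired while the
imaging catheter is withdrawn through the vessel at constant speed.  Each
frame here is a segmentation label mask (0 = background, 1 = lumen,
2 = calcification); the raw OCT signal and the segmentation step itself are
out of scope — masks are the input.

Storage dialect: a multi-page 8-bit TIFF label stack plus a JSON metadata
sidecar (lesion id, spacings, reference lumen areas, stented segment, and —
for training data — the registered per-frame post-stent lumen areas).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

BACKGROUND = 0
LUMEN = 1
CALCIFICATION = 2

_VALID_LABELS = frozenset({BACKGROUND, LUMEN, CALCIFICATION})

# 8-connectivity for in-plane connected components
_STRUCT_2D = np.ones((3, 3), dtype=bool)


class PullbackError(ValueError):
    """Raised for malformed masks or metadata."""


@dataclasses.dataclass
class FrameMask:
    """One cross-sectional label mask with isotropic in-plane spacing (mm/px)."""

    labels: np.ndarray
    pixel_spacing: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise PullbackError(f"frame {self.frame_index}: labels must be 2D")
        if not np.isfinite(self.pixel_spacing) or self.pixel_spacing <= 0:
            raise PullbackError(
                f"frame {self.frame_index}: pixel_spacing must be a positive number"
            )
        bad = set(np.unique(self.labels)) - _VALID_LABELS
        if bad:
            raise PullbackError(
                f"frame {self.frame_index}: label values outside {{0,1,2}}: {sorted(bad)}"
            )

    @property
    def lumen_mask(self) -> np.ndarray:
        return self.labels == LUMEN

    @property
    def calc_mask(self) -> np.ndarray:
        return self.labels == CALCIFICATION

    def has_lumen(self) -> bool:
        return bool(self.lumen_mask.any())

    def keep_largest_lumen(self) -> "FrameMask":
        """Return a copy with only the largest connected lumen component.

        Masks occasionally carry spurious secondary lumen blobs (e.g. a side
        branch); the vessel lumen is taken to be the largest component and
        the rest is relabeled as background, with a warning.
        """
        lab, n = ndimage.label(self.lumen_mask, structure=_STRUCT_2D)
        if n <= 1:
            return self
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(
            f"frame {self.frame_index}: {n} lumen components, keeping largest",
            stacklevel=2,
        )
        labels = self.labels.copy()
        labels[(lab > 0) & (lab != keep)] = BACKGROUND
        return FrameMask(labels, self.pixel_spacing, self.frame_index)


@dataclasses.dataclass
class Pullback:
    """An ordered lesion pullback (distal to proximal) with lesion metadata.

    ``stent_segment`` is the inclusive 0-based frame range covered by the
    stent; ``ref_proximal_area`` / ``ref_distal_area`` are the largest lumen
    areas within the reference zones adjacent to that segment (mm^2).
    ``post_stent_area``, when present, holds one registered post-stent lumen
    area per stented frame and serves as the regression training label.
    """

    frames: list[FrameMask]
    frame_spacing: float
    lesion_id: str
    ref_proximal_area: float
    ref_distal_area: float
    stent_segment: tuple[int, int]
    post_stent_area: np.ndarray | None = None
    phenotype: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.frame_spacing) or self.frame_spacing <= 0:
            raise PullbackError("frame_spacing must be a positive number")
        for ref in (self.ref_proximal_area, self.ref_distal_area):
            if not np.isfinite(ref) or ref <= 0:
                raise PullbackError("reference areas must be positive")
        first, last = self.stent_segment
        if not (0 <= first <= last < len(self.frames)):
            raise PullbackError(
                f"stent_segment {self.stent_segment} outside frame range "
                f"[0, {len(self.frames) - 1}]"
            )
        self.stent_segment = (int(first), int(last))
        if self.post_stent_area is not None:
            self.post_stent_area = np.asarray(self.post_stent_area, dtype=float)
            if len(self.post_stent_area) != self.n_stent_frames:
                raise PullbackError(
                    "post_stent_area must have one value per stented frame "
                    f"({self.n_stent_frames}), got {len(self.post_stent_area)}"
                )
        if self.phenotype is not None and self.phenotype not in (
            "nodule",
            "protrusion",
            "sheet",
        ):
            raise PullbackError(f"unknown phenotype {self.phenotype!r}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_stent_frames(self) -> int:
        return self.stent_segment[1] - self.stent_segment[0] + 1

    @property
    def stent_frames(self) -> range:
        return range(self.stent_segment[0], self.stent_segment[1] + 1)

    @property
    def pixel_spacing(self) -> float:
        return self.frames[0].pixel_spacing

    @property
    def mean_ref_area(self) -> float:
        return 0.5 * (self.ref_proximal_area + self.ref_distal_area)

    @property
    def length_mm(self) -> float:
        return self.n_frames * self.frame_spacing


def frame_spacing_from_acquisition(pullback_length_mm: float, n_frames: int) -> float:
    """Frame spacing implied by an acquisition, e.g. 75 mm / 375 frames = 0.2 mm."""
    if pullback_length_mm <= 0 or n_frames <= 0:
        raise PullbackError("pullback length and frame count must be positive")
    return pullback_length_mm / n_frames


def save_pullback(p: Pullback, mask_path: str | Path, meta_path: str | Path) -> None:
    """Write the label stack (multi-page uint8 TIFF) and JSON metadata sidecar."""
    stack = np.stack([f.labels.astype(np.uint8) for f in p.frames])
    tifffile.imwrite(str(mask_path), stack)
    meta = {
        "lesion_id": p.lesion_id,
        "frame_spacing_mm": p.frame_spacing,
        "pixel_spacing_mm": p.pixel_spacing,
        "ref_proximal_area_mm2": p.ref_proximal_area,
        "ref_distal_area_mm2": p.ref_distal_area,
        "stent_segment": list(p.stent_segment),
        "phenotype": p.phenotype,
    }
    if p.post_stent_area is not None:
        meta["post_stent_area_mm2"] = [float(v) for v in p.post_stent_area]
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def load_pullback(mask_path: str | Path, meta_path: str | Path) -> Pullback:
    """Load and validate a pullback from a label stack + metadata sidecar.

    Frames are ordered by page index (distal to proximal).  Each frame must
    contain a lumen; multiple lumen components are reduced to the largest
    with a warning.  Label values outside {0,1,2}, missing/invalid spacings
    and mask/metadata frame-count mismatches are hard errors.
    """
    mask_path, meta_path = Path(mask_path), Path(meta_path)
    if not mask_path.exists():
        raise PullbackError(f"mask stack not found: {mask_path}")
    if not meta_path.exists():
        raise PullbackError(f"metadata not found: {meta_path}")
    stack = tifffile.imread(str(mask_path))
    if stack.ndim == 2:
        stack = stack[None]
    meta = json.loads(meta_path.read_text())
    for key in ("frame_spacing_mm", "pixel_spacing_mm"):
        v = meta.get(key)
        if v is None or not np.isfinite(v) or v <= 0:
            raise PullbackError(f"metadata {key} missing or invalid: {v!r}")
    post = meta.get("post_stent_area_mm2")
    if post is not None:
        post = np.asarray(post, dtype=float)
    px = float(meta["pixel_spacing_mm"])
    frames = []
    for i, labels in enumerate(stack):
        f = FrameMask(labels, px, i)  # raises on bad labels, names the frame
        if not f.has_lumen():
            raise PullbackError(f"no lumen in frame {i}")
        frames.append(f.keep_largest_lumen())
    return Pullback(
        frames=frames,
        frame_spacing=float(meta["frame_spacing_mm"]),
        lesion_id=str(meta["lesion_id"]),
        ref_proximal_area=float(meta["ref_proximal_area_mm2"]),
        ref_distal_area=float(meta["ref_distal_area_mm2"]),
        stent_segment=tuple(meta["stent_segment"]),
        post_stent_area=post,
        phenotype=meta.get("phenotype"),
    )


@dataclasses.dataclass
class ValidationReport:
    """Non-mutating pullback sanity report: list of (issue_code, detail)."""

    issues: list[tuple[str, object]] = dataclasses.field(default_factory=list)

    def ok(self) -> bool:
        return not self.issues

    def codes(self) -> list[str]:
        return [code for code, _ in self.issues]


def validate_pullback(p: Pullback) -> ValidationReport:
    """Report frames with no lumen, calcification without lumen, metadata gaps."""
    report = ValidationReport()
    for f in p.frames:
        if not f.has_lumen():
            report.issues.append(("no_lumen", f.frame_index))
            if f.calc_mask.any():
                report.issues.append(("calc_without_lumen", f.frame_index))
    if p.post_stent_area is not None and len(p.post_stent_area) != p.n_stent_frames:
        report.issues.append(("label_length_mismatch", len(p.post_stent_area)))
    if p.post_stent_area is not None and not np.all(np.isfinite(p.post_stent_area)):
        report.issues.append(("nonfinite_post_area", None))
    return report
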