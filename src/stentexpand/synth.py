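"""Seeded generator of synthetic labeled IVOCT pullbacks.

Each synthetic lesion is a stack of label masks with a smooth stenotic
lumen-area profile along the pullback and one or more calcific deposits
rendered as annular sectors around the lumen.  Deposit geometry follows the
three clinical phenotypes: an eruptive calcified nodule is a protruding
deposit with an irregular (jittered) leading edge; a calcified protrusion is
a smooth sector bulging into the lumen; a superficial calcific sheet is a
wide, comparatively thin sector lying at depth ~0 just outside the lumen
border.

Ground-truth post-stent lumen areas are produced by an explicit expansion
response: the stent is assumed to restore the lumen to the reference area
except where local calcification burden resists dilation,

    E(f) = clamp(1 - alpha * (theta_w(f)/360) * min(T_w(f)/T0, 1), E_min, 1)
    post_area(f) = max(E(f) * mean_ref + noise, 0.5 * mean_ref)

where theta_w and T_w are the calcification arc angle and thickness averaged
over +-w frames around f.  The windowed form encodes that expansion at a
frame depends on the calcium burden of a neighbourhood, not of the single
frame — the biomechanical premise behind segmental feature aggregation.
This response is a modeling device for generating learnable data; it is not
fitted to patient outcomes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .expansion import ExpansionResult, compute_expansion
from .pullback import CALCIFICATION, LUMEN, FrameMask, Pullback, PullbackError

PHENOTYPE_MIX = {"nodule": 0.13, "protrusion": 0.23, "sheet": 0.64}

# Relative resistance to dilation per unit calcium burden.  Protruding
# phenotypes (eruptive nodules, protrusions) impede expansion more than
# superficial sheets of the same arc/thickness; protrusions are the worst
# actors (they show the lowest minimum-SEI values).  Phenotype is visible
# to per-frame shape features (depth, leading-edge irregularity) but only
# weakly to whole-lesion volumetric summaries.
PHENOTYPE_BURDEN_FACTOR = {"nodule": 1.1, "protrusion": 1.3, "sheet": 0.85}

# phenotype-specific sampling ranges: arc angle (deg), peak thickness (mm),
# depth of the leading edge below the lumen border (mm; negative protrudes
# into the lumen), leading-edge jitter amplitude (mm)
PHENOTYPE_GEOMETRY = {
    "nodule": {"angle": (40.0, 150.0), "thickness": (0.5, 1.5), "depth": (-0.15, 0.05), "jitter": 0.12},
    "protrusion": {"angle": (60.0, 220.0), "thickness": (0.3, 1.2), "depth": (-0.3, -0.05), "jitter": 0.0},
    "sheet": {"angle": (120.0, 360.0), "thickness": (0.2, 0.9), "depth": (0.0, 0.06), "jitter": 0.0},
}


@dataclasses.dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror a survey-mode acquisition
    (375 frames over 75 mm) at 512 x 512 / 0.02 mm resolution."""

    n_lesions: int = 110
    n_frames: int = 375
    frame_spacing: float = 0.2  # mm
    pixel_spacing: float = 0.02  # mm
    grid_size: int = 512
    margin_frames: int = 25  # reference zone at each end of the pullback
    baseline_radius: tuple[float, float] = (1.4, 2.0)  # mm, at the distal end
    taper_ratio: tuple[float, float] = (1.0, 1.4)  # proximal/distal ref area ratio
    stenosis_depth: tuple[float, float] = (0.25, 0.55)  # fractional radius loss
    stenosis_sigma: tuple[float, float] = (3.0, 8.0)  # mm
    n_deposit_probs: tuple[float, ...] = (0.3, 0.4, 0.3)  # P(1), P(2), P(3)
    deposit_length: tuple[float, float] = (3.0, 15.0)  # mm
    clutter_rate: float = 2.0  # Poisson mean of small scattered deposits
    phenotype_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(PHENOTYPE_MIX)
    )
    # expansion response
    alpha: float = 0.65
    t0: float = 1.0  # mm; thickness above which burden saturates
    e_min: float = 0.4
    response_half_window: int = 15  # frames; +-w neighbourhood of the response
    noise_sd: float = 0.1  # mm^2, additive on the post-stent area
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.phenotype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("phenotype mix must sum to 1")
        for v in (self.frame_spacing, self.pixel_spacing, self.t0):
            if v <= 0:
                raise ValueError("physical parameters must be positive")
        if self.n_frames <= 2 * self.margin_frames:
            raise ValueError("pullback too short for the reference margins")

    @classmethod
    def fast(cls, **overrides) -> "SyntheticConfig":
        """Reduced-scale configuration (shorter pullback, coarser grid) for
        quick experiments and the test suite."""
        params = dict(
            n_frames=120,
            margin_frames=10,
            pixel_spacing=0.08,
            grid_size=128,
            stenosis_sigma=(2.0, 5.0),
        )
        params.update(overrides)
        return cls(**params)

    @property
    def stent_segment(self) -> tuple[int, int]:
        return (self.margin_frames, self.n_frames - self.margin_frames - 1)


@dataclasses.dataclass
class DepositSpec:
    """One calcific deposit: longitudinal placement and polar geometry."""

    center_frame: int
    length_mm: float
    peak_angle_deg: float
    peak_thickness_mm: float
    depth_mm: float
    center_angle_deg: float
    jitter_amp_mm: float = 0.0
    jitter_seed: int = 0


@dataclasses.dataclass
class LesionGeometry:
    """Complete deterministic description of one synthetic lesion.

    ``baseline_radius_mm`` is the healthy lumen radius at the distal end;
    ``taper_ratio`` is the proximal-to-distal reference area ratio of the
    conically tapering vessel (1.0 = cylindrical).
    """

    baseline_radius_mm: float
    stenosis_depth_frac: float
    stenosis_center_frame: int
    stenosis_sigma_mm: float
    deposits: list[DepositSpec]
    phenotype: str | None = None
    taper_ratio: float = 1.0


def _taper(u: np.ndarray) -> np.ndarray:
    """Longitudinal deposit profile: 1 at the center, 0.3 at the ends."""
    return np.where(np.abs(u) <= 1.0, 0.3 + 0.35 * (1.0 + np.cos(np.pi * u)), 0.0)


def sample_geometry(cfg: SyntheticConfig, rng: np.random.Generator) -> LesionGeometry:
    """Draw one lesion's geometry from the configured distributions."""
    lo, hi = cfg.stent_segment
    span = hi - lo + 1
    phenotypes = list(cfg.phenotype_mix)
    phenotype = rng.choice(phenotypes, p=[cfg.phenotype_mix[k] for k in phenotypes])
    geom = PHENOTYPE_GEOMETRY[phenotype]
    n_dep = rng.choice(
        np.arange(1, len(cfg.n_deposit_probs) + 1), p=cfg.n_deposit_probs
    )
    deposits = []
    for _ in range(int(n_dep)):
        length = rng.uniform(*cfg.deposit_length)
        half_frames = length / 2.0 / cfg.frame_spacing
        c_lo = lo + half_frames
        c_hi = hi - half_frames
        center = rng.uniform(c_lo, max(c_lo + 1, c_hi))
        deposits.append(
            DepositSpec(
                center_frame=int(round(center)),
                length_mm=length,
                peak_angle_deg=rng.uniform(*geom["angle"]),
                peak_thickness_mm=rng.uniform(*geom["thickness"]),
                depth_mm=rng.uniform(*geom["depth"]),
                center_angle_deg=rng.uniform(0.0, 360.0),
                jitter_amp_mm=geom["jitter"],
                jitter_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    # scattered spotty calcium: small deposits that are ubiquitous in
    # calcified vessels and contribute little to the local burden but do
    # inflate lesion-wide calcium statistics
    for _ in range(int(rng.poisson(cfg.clutter_rate))):
        length = rng.uniform(0.6, 2.5)
        half_frames = length / 2.0 / cfg.frame_spacing
        deposits.append(
            DepositSpec(
                center_frame=int(round(rng.uniform(lo + half_frames, hi - half_frames))),
                length_mm=length,
                peak_angle_deg=rng.uniform(15.0, 60.0),
                peak_thickness_mm=rng.uniform(0.15, 0.4),
                depth_mm=rng.uniform(0.0, 0.3),
                center_angle_deg=rng.uniform(0.0, 360.0),
                jitter_amp_mm=0.0,
                jitter_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return LesionGeometry(
        baseline_radius_mm=rng.uniform(*cfg.baseline_radius),
        stenosis_depth_frac=rng.uniform(*cfg.stenosis_depth),
        stenosis_center_frame=int(
            rng.uniform(lo + 0.2 * span, lo + 0.8 * span)
        ),
        stenosis_sigma_mm=rng.uniform(*cfg.stenosis_sigma),
        deposits=deposits,
        phenotype=phenotype,
        taper_ratio=rng.uniform(*cfg.taper_ratio),
    )


def lumen_radius_profile(cfg: SyntheticConfig, geom: LesionGeometry) -> np.ndarray:
    """Per-frame lumen radius (mm): a conically tapering baseline (distal to
    proximal) with a Gaussian stenosis dip."""
    f = np.arange(cfg.n_frames, dtype=float)
    z = (f - geom.stenosis_center_frame) * cfg.frame_spacing
    dip = geom.stenosis_depth_frac * np.exp(-0.5 * (z / geom.stenosis_sigma_mm) ** 2)
    taper = 1.0 + (np.sqrt(geom.taper_ratio) - 1.0) * f / (cfg.n_frames - 1)
    return geom.baseline_radius_mm * taper * (1.0 - dip)


def deposit_profiles(
    cfg: SyntheticConfig, geom: LesionGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth per-frame calcification angle (deg, capped at 360) and
    thickness (mm, max over deposits)."""
    theta = np.zeros(cfg.n_frames)
    thick = np.zeros(cfg.n_frames)
    f = np.arange(cfg.n_frames, dtype=float)
    for d in geom.deposits:
        half = d.length_mm / 2.0 / cfg.frame_spacing
        u = (f - d.center_frame) / max(half, 1e-9)
        w = _taper(u)
        theta += d.peak_angle_deg * w
        thick = np.maximum(thick, d.peak_thickness_mm * w)
    return np.minimum(theta, 360.0), thick


def expansion_fraction(cfg: SyntheticConfig, geom: LesionGeometry) -> np.ndarray:
    """The expansion response E(f) over the whole pullback."""
    theta, thick = deposit_profiles(cfg, geom)
    size = 2 * cfg.response_half_window + 1
    theta_w = ndimage.uniform_filter1d(theta, size=size, mode="nearest")
    thick_w = ndimage.uniform_filter1d(thick, size=size, mode="nearest")
    burden = (theta_w / 360.0) * np.minimum(thick_w / cfg.t0, 1.0)
    factor = PHENOTYPE_BURDEN_FACTOR.get(geom.phenotype, 1.0)
    return np.clip(1.0 - cfg.alpha * factor * burden, cfg.e_min, 1.0)


def _angdiff(a: np.ndarray, b: float) -> np.ndarray:
    return (a - b + 180.0) % 360.0 - 180.0


def render_lesion(
    cfg: SyntheticConfig,
    geom: LesionGeometry,
    lesion_id: str = "L000",
    noise_rng: np.random.Generator | None = None,
) -> Pullback:
    """Render a geometry into a labeled pullback with ground-truth
    post-stent areas attached."""
    n, g = cfg.n_frames, cfg.grid_size
    px, fs = cfg.pixel_spacing, cfg.frame_spacing
    half_fov = g * px / 2.0
    radius = lumen_radius_profile(cfg, geom)
    max_outer = max(
        (
            radius.max() + max(d.depth_mm, 0.0) + d.peak_thickness_mm + d.jitter_amp_mm
            for d in geom.deposits
        ),
        default=radius.max(),
    )
    if max_outer >= half_fov - 2 * px:
        raise PullbackError(
            f"lesion geometry (outer radius {max_outer:.2f} mm) does not fit "
            f"the {2 * half_fov:.2f} mm field of view"
        )

    c = (g - 1) / 2.0
    yy, xx = np.mgrid[0:g, 0:g]
    R = np.hypot(yy - c, xx - c) * px
    PHI = np.degrees(np.arctan2(yy - c, xx - c)) % 360.0

    jitter_lookup = {}
    for d in geom.deposits:
        if d.jitter_amp_mm > 0:
            jrng = np.random.default_rng(d.jitter_seed)
            rough = ndimage.gaussian_filter1d(
                jrng.normal(0.0, 1.0, 360), sigma=6.0, mode="wrap"
            )
            rough *= d.jitter_amp_mm / max(np.abs(rough).max(), 1e-9)
            jitter_lookup[id(d)] = rough

    frames = []
    for f in range(n):
        labels = np.zeros((g, g), dtype=np.uint8)
        lum = R <= radius[f]
        labels[lum] = LUMEN
        for d in geom.deposits:
            half = d.length_mm / 2.0 / fs
            u = (f - d.center_frame) / max(half, 1e-9)
            if abs(u) > 1.0:
                continue
            w = float(_taper(np.array([u]))[0])
            theta_f = d.peak_angle_deg * w
            thick_f = d.peak_thickness_mm * w
            if theta_f <= 0 or thick_f <= 0:
                continue
            inner = radius[f] + d.depth_mm
            if id(d) in jitter_lookup:
                inner = inner + np.interp(
                    PHI, np.arange(360), jitter_lookup[id(d)], period=360
                )
            sector = np.abs(_angdiff(PHI, d.center_angle_deg)) <= theta_f / 2.0
            calc = sector & (R >= inner) & (R <= inner + thick_f)
            labels[calc] = CALCIFICATION
        frames.append(FrameMask(labels, px, f))

    # references: largest lumen area within each margin zone
    areas = np.array([f.lumen_mask.sum() * px * px for f in frames])
    lo, hi = cfg.stent_segment
    ref_dist = float(areas[:lo].max())
    ref_prox = float(areas[hi + 1 :].max())

    # the stent restores the local healthy caliber (dip-free tapering
    # profile) except where calcification burden resists dilation
    f = np.arange(cfg.n_frames, dtype=float)
    taper = 1.0 + (np.sqrt(geom.taper_ratio) - 1.0) * f / (cfg.n_frames - 1)
    healthy_area = np.pi * (geom.baseline_radius_mm * taper) ** 2
    E = expansion_fraction(cfg, geom)
    if noise_rng is None:
        noise_rng = np.random.default_rng(0)
    noise = noise_rng.normal(0.0, cfg.noise_sd, size=cfg.n_frames)
    post = np.maximum(E * healthy_area + noise, 0.5 * healthy_area)[lo : hi + 1]

    return Pullback(
        frames=frames,
        frame_spacing=fs,
        lesion_id=lesion_id,
        ref_proximal_area=ref_prox,
        ref_distal_area=ref_dist,
        stent_segment=(lo, hi),
        post_stent_area=post,
        phenotype=geom.phenotype,
    )


def generate_lesion(
    cfg: SyntheticConfig, seed: int, lesion_id: str = "L000"
) -> Pullback:
    """Sample a geometry and render it; fully determined by (cfg, seed)."""
    rng = np.random.default_rng(seed)
    geom = sample_geometry(cfg, rng)
    return render_lesion(cfg, geom, lesion_id, noise_rng=rng)


def truth_msei(p: Pullback) -> ExpansionResult:
    """Actual expansion result from a pullback's ground-truth post-stent
    areas (same code path as predicted curves)."""
    if p.post_stent_area is None:
        raise PullbackError(f"lesion {p.lesion_id} carries no post-stent areas")
    return compute_expansion(
        p.post_stent_area,
        p.ref_proximal_area,
        p.ref_distal_area,
        frames=p.stent_frames,
        source="actual",
    )


def generate_cohort(cfg: SyntheticConfig, seed: int | None = None):
    """Generate ``cfg.n_lesions`` pullbacks plus a ground-truth table
    (lesion_id, phenotype, mSEI, expansion class)."""
    import pandas as pd

    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    lesion_seeds = ss.generate_state(max(cfg.n_lesions, 1)) % (2**31 - 1)
    cohort = []
    records = []
    for i in range(cfg.n_lesions):
        lesion_id = f"L{i:03d}"
        p = generate_lesion(cfg, int(lesion_seeds[i]), lesion_id)
        res = truth_msei(p)
        cohort.append(p)
        records.append(
            {
                "lesion_id": lesion_id,
                "phenotype": p.phenotype,
                "msei": res.msei,
                "msei_frame": res.msei_frame,
                "label": res.label,
                "seed": int(lesion_seeds[i]),
            }
        )
    truth = pd.DataFrame.from_records(records, columns=[
        "lesion_id", "phenotype", "msei", "msei_frame", "label", "seed"
    ])
    return cohort, truth
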