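"""Shared fixtures: small rendered lesions for unit tests and one
session-scoped synthetic cohort (with its method comparison) for the
end-to-end checks."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

from stentexpand.pipelines import compare_methods_mean, frame_tables
from stentexpand.synth import (
    DepositSpec,
    LesionGeometry,
    SyntheticConfig,
    generate_cohort,
    render_lesion,
)

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


def make_sector_lesion(
    peak_angle=90.0,
    peak_thickness=0.5,
    depth=0.1,
    center_angle=45.0,
    pixel_spacing=0.02,
    grid_size=512,
    n_frames=21,
    length_mm=60.0,
    radius=1.6,
    phenotype=None,
    **cfg_kwargs,
):
    """One lesion with a single, longitudinally uniform annular-sector
    deposit of known geometry (the analytic oracle workhorse)."""
    cfg = SyntheticConfig(
        n_frames=n_frames,
        margin_frames=max(2, n_frames // 8),
        grid_size=grid_size,
        pixel_spacing=pixel_spacing,
        clutter_rate=0.0,
        **cfg_kwargs,
    )
    mid = n_frames // 2
    geom = LesionGeometry(
        baseline_radius_mm=radius,
        stenosis_depth_frac=0.0,
        stenosis_center_frame=mid,
        stenosis_sigma_mm=4.0,
        deposits=[
            DepositSpec(
                center_frame=mid,
                length_mm=length_mm,  # >> pullback, so the taper is ~flat
                peak_angle_deg=peak_angle,
                peak_thickness_mm=peak_thickness,
                depth_mm=depth,
                center_angle_deg=center_angle,
            )
        ],
        phenotype=phenotype,
    )
    return cfg, geom, render_lesion(cfg, geom, "sector")


@pytest.fixture(scope="session")
def small_lesion():
    """A coarse-resolution lesion with one deposit, for plumbing tests."""
    cfg = SyntheticConfig.fast(n_frames=60, margin_frames=8, grid_size=96,
                               pixel_spacing=0.1)
    geom = LesionGeometry(
        baseline_radius_mm=1.5,
        stenosis_depth_frac=0.3,
        stenosis_center_frame=30,
        stenosis_sigma_mm=3.0,
        deposits=[
            DepositSpec(center_frame=30, length_mm=5.0, peak_angle_deg=120.0,
                        peak_thickness_mm=0.8, depth_mm=0.05, center_angle_deg=200.0)
        ],
        phenotype="sheet",
        taper_ratio=1.2,
    )
    return render_lesion(cfg, geom, "small", noise_rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def cohort_and_truth():
    """The seeded 110-lesion reduced-resolution study cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(SyntheticConfig.fast(), seed=0)


@pytest.fixture(scope="session")
def cohort_tables(cohort_and_truth):
    cohort, _ = cohort_and_truth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return frame_tables(cohort)


@pytest.fixture(scope="session")
def method_comparison(cohort_and_truth, cohort_tables):
    """Split-averaged AUC table of all methods on the session cohort."""
    cohort, truth = cohort_and_truth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compare_methods_mean(
            cohort, truth, split_seeds=(0, 1, 2), tables=cohort_tables
        )
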