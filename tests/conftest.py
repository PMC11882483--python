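"""Shared fixtures: small deterministic phantoms and movies.

Heavy end-to-end artifacts are session-scoped so the acceptance-style tests
and the per-module tests share one computation.
"""
from __future__ import annotations

import numpy as np
import pytest

import ulmtools as u


def gaussian_spot(shape, cx, cy, sigma=1.5, peak=1.0):
    """Render one isotropic Gaussian at sub-pixel centre (cx, cy)."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return peak * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma ** 2))


@pytest.fixture(scope="session")
def straight_vessel_phantom():
    """One straight horizontal vessel, radius 20 um, mean speed 5 mm/s."""
    pts = np.column_stack([np.linspace(100.0, 1100.0, 101),
                           np.full(101, 640.0)])
    seg = u.phantom.VesselSegment(points_um=pts, radius_um=20.0,
                                  mean_speed_mm_s=5.0, region=0)
    label = np.zeros((128, 128), dtype=np.int64)
    return u.VascularPhantom(segments=[seg], region_label_map=label,
                             region_names=["core"], pixel_size_um=10.0)


@pytest.fixture(scope="session")
def default_phantom():
    return u.generate_phantom(seed=7)


@pytest.fixture(scope="session")
def fixture_movie():
    """Seeded dilute-tracer movie with rank-1 clutter at 100x bubble peak.

    200 frames of 128 x 128 in the high-dilution regime standard ULM
    protocols use (a couple of dozen bubbles in view, all moving faster
    than the clutter band).  Returns everything needed to compare against
    ground truth: the phantom, truth trajectories, the noiseless bubble-only
    rendering and the cluttered movie.
    """
    ph = u.generate_phantom(regions=u.two_region_config(), seed=11)
    traj = u.simulate_bubble_flow(ph, bubbles_per_frame=0.1, n_frames=200,
                                  seed=12, min_speed_mm_s=1.0)
    clean = u.render_movie(traj, psf_sigma_um=10.0, clutter_rank=0,
                           noise_sigma=0.0, seed=13)
    cluttered = u.render_movie(traj, psf_sigma_um=10.0, clutter_rank=1,
                               clutter_amplitude=100.0, noise_sigma=0.0,
                               seed=13)
    return {"phantom": ph, "trajectories": traj, "clean": clean,
            "cluttered": cluttered}


@pytest.fixture(scope="session")
def default_end_to_end():
    """Full-default end-to-end run shared across recovery-style tests."""
    from ulmtools.recovery import run_end_to_end

    return run_end_to_end(seed=21)
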