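"""Shared phantom fixtures (session-scoped; voxelization is the slow part)."""

import numpy as np
import pytest

import gaparea3d as g3


def make_flat_spec(d=3.0, dz=0.0, spacing=0.5, noise_sd=0.0, seed=0):
    """Two-fragment plate phantom: 20x20x10 mm, one vertical cut at x=10,
    second fragment translated by (d, 0, dz)."""
    return g3.PhantomSpec(
        plate_dims=(20.0, 20.0, 10.0),
        cuts=[g3.CutPlane((10.0, 0.0, 0.0), (1.0, 0.0, 0.0))],
        displacements=[g3.RigidDisplacement(),
                       g3.RigidDisplacement(translation=(d, 0.0, dz))],
        spacing=spacing, noise_sd=noise_sd, seed=seed)


def make_cross_spec(spacing=0.5):
    """Four-quadrant plate with perpendicular cuts; the +x half is shifted
    4 mm, opening two 10 mm x 4 mm gaps (analytic areas {40, 40, 0, 0})."""
    return g3.PhantomSpec(
        plate_dims=(20.0, 20.0, 10.0),
        cuts=[g3.CutPlane((10.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
              g3.CutPlane((0.0, 10.0, 0.0), (0.0, 1.0, 0.0))],
        displacements=[g3.RigidDisplacement(), g3.RigidDisplacement(),
                       g3.RigidDisplacement(translation=(4.0, 0.0, 0.0)),
                       g3.RigidDisplacement(translation=(4.0, 0.0, 0.0))],
        spacing=spacing)


def marked_patches(mask, min_area=5.0):
    proxy = g3.ArticularProxy(kind="roi_mask", roi=g3.top_surface_roi(mask))
    return g3.mark_all(g3.mesh_all_fragments(mask), proxy, min_area=min_area)


@pytest.fixture(scope="session")
def flat_phantom():
    spec = make_flat_spec(d=3.0)
    vol, mask, truth = g3.make_fracture_phantom(spec)
    return spec, vol, mask, truth


@pytest.fixture(scope="session")
def flat_patches(flat_phantom):
    _, _, mask, _ = flat_phantom
    return marked_patches(mask)


@pytest.fixture(scope="session")
def cross_phantom():
    spec = make_cross_spec()
    vol, mask, truth = g3.make_fracture_phantom(spec)
    return spec, vol, mask, truth


@pytest.fixture(scope="session")
def cross_patches(cross_phantom):
    _, _, mask, _ = cross_phantom
    return marked_patches(mask)


def random_polyline(rng, n_points, scale=10.0):
    pts = rng.uniform(0, scale, size=(n_points, 3))
    # ensure consecutive points distinct
    for i in range(1, n_points):
        while np.linalg.norm(pts[i] - pts[i - 1]) < 1e-6:
            pts[i] = rng.uniform(0, scale, size=3)
    return pts
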