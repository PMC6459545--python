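"""Shared fixtures: small phantoms generated once per session."""

import numpy as np
import pytest

import fibramorph as fm


@pytest.fixture(scope="session")
def small_aligned_phantom():
    """Aligned phantom at desk scale (128³, ~10 fibers, θ=27°, φ=15°)."""
    cfg = fm.aligned_config(volume_shape=(128, 128, 128),
                            n_fibers_range=(8, 12), rng_seed=3)
    return fm.simulate_fibers(cfg)


@pytest.fixture(scope="session")
def small_disordered_phantom():
    cfg = fm.disordered_config(volume_shape=(96, 96, 96),
                               n_fibers_range=(6, 10),
                               diameter_range_vox=(3.0, 9.0), rng_seed=9)
    return fm.simulate_fibers(cfg)


@pytest.fixture(scope="session")
def small_aligned_skeleton(small_aligned_phantom):
    return fm.skeletonize3d(small_aligned_phantom.volume)


@pytest.fixture(scope="session")
def small_aligned_field(small_aligned_phantom, small_aligned_skeleton):
    return fm.estimate_tensor_orientation(
        small_aligned_phantom.volume, small_aligned_skeleton, window_vox=32)


def axis_orientation_field(axis_coords, theta_deg, phi_deg, window=32):
    """Orientation field with constant angles on given (z,y,x) voxels."""
    n = len(axis_coords)
    return fm.OrientationField(np.asarray(axis_coords, dtype=np.int64),
                               np.full(n, float(theta_deg)),
                               np.full(n, float(phi_deg)), window)
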