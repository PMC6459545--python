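"""Phantom generator: geometry, ground truth, sampling, contamination."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import kstest

import fibramorph as fm
from fibramorph.orient import angles_to_vector


def brute_force_cylinder_count(shape, center_xyz, theta, phi, diameter, length):
    """Independent rasterization oracle: test every voxel center's distance
    to the parametric axis segment (no bounding box, no broadcasting tricks
    shared with the implementation)."""
    d = angles_to_vector(theta, phi)
    a = np.asarray(center_xyz, float) - 0.5 * length * d
    count = 0
    zz, yy, xx = np.indices(shape)
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1).astype(float)
    rel = pts - a
    t = np.clip(rel @ d, 0.0, length)
    closest = a + t[:, None] * d[None, :]
    dist = np.linalg.norm(pts - closest, axis=1)
    return int((dist <= diameter / 2.0).sum())


def test_aligned_config_fixes_angles(small_aligned_phantom):
    assert len(small_aligned_phantom.fibers) >= 8
    for f in small_aligned_phantom.fibers:
        assert f.theta_deg == 27.0 and f.phi_deg == 15.0
        assert np.linalg.norm(f.direction) == pytest.approx(1.0, abs=1e-9)


def test_zero_fiber_stop_rule_gives_empty_phantom():
    cfg = fm.SimulationConfig(volume_shape=(32, 32, 32), stop_rule="max_fibers",
                              stop_value=0)
    with pytest.warns(UserWarning, match="empty"):
        ph = fm.simulate_fibers(cfg)
    assert ph.fibers == [] and not ph.volume.any() and not ph.labels.any()


def test_single_fiber_voxel_count_matches_point_to_segment_oracle():
    shape = (120, 120, 120)
    vol, _ = fm.make_cylinder(shape, (59.5, 59.5, 59.5), 0.0, 0.0, 9.0, 100.0)
    expected = brute_force_cylinder_count(shape, (59.5, 59.5, 59.5), 0.0, 0.0,
                                          9.0, 100.0)
    assert vol.sum() == expected
    assert abs(vol.sum() - np.pi * 4.5**2 * 100) / (np.pi * 4.5**2 * 100) < 0.10


def test_phantom_reproducible_and_label_volume_consistent(small_aligned_phantom):
    ph2 = fm.simulate_fibers(small_aligned_phantom.config)
    assert np.array_equal(ph2.volume, small_aligned_phantom.volume)
    assert np.array_equal(ph2.labels, small_aligned_phantom.labels)
    assert [f.label for f in ph2.fibers] == [f.label for f in small_aligned_phantom.fibers]
    # labels and binary foreground coincide; every label has a record
    assert np.array_equal(small_aligned_phantom.labels > 0,
                          small_aligned_phantom.volume > 0)
    present = set(np.unique(small_aligned_phantom.labels)) - {0}
    assert present == {f.label for f in small_aligned_phantom.fibers}


def test_non_intersection_gap_enforced():
    cfg = fm.disordered_config(volume_shape=(64, 64, 64), n_fibers_range=(5, 5),
                               diameter_range_vox=(3.0, 6.0),
                               gap_range_vox=(3.0, 5.0), rng_seed=21)
    ph = fm.simulate_fibers(cfg)
    assert len(ph.fibers) >= 2
    clouds = [np.argwhere(ph.labels == f.label) for f in ph.fibers]
    for i in range(len(clouds)):
        for j in range(i + 1, len(clouds)):
            assert cdist(clouds[i], clouds[j]).min() >= cfg.gap_range_vox[0]


def test_ground_truth_direction_matches_voxel_cloud_principal_axis():
    cfg = fm.disordered_config(volume_shape=(96, 96, 96), n_fibers_range=(6, 6),
                               diameter_range_vox=(3.0, 4.0),
                               length_fraction_range=(0.5, 0.7), rng_seed=4)
    ph = fm.simulate_fibers(cfg)
    checked = 0
    for f in ph.fibers:
        if f.length_vox < 10 * f.diameter_vox:
            continue
        cloud = np.argwhere(ph.labels == f.label).astype(float)
        cloud -= cloud.mean(axis=0)
        _, _, vt = np.linalg.svd(cloud, full_matrices=False)
        axis_xyz = vt[0][::-1]
        cosang = abs(axis_xyz @ np.asarray(f.direction))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 3.0
        checked += 1
    assert checked >= 3


def test_realized_parameters_within_ranges_and_uniform():
    cfg = fm.disordered_config(volume_shape=(96, 96, 96),
                               diameter_range_vox=(3.0, 10.0),
                               length_fraction_range=(0.2, 0.5),
                               allow_intersections=True,
                               stop_value=250, rng_seed=17)
    ph = fm.simulate_fibers(cfg)
    assert len(ph.fibers) >= 200
    diam = np.array([f.diameter_vox for f in ph.fibers])
    theta = np.array([f.theta_deg for f in ph.fibers])
    phi = np.array([f.phi_deg for f in ph.fibers])
    assert diam.min() >= 3.0 and diam.max() <= 10.0
    assert theta.min() >= -89.0 and theta.max() <= 90.0
    assert phi.min() >= 0.0 and phi.max() <= 90.0
    for vals, lo, hi in [(diam, 3.0, 10.0), (theta, -89.0, 90.0), (phi, 0.0, 90.0)]:
        p = kstest(vals, "uniform", args=(lo, hi - lo)).pvalue
        assert p > 0.01


def test_degenerate_diameter_yields_empty_phantom_not_exception():
    cfg = fm.SimulationConfig(volume_shape=(32, 32, 32),
                              diameter_range_vox=(100.0, 100.0),
                              max_failed_attempts=20)
    with pytest.warns(UserWarning, match="empty"):
        ph = fm.simulate_fibers(cfg)
    assert ph.fibers == []


def test_invalid_ranges_raise():
    with pytest.raises(ValueError):
        fm.SimulationConfig(azimuth_range_deg=(50, -50))
    with pytest.raises(ValueError):
        fm.SimulationConfig(elevation_range_deg=(0, 120))
    with pytest.raises(ValueError):
        fm.SimulationConfig(diameter_range_vox=(0.5, 3.0))
    with pytest.raises(ValueError):
        fm.SimulationConfig(stop_rule="until_tired")


def test_contaminate_identity_and_noise_level():
    vol = np.zeros((64, 64, 64), dtype=np.uint8)
    out = fm.contaminate(vol, 0.0, 0.0, rng_seed=1)
    assert np.array_equal(out, vol)
    noisy = fm.contaminate(vol, 1.0, 0.0, rng_seed=1)
    assert 0.98 <= noisy.std() <= 1.02  # CLT bound for 64³ iid normals
    assert np.array_equal(noisy, fm.contaminate(vol, 1.0, 0.0, rng_seed=1))
    with pytest.raises(ValueError):
        fm.contaminate(vol, -0.5, 0.0)


def test_contaminated_phantom_still_thresholdable(small_aligned_phantom):
    noisy = fm.contaminate(small_aligned_phantom.volume, 1.5, 1.0, rng_seed=2)
    binary = fm.binarize(noisy, method="otsu")
    truth = small_aligned_phantom.volume.astype(bool)
    # foreground recovery: most true fiber voxels survive segmentation
    assert (binary & truth).sum() / truth.sum() > 0.5
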