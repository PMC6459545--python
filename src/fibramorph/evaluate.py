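"""Validation protocol against phantom ground truth.

Quantifies the structure-tensor estimator on generated phantoms: per-voxel
angular errors (azimuth with 180° wraparound, elevation absolute), the
window-size sweep used to pick the operating window, the noise-robustness
sweep (contaminate → Otsu → skeletonize → orient), and the angular-range
scan that maps error-prone orientation zones with single-fiber phantoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .orient import (OrientationField, _vectors_to_angles_batch,
                     angles_to_vector, estimate_tensor_orientation,
                     tensor_orientation_multi)
from .preprocess import binarize, skeletonize3d
from .simulate import Phantom, contaminate, make_cylinder

__all__ = [
    "ErrorSummary",
    "azimuth_distance_deg",
    "angular_error",
    "window_sweep",
    "noise_sweep",
    "angular_range_scan",
]


@dataclass
class ErrorSummary:
    """Mean ± std of per-voxel absolute angular errors (degrees)."""

    mean_azimuth_err_deg: float
    std_azimuth_err_deg: float
    mean_elevation_err_deg: float
    std_elevation_err_deg: float
    n_points: int


def azimuth_distance_deg(a, b):
    """Wraparound-aware azimuth distance: min(|Δ|, 180 − |Δ|)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def _ground_truth_per_voxel(coords: np.ndarray, phantom: Phantom):
    """(θ, φ) of the fiber each voxel belongs to; voxels off the label map
    (skeletonization drift, segmentation noise) inherit the nearest labeled
    voxel's fiber."""
    labels = phantom.labels
    lab = labels[coords[:, 0], coords[:, 1], coords[:, 2]].astype(np.int64)
    missing = lab == 0
    if missing.any():
        fg = np.argwhere(labels > 0)
        if len(fg) == 0:
            raise ValueError("phantom has no labeled voxels")
        tree = cKDTree(fg)
        _, idx = tree.query(coords[missing], k=1)
        nearest = fg[idx]
        lab[missing] = labels[nearest[:, 0], nearest[:, 1], nearest[:, 2]]
    max_label = max(f.label for f in phantom.fibers)
    theta_of = np.full(max_label + 1, np.nan)
    phi_of = np.full(max_label + 1, np.nan)
    for f in phantom.fibers:
        theta_of[f.label] = f.theta_deg
        phi_of[f.label] = f.phi_deg
    return theta_of[lab], phi_of[lab]


def angular_error(estimated: OrientationField, phantom: Phantom) -> ErrorSummary:
    """Per-voxel absolute angular error of an orientation field against the
    phantom's ground truth, summarized as mean ± std."""
    if len(estimated) == 0:
        raise ValueError("estimated orientation field is empty")
    coords = np.asarray(estimated.coords, dtype=np.int64)
    theta_true, phi_true = _ground_truth_per_voxel(coords, phantom)
    az_err = azimuth_distance_deg(estimated.theta_deg, theta_true)
    el_err = np.abs(np.asarray(estimated.phi_deg, dtype=float) - phi_true)
    return ErrorSummary(
        mean_azimuth_err_deg=float(az_err.mean()),
        std_azimuth_err_deg=float(az_err.std()),
        mean_elevation_err_deg=float(el_err.mean()),
        std_elevation_err_deg=float(el_err.std()),
        n_points=len(az_err),
    )


def _field_from_multi(coords, dirs, valid, window, sigma) -> OrientationField:
    theta, phi = _vectors_to_angles_batch(dirs[valid])
    return OrientationField(coords[valid], theta, phi, window, sigma,
                            n_skipped=int((~valid).sum()))


def window_sweep(phantom: Phantom, windows, gradient_sigma_vox: float = 1.0) -> pd.DataFrame:
    """Angular error of the tensor estimator for each window size on the
    clean phantom.  Gradients are shared across windows, so the sweep costs
    little more than a single estimation."""
    windows = sorted(int(w) for w in windows)
    usable = []
    for w in windows:
        if w > min(phantom.volume.shape):
            warnings.warn(f"window {w} exceeds the smallest volume side; skipped",
                          stacklevel=2)
        else:
            usable.append(w)
    skel = skeletonize3d(phantom.volume)
    coords = np.argwhere(skel.skeleton)
    multi = tensor_orientation_multi(phantom.volume, coords, usable,
                                     gradient_sigma_vox)
    rows = []
    for w in usable:
        dirs, valid = multi[w]
        est = _field_from_multi(coords, dirs, valid, w, gradient_sigma_vox)
        s = angular_error(est, phantom)
        rows.append({"window": w, **s.__dict__})
    return pd.DataFrame(rows)


def noise_sweep(phantom: Phantom, sigmas, sigma_smooth: float = 1.0,
                rng_seed: int = 0, window_vox: int = 32,
                gradient_sigma_vox: float = 1.0) -> pd.DataFrame:
    """Angular error under increasing additive Gaussian noise.

    For each σ_agn: contaminate → Otsu binarize → skeletonize → tensor
    orientation (on the contaminated grayscale volume) → error vs ground
    truth.  A σ whose segmentation fails yields a flagged row, not an error.
    """
    rows = []
    for i, sigma in enumerate(sorted(float(s) for s in sigmas)):
        vol = contaminate(phantom.volume, sigma, sigma_smooth,
                          rng_seed=rng_seed + i)
        row = {"sigma_agn": sigma, "sigma_smooth": sigma_smooth, "failed": False}
        try:
            binary = binarize(vol, method="otsu")
            if not binary.any():
                raise ValueError("empty foreground after thresholding")
            skel = skeletonize3d(binary)
            est = estimate_tensor_orientation(vol, skel, window_vox,
                                              gradient_sigma_vox)
            s = angular_error(est, phantom)
            row.update(s.__dict__)
        except ValueError as exc:
            row.update({"failed": True, "reason": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)


def angular_range_scan(step_deg: float = 5.0, window_vox: int = 32,
                       volume_side: int = 64, diameter_vox: float = 9.0,
                       gradient_sigma_vox: float = 1.0) -> pd.DataFrame:
    """Error surface over the (θ, φ) grid from single-fiber phantoms.

    For each grid orientation a clean cylinder (length 0.75 × side) is
    rasterized through the volume centre and the tensor estimator is
    evaluated on interior axis voxels (a window/2 margin from the ends, so
    the scan isolates the estimator from end effects and thinning).  Besides
    the azimuth/elevation errors the geodesic axis error (angle between
    estimated and true axis) is reported — azimuth is ill-conditioned near
    φ = 90°, the axis error never is.
    """
    if step_deg <= 0 or (180.0 % step_deg) or (90.0 % step_deg):
        raise ValueError("step_deg must divide both 180 and 90")
    thetas = np.arange(-90.0 + step_deg, 90.0 + 1e-9, step_deg)
    phis = np.arange(0.0, 90.0 + 1e-9, step_deg)
    shape = (volume_side,) * 3
    center = ((volume_side - 1) / 2.0,) * 3
    length = 0.75 * volume_side
    margin = max(window_vox // 2, int(np.ceil(diameter_vox)))
    rows = []
    for phi in phis:
        for theta in thetas:
            vol, axis = make_cylinder(shape, center, theta, phi,
                                      diameter_vox, length)
            d_true = angles_to_vector(theta, phi)
            c = np.asarray(center)[::-1]
            t_along = (axis - c) @ d_true[::-1]
            interior = axis[np.abs(t_along) <= (length / 2.0 - margin)]
            if len(interior) == 0:
                interior = axis
            dirs, valid = tensor_orientation_multi(
                vol, interior, [window_vox], gradient_sigma_vox)[window_vox]
            if not valid.any():
                rows.append({"theta_deg": theta, "phi_deg": phi,
                             "mean_azimuth_err_deg": np.nan,
                             "max_azimuth_err_deg": np.nan,
                             "mean_elevation_err_deg": np.nan,
                             "max_elevation_err_deg": np.nan,
                             "max_axis_err_deg": np.nan, "n_points": 0})
                continue
            th_est, ph_est = _vectors_to_angles_batch(dirs[valid])
            az = azimuth_distance_deg(th_est, theta)
            el = np.abs(ph_est - phi)
            cosang = np.clip(np.abs(dirs[valid] @ d_true), 0.0, 1.0)
            axis_err = np.degrees(np.arccos(cosang))
            rows.append({"theta_deg": theta, "phi_deg": phi,
                         "mean_azimuth_err_deg": float(az.mean()),
                         "max_azimuth_err_deg": float(az.max()),
                         "mean_elevation_err_deg": float(el.mean()),
                         "max_elevation_err_deg": float(el.max()),
                         "max_axis_err_deg": float(axis_err.max()),
                         "n_points": int(valid.sum())})
    return pd.DataFrame(rows)
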