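"""Fiber orientation estimation.

Two estimators are provided:

* a per-voxel 3D estimator based on the second-order structure tensor,
  evaluated at skeleton (medial-axis) voxels — the fiber axis is the
  eigenvector of the smallest eigenvalue of the locally averaged tensor of
  gradient outer products;
* a global 2D estimator based on a PCA of the Fourier power spectrum — the
  dominant image orientation is perpendicular to the spectrum's major axis.

Angle convention (shared by the whole package)
----------------------------------------------
A fiber axis is described by azimuth θ ∈ (−90°, 90°] and elevation
φ ∈ [0°, 90°], with the unit direction (as an (x, y, z) vector)

    d(θ, φ) = (cos φ · cos θ,  cos φ · sin θ,  sin φ)

θ is the in-XY-plane angle, φ the tilt out of the XY plane (φ = 90° means
the fiber runs along Z). Fibers are headless axes: ``v`` and ``−v`` are the
same orientation, and because the elevation is unsigned (``asin(|z|)``) a
(θ, φ) pair also identifies an axis together with its mirror image through
the XY plane. Volumes are indexed ``(z, y, x)``; directions are kept as
(x, y, z) vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "OrientationField",
    "angles_to_vector",
    "vector_to_angles",
    "fold_azimuth_deg",
    "estimate_tensor_orientation",
    "tensor_orientation_multi",
    "estimate_fourier_orientation",
]


def angles_to_vector(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit (x, y, z) direction for azimuth/elevation in degrees."""
    t = np.deg2rad(theta_deg)
    p = np.deg2rad(phi_deg)
    return np.array([np.cos(p) * np.cos(t), np.cos(p) * np.sin(t), np.sin(p)])


def fold_azimuth_deg(theta_deg):
    """Fold an angle in degrees into the canonical azimuth range (−90, 90]."""
    t = np.asarray(theta_deg, dtype=float) % 180.0
    t = np.where(t > 90.0, t - 180.0, t)
    return t if t.ndim else float(t)


def vector_to_angles(direction) -> tuple[float, float]:
    """Canonical (azimuth, elevation) in degrees of a 3-vector.

    The sign is canonicalized first (flip so that x > 0; if x == 0 flip so
    that y > 0; if both vanish θ := 0), then θ = atan2(y, x) and
    φ = asin(|z| / ‖v‖).  Inverse of :func:`angles_to_vector` on the
    quarter-sphere x ≥ 0, z ≥ 0.
    """
    v = np.asarray(direction, dtype=float)
    if v.shape != (3,):
        raise ValueError("direction must be a 3-vector")
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise ValueError("cannot derive angles from a zero or non-finite vector")
    x, y, z = v / n
    if x < 0 or (x == 0 and y < 0):
        x, y, z = -x, -y, -z
    if x == 0 and y == 0:
        theta = 0.0
    else:
        theta = np.degrees(np.arctan2(y, x))
    phi = np.degrees(np.arcsin(min(abs(z), 1.0)))
    return float(theta), float(phi)


def _vectors_to_angles_batch(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized canonicalization; ``dirs`` is (N, 3) in (x, y, z) order."""
    v = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    flip = (v[:, 0] < 0) | ((v[:, 0] == 0) & (v[:, 1] < 0))
    v[flip] *= -1.0
    theta = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    theta[(v[:, 0] == 0) & (v[:, 1] == 0)] = 0.0
    phi = np.degrees(np.arcsin(np.clip(np.abs(v[:, 2]), 0.0, 1.0)))
    return theta, phi


@dataclass
class OrientationField:
    """Sparse per-voxel orientation map on skeleton voxels.

    ``coords`` holds (z, y, x) voxel indices, row-aligned with the angle
    arrays. ``n_skipped`` counts skeleton voxels where no orientation could
    be assigned (vanishing or isotropic structure tensor).
    """

    coords: np.ndarray
    theta_deg: np.ndarray
    phi_deg: np.ndarray
    window_vox: int
    gradient_sigma_vox: float = 1.0
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.coords)

    def to_dataframe(self) -> pd.DataFrame:
        """Export as a table with 0-based x, y, z voxel coordinates."""
        return pd.DataFrame(
            {
                "x": self.coords[:, 2],
                "y": self.coords[:, 1],
                "z": self.coords[:, 0],
                "theta_deg": self.theta_deg,
                "phi_deg": self.phi_deg,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, window_vox: int = 0,
                       gradient_sigma_vox: float = 1.0) -> "OrientationField":
        coords = np.column_stack([df["z"], df["y"], df["x"]]).astype(np.int64)
        return cls(coords, df["theta_deg"].to_numpy(dtype=float),
                   df["phi_deg"].to_numpy(dtype=float), window_vox,
                   gradient_sigma_vox)


def _padded_sat(a: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero border so box queries need no branches."""
    s = np.zeros(tuple(n + 1 for n in a.shape), dtype=np.float64)
    s[1:, 1:, 1:] = np.cumsum(a, axis=0, dtype=np.float64)
    np.cumsum(s[1:, 1:, 1:], axis=1, out=s[1:, 1:, 1:])
    np.cumsum(s[1:, 1:, 1:], axis=2, out=s[1:, 1:, 1:])
    return s


def _box_sums(sat: np.ndarray, coords: np.ndarray, window: int,
              shape: tuple[int, int, int]) -> np.ndarray:
    """Sum of the underlying array over the window centred on each coord.

    Windows are clipped at the volume border (the sum then covers only the
    valid part).
    """
    lo = coords - window // 2
    hi = lo + window
    lo = np.clip(lo, 0, np.asarray(shape))
    hi = np.clip(hi, 0, np.asarray(shape))
    z0, y0, x0 = lo[:, 0], lo[:, 1], lo[:, 2]
    z1, y1, x1 = hi[:, 0], hi[:, 1], hi[:, 2]
    return (sat[z1, y1, x1] - sat[z0, y1, x1] - sat[z1, y0, x1]
            - sat[z1, y1, x0] + sat[z0, y0, x1] + sat[z0, y1, x0]
            + sat[z1, y0, x0] - sat[z0, y0, x0])


_TENSOR_PAIRS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def tensor_orientation_multi(
    volume: np.ndarray,
    coords: np.ndarray,
    windows,
    gradient_sigma_vox: float = 1.0,
):
    """Structure-tensor fiber directions at given voxels for several windows.

    Gradients and the per-component summed-area tables are computed once and
    queried for every window size, which makes window sweeps cheap.

    Returns ``{window: (directions, valid)}`` where ``directions`` is (N, 3)
    in (x, y, z) order (rows with ``valid == False`` are undefined: vanishing
    or isotropic tensor).
    """
    vol = np.ascontiguousarray(volume, dtype=np.float32)
    coords = np.asarray(coords, dtype=np.int64)
    windows = [int(w) for w in windows]
    if any(w < 4 for w in windows):
        raise ValueError("window_vox must be >= 4")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an (N, 3) array of voxel indices")

    orders = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]  # d/dz, d/dy, d/dx
    grads = [gaussian_filter(vol, gradient_sigma_vox, order=o) for o in orders]

    n = len(coords)
    comp = {w: np.empty((n, 6), dtype=np.float64) for w in windows}
    for k, (i, j) in enumerate(_TENSOR_PAIRS):
        prod = grads[i] * grads[j]
        sat = _padded_sat(prod)
        del prod
        for w in windows:
            comp[w][:, k] = _box_sums(sat, coords, w, vol.shape)
        del sat

    out = {}
    for w in windows:
        c = comp[w]
        tensors = np.empty((n, 3, 3), dtype=np.float64)
        tensors[:, 0, 0] = c[:, 0]
        tensors[:, 0, 1] = tensors[:, 1, 0] = c[:, 1]
        tensors[:, 0, 2] = tensors[:, 2, 0] = c[:, 2]
        tensors[:, 1, 1] = c[:, 3]
        tensors[:, 1, 2] = tensors[:, 2, 1] = c[:, 4]
        tensors[:, 2, 2] = c[:, 5]
        trace = tensors[:, 0, 0] + tensors[:, 1, 1] + tensors[:, 2, 2]
        valid = trace > 1e-12
        evals = np.zeros((n, 3))
        evecs = np.tile(np.eye(3), (n, 1, 1))
        if valid.any():
            evals_v, evecs_v = np.linalg.eigh(tensors[valid])
            evals[valid] = evals_v
            evecs[valid] = evecs_v
        # isotropic tensor: the two smallest eigenvalues tie, no axis defined
        tie = valid & ((evals[:, 1] - evals[:, 0]) <= 1e-9 * np.maximum(trace, 1e-30))
        valid &= ~tie
        # eigenvector of the smallest eigenvalue, reordered (z,y,x) -> (x,y,z)
        axis = evecs[:, :, 0][:, ::-1]
        out[w] = (axis, valid)
    return out


def estimate_tensor_orientation(
    volume: np.ndarray,
    skeleton,
    window_vox: int = 32,
    gradient_sigma_vox: float = 1.0,
) -> OrientationField:
    """Per-skeleton-voxel 3D orientation via the local structure tensor.

    At every skeleton voxel the 3×3 tensor of Gaussian-derivative gradient
    outer products is averaged uniformly over the cubic window of side
    ``window_vox`` (clipped at volume borders); the fiber direction is the
    eigenvector of the smallest eigenvalue, converted to (θ, φ) degrees.

    ``skeleton`` may be a :class:`~fibramorph.preprocess.SkeletonVolume` or
    a binary array of the same shape as ``volume``.
    """
    skel = getattr(skeleton, "skeleton", skeleton)
    skel = np.asarray(skel).astype(bool)
    if skel.shape != volume.shape:
        raise ValueError("skeleton and volume shapes differ")
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return OrientationField(coords.reshape(0, 3), np.empty(0), np.empty(0),
                                int(window_vox), float(gradient_sigma_vox))
    dirs, valid = tensor_orientation_multi(
        volume, coords, [int(window_vox)], gradient_sigma_vox)[int(window_vox)]
    theta, phi = _vectors_to_angles_batch(dirs[valid])
    return OrientationField(
        coords=coords[valid],
        theta_deg=theta,
        phi_deg=phi,
        window_vox=int(window_vox),
        gradient_sigma_vox=float(gradient_sigma_vox),
        n_skipped=int((~valid).sum()),
    )


def estimate_fourier_orientation(image: np.ndarray) -> tuple[float, float]:
    """Global 2D orientation from a PCA of the Fourier power spectrum.

    Spectral power is treated as point weights on (centred) frequency
    coordinates; the dominant image orientation is perpendicular to the
    spectrum's major principal axis.  Returns ``(theta_deg, anisotropy)``
    with θ ∈ (−90, 90] measured from the +x (column) axis toward +y (row),
    and anisotropy = 1 − λ_minor/λ_major ∈ [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("estimate_fourier_orientation expects a 2D image")
    if min(img.shape) < 16:
        raise ValueError("image sides must be >= 16 pixels")
    if np.ptp(img) == 0:
        raise ValueError("constant image has no spectral energy")

    # Hann window suppresses spectral leakage from the non-periodic borders,
    # which would otherwise smear energy along the frequency axes
    win = (np.hanning(img.shape[0])[:, None] * np.hanning(img.shape[1])[None, :])
    power = np.abs(np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))) ** 2
    cy, cx = np.asarray(power.shape) // 2
    power[cy, cx] = 0.0  # remove any residual DC
    total = power.sum()
    if total <= 0:
        raise ValueError("constant image has no spectral energy")

    fy = (np.arange(power.shape[0]) - cy)[:, None]
    fx = (np.arange(power.shape[1]) - cx)[None, :]
    mxx = float((power * fx * fx).sum() / total)
    myy = float((power * fy * fy).sum() / total)
    mxy = float((power * fx * fy).sum() / total)
    evals, evecs = np.linalg.eigh(np.array([[mxx, mxy], [mxy, myy]]))
    major = evecs[:, 1]  # (x, y) of the spectrum's major axis
    # the image texture runs perpendicular to the spectral major axis
    theta = fold_azimuth_deg(np.degrees(np.arctan2(major[0], -major[1])))
    anisotropy = float(1.0 - max(evals[0], 0.0) / evals[1]) if evals[1] > 0 else 0.0
    return float(theta), anisotropy
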