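"""Segmentation and skeletonization: grayscale volume -> binary -> medial axis.

The estimators operate on a binary volume plus its one-voxel-thick skeleton.
Foreground is defined as *strictly above* the threshold so binarization is
bit-reproducible; thinning is delegated to scikit-image's 3D skeletonization
(Lee's parallel medial-axis thinning), recorded in the result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import skimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = ["SkeletonVolume", "binarize", "skeletonize3d"]


@dataclass
class SkeletonVolume:
    """One-voxel-thick medial-axis approximation of a binary volume."""

    skeleton: np.ndarray
    source: np.ndarray
    method: str = f"skimage.morphology.skeletonize (Lee94), scikit-image {skimage.__version__}"


def binarize(volume: np.ndarray, method: str = "otsu",
             threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale volume; foreground = values strictly above.

    ``method='otsu'`` computes the global Otsu threshold; ``method='fixed'``
    uses the supplied ``threshold``.
    """
    vol = np.asarray(volume)
    if method == "otsu":
        if np.ptp(vol) == 0:
            raise ValueError(
                "constant-valued volume: Otsu thresholding is undefined; "
                "use method='fixed' with an explicit threshold")
        threshold = threshold_otsu(vol)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return vol > threshold


def skeletonize3d(volume: np.ndarray) -> SkeletonVolume:
    """Medial-axis skeleton of a binary volume via 3D thinning.

    Preserves the connectivity of each foreground component; an empty volume
    yields an empty skeleton.
    """
    vol = np.asarray(volume).astype(bool)
    if vol.ndim != 3:
        raise ValueError("skeletonize3d expects a 3D volume")
    if not vol.any():
        return SkeletonVolume(skeleton=np.zeros_like(vol), source=vol)
    skel = _skimage_skeletonize(vol).astype(bool)
    return SkeletonVolume(skeleton=skel, source=vol)
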