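"""Porosity and particle morphometrics on labeled volumes.

A segmented material volume carries integer labels 1..M on a zero
background; porosity is the background ("air") fraction.  Particle/inclusion
counting is a connected-component analysis followed by per-object
morphometrics, exportable as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = ["PorosityResult", "calc_porosity", "object_counter"]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class PorosityResult:
    """Background fraction plus the volume fraction of each material label."""

    porosity: float
    per_material: dict
    total_voxels: int


def calc_porosity(labels: np.ndarray) -> PorosityResult:
    """Exact voxel-count porosity of a labeled volume.

    porosity = (# zero voxels) / (total voxels); ``per_material`` maps each
    label present to its fraction, so porosity + Σ fractions = 1.
    """
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("cannot compute porosity of an empty volume")
    if not np.issubdtype(lab.dtype, np.integer) and not lab.dtype == bool:
        if not np.array_equal(lab, np.round(lab)):
            raise ValueError("labels must be non-negative integers")
        lab = lab.astype(np.int64)
    if lab.min() < 0:
        raise ValueError("labels must be non-negative")
    counts = np.bincount(lab.ravel().astype(np.int64))
    total = lab.size
    per_material = {int(v): counts[v] / total
                    for v in range(1, len(counts)) if counts[v] > 0}
    return PorosityResult(porosity=counts[0] / total if len(counts) else 1.0,
                          per_material=per_material, total_voxels=int(total))


def object_counter(binary_or_labels: np.ndarray, connectivity: int = 26) -> pd.DataFrame:
    """Connected-component morphometrics of non-adjacent particles.

    Binary input is labeled internally under the chosen voxel connectivity
    (6/18/26); integer input is treated as pre-labeled.  Returns one row per
    object with its voxel count, centroid and bounding box (x, y, z order,
    0-based) and the equivalent-sphere diameter (6·V/π)^(1/3), sorted by
    label (scan order of component minima for internally labeled input).
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    vol = np.asarray(binary_or_labels)
    if vol.ndim != 3:
        raise ValueError("object_counter expects a 3D volume")
    vals = np.unique(vol)
    is_binary = vol.dtype == bool or np.array_equal(vals, vals.astype(bool).astype(vals.dtype))
    if is_binary:
        lab = cc_label(vol.astype(bool), connectivity=_CONNECTIVITY[connectivity])
    else:
        if not np.issubdtype(vol.dtype, np.integer) or vol.min() < 0:
            raise ValueError("pre-labeled input must be non-negative integers")
        lab = vol

    rows = []
    for rp in regionprops(lab):
        cz, cy, cx = rp.centroid
        z0, y0, x0, z1, y1, x1 = rp.bbox
        rows.append(
            {
                "label": int(rp.label),
                "voxel_count": int(rp.area),
                "centroid_x": cx, "centroid_y": cy, "centroid_z": cz,
                "bbox_x0": x0, "bbox_y0": y0, "bbox_z0": z0,
                "bbox_x1": x1, "bbox_y1": y1, "bbox_z1": z1,
                "equivalent_diameter_vox": float((6.0 * rp.area / np.pi) ** (1.0 / 3.0)),
            }
        )
    df = pd.DataFrame(rows, columns=[
        "label", "voxel_count", "centroid_x", "centroid_y", "centroid_z",
        "bbox_x0", "bbox_y0", "bbox_z0", "bbox_x1", "bbox_y1", "bbox_z1",
        "equivalent_diameter_vox"])
    return df.sort_values("label", ignore_index=True) if len(df) else df
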