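"""Volume and table input/output.

Volumes travel as multipage TIFF stacks or directories of equally sized 2D
TIFF/PNG slices (stacked in lexicographic filename order); sparse fields and
object tables as CSV with 0-based x, y, z voxel coordinates.  Arrays are
indexed (z, y, x).  Round trips are lossless for uint8/uint16/int32/float32.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_volume",
    "write_volume",
    "read_field_csv",
    "write_table",
    "write_config_json",
    "save_phantom",
]

_SUPPORTED_DTYPES = ("uint8", "uint16", "int32", "float32", "float64")
_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


def read_volume(path) -> np.ndarray:
    """Load a 3D volume from a multipage TIFF or a directory of 2D slices.

    A single 2D image yields a single-slice volume of shape (1, H, W).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise ValueError(f"no TIFF/PNG slices found in {path}")
        slices, shapes = [], {}
        for p in files:
            arr = tifffile.imread(p) if p.suffix.lower() in (".tif", ".tiff") \
                else iio.imread(p)
            if arr.ndim != 2:
                raise ValueError(f"slice {p.name} is not a 2D image")
            slices.append(arr)
            shapes.setdefault(arr.shape, []).append(p.name)
        if len(shapes) > 1:
            detail = "; ".join(f"{s}: {', '.join(names)}"
                               for s, names in shapes.items())
            raise ValueError(f"mixed slice shapes in {path}: {detail}")
        vol = np.stack(slices)
    else:
        vol = tifffile.imread(path)
        if vol.ndim == 2:
            vol = vol[None, ...]
    if vol.ndim != 3:
        raise ValueError(f"{path} does not contain a 2D image or 3D stack")
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    if vol.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {vol.dtype} in {path}; "
                         f"supported: {', '.join(_SUPPORTED_DTYPES)}")
    return vol


def _refuse_overwrite(path: Path, force: bool):
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (--force) to overwrite")


def write_volume(volume: np.ndarray, path, force: bool = False) -> None:
    """Write a volume as a multipage TIFF (lossless for supported dtypes)."""
    path = Path(path)
    _refuse_overwrite(path, force)
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    if vol.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {vol.dtype}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol)


def write_table(df: pd.DataFrame, path, force: bool = False) -> None:
    path = Path(path)
    _refuse_overwrite(path, force)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_field_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config_json(config: dict, path, force: bool = False) -> None:
    """Record a run's resolved parameters next to its outputs."""
    path = Path(path)
    _refuse_overwrite(path, force)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def save_phantom(phantom, outdir, force: bool = False) -> dict:
    """Export a phantom: volume + labels TIFF, fiber table CSV, config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": outdir / "volume.tif",
        "labels": outdir / "labels.tif",
        "fibers": outdir / "fibers.csv",
        "config": outdir / "config.json",
    }
    write_volume(phantom.volume.astype(np.uint8), paths["volume"], force)
    write_volume(phantom.labels.astype(np.uint16), paths["labels"], force)
    rows = [
        {
            "label": f.label,
            "theta_deg": f.theta_deg,
            "phi_deg": f.phi_deg,
            "diameter_vox": f.diameter_vox,
            "length_vox": f.length_vox,
            "seed_x": f.seed_point[0],
            "seed_y": f.seed_point[1],
            "seed_z": f.seed_point[2],
        }
        for f in phantom.fibers
    ]
    write_table(pd.DataFrame(rows, columns=[
        "label", "theta_deg", "phi_deg", "diameter_vox", "length_vox",
        "seed_x", "seed_y", "seed_z"]), paths["fibers"], force)
    write_config_json(phantom.config.to_dict(), paths["config"], force)
    return {k: str(v) for k, v in paths.items()}
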