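"""Orientation color mapping and post-hoc statistics.

``geo2rgb`` maps an (azimuth, elevation) pair onto an HSV-derived RGB triple
for volume rendering: hue encodes the azimuth, brightness the elevation (a
0.3 floor keeps in-plane fibers visible), saturation is fixed at 1.  The
mapping is deterministic so renders are reproducible with any viewer.

``calculate_tukey_posthoc`` wraps Tukey's HSD (studentized-range) test over
all pairs of groups, the standard post-hoc after ANOVA for comparing e.g.
porosities across biomaterial types.
"""

from __future__ import annotations

import colorsys

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .orient import OrientationField

__all__ = ["geo2rgb", "colorize_field", "calculate_tukey_posthoc"]


def geo2rgb(theta_deg: float, phi_deg: float) -> tuple[float, float, float]:
    """RGB in [0,1]³ for azimuth θ ∈ (−90, 90] and elevation φ ∈ [0, 90].

    hue = (θ + 90)/180, saturation = 1, value = 0.3 + 0.7·φ/90.
    """
    if not (-90.0 < theta_deg <= 90.0):
        raise ValueError(f"azimuth {theta_deg} outside (-90, 90]")
    if not (0.0 <= phi_deg <= 90.0):
        raise ValueError(f"elevation {phi_deg} outside [0, 90]")
    hue = (theta_deg + 90.0) / 180.0
    value = 0.3 + 0.7 * (phi_deg / 90.0)
    r, g, b = colorsys.hsv_to_rgb(hue % 1.0, 1.0, value)
    return (float(np.clip(r, 0, 1)), float(np.clip(g, 0, 1)), float(np.clip(b, 0, 1)))


def colorize_field(field: OrientationField) -> pd.DataFrame:
    """Per-voxel RGB table (x, y, z, r, g, b) for an orientation field."""
    theta = np.asarray(field.theta_deg, dtype=float)
    phi = np.asarray(field.phi_deg, dtype=float)
    hsv = np.stack([((theta + 90.0) / 180.0) % 1.0,
                    np.ones_like(theta),
                    0.3 + 0.7 * (phi / 90.0)], axis=1)
    rgb = hsv_to_rgb(hsv)
    df = field.to_dataframe()[["x", "y", "z"]].copy()
    df[["r", "g", "b"]] = np.clip(rgb, 0.0, 1.0)
    return df


def calculate_tukey_posthoc(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over all group pairs.

    ``values`` are observations (e.g. per-sample porosities), ``groups`` the
    matching group labels (e.g. biomaterial types).  Returns one row per
    pair: group_a, group_b, mean_diff, p_adj, reject.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2]
    if len(small):
        raise ValueError(
            f"group(s) with fewer than 2 observations: {', '.join(map(str, small))}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tbl = res.summary().data[1:]
    return pd.DataFrame(
        [
            {
                "group_a": row[0],
                "group_b": row[1],
                "mean_diff": float(row[2]),
                "p_adj": float(pv),
                "reject": bool(rej),
            }
            for row, pv, rej in zip(tbl, res.pvalues, res.reject)
        ]
    )
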