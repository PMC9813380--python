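"""Per-map image features.

Three families, all computed on the 8 x 8 intensity image:

* **LoC** (location of the center, or barycenter): the intensity-weighted
  centroid of the electrode positions, in mm from the corner electrode;
  ``LoC = sum(I_ij * (i, j)) / sum(I_ij)`` converted by the IED.
* **Shannon entropy** of the squared-intensity distribution:
  ``p_k = I_k^2 / sum_j I_j^2``, ``E = -sum p_k log2 p_k`` (0 log 0 = 0),
  in bits; 6 bits for a perfectly homogeneous 64-pixel map, 0 for a
  one-hot map.
* **Histogram moments** of the 64 pixel intensities: mean, population
  variance, standardized skewness and (non-excess) kurtosis; skewness and
  kurtosis are 0 by convention when the variance vanishes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError
from .grid import ElectrodeGrid
from .maps import ActivationMapStack

FEATURE_COLUMNS = (
    "loc_x_mm",
    "loc_y_mm",
    "entropy_bits",
    "m1",
    "m2",
    "m3",
    "m4",
)


def loc(map_2d: np.ndarray, grid: ElectrodeGrid | None = None) -> tuple[float, float]:
    """Intensity-weighted centroid in mm; origin at the (0, 0) corner electrode."""
    grid = grid or ElectrodeGrid()
    m = np.asarray(map_2d, dtype=float)
    total = m.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero map has no center")
    rows, cols = np.indices(m.shape)
    y = (m * rows).sum() / total * grid.ied_mm
    x = (m * cols).sum() / total * grid.ied_mm
    return float(x), float(y)


def map_entropy(map_2d: np.ndarray, power: float = 2.0) -> float:
    """Shannon entropy (bits) of the normalized ``I^power`` distribution."""
    m = np.asarray(map_2d, dtype=float).ravel()
    w = m**power
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero map has no entropy")
    p = w / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def histogram_moments(map_2d: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, population variance, skewness, kurtosis) of pixel intensities.

    Kurtosis is the Pearson (non-excess) form, 3 for a Gaussian histogram.
    """
    x = np.asarray(map_2d, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValidationError("map contains non-finite pixels")
    m1 = x.mean()
    d = x - m1
    m2 = (d**2).mean()
    # constant maps leave O(eps) rounding residue after mean removal
    if m2 <= (8 * np.finfo(float).eps * max(1.0, abs(m1))) ** 2:
        return float(m1), 0.0, 0.0, 0.0
    m3 = (d**3).mean() / m2**1.5
    m4 = (d**4).mean() / m2**2
    return float(m1), float(m2), float(m3), float(m4)


def map_features(map_2d: np.ndarray, grid: ElectrodeGrid | None = None) -> dict:
    """All seven features of one map; degenerate maps get NaN location/entropy."""
    m1, m2, m3, m4 = histogram_moments(map_2d)
    try:
        x_mm, y_mm = loc(map_2d, grid)
        ent = map_entropy(map_2d)
        degenerate = False
    except DegenerateInputError:
        x_mm = y_mm = ent = float("nan")
        degenerate = True
    return {
        "loc_x_mm": x_mm,
        "loc_y_mm": y_mm,
        "entropy_bits": ent,
        "m1": m1,
        "m2": m2,
        "m3": m3,
        "m4": m4,
        "degenerate": degenerate,
    }


def feature_table(
    stacks: list[ActivationMapStack], grid: ElectrodeGrid | None = None
) -> pd.DataFrame:
    """One row per map per condition, ordered by (condition, map index)."""
    if not stacks:
        raise ValidationError("empty stack list")
    grid = grid or ElectrodeGrid()
    rows = []
    for stack in stacks:
        for t in range(stack.n_maps):
            row = {
                "window_ms": stack.scheme.window_ms,
                "overlap_pct": stack.scheme.overlap_pct,
                "map_index": t,
            }
            row.update(map_features(stack.maps[t], grid))
            rows.append(row)
    return pd.DataFrame(rows)
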