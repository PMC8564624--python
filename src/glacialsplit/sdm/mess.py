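"""Multivariate environmental similarity surfaces (MESS).

For each variable, with ``f`` the percentage of reference values strictly
below the point value, the similarity is

    f = 0        : 100 * (p - min) / (max - min)
    0 < f <= 50  : 2 f
    50 < f < 100 : 2 (100 - f)
    f = 100      : 100 * (max - p) / (max - min)

and the MESS value is the minimum across variables; values below zero flag
cells where at least one variable is extrapolated beyond its reference range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from glacialsplit.sdm.raster import EnvStack, Raster

logger = logging.getLogger(__name__)


def mess_one_variable(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Similarity of each point value to a reference sample for one variable."""
    reference = np.sort(np.asarray(reference, dtype=float))
    if reference.size == 0:
        raise ValueError("empty reference sample")
    points = np.asarray(points, dtype=float)
    ref_min, ref_max = reference[0], reference[-1]
    span = ref_max - ref_min
    m = reference.size
    f = 100.0 * np.searchsorted(reference, points, side="left") / m
    sim = np.empty_like(points, dtype=float)
    if span == 0:
        logger.warning("degenerate reference (max == min); similarity is 0 at "
                       "the reference value and negative-linear outside")
        scale = max(abs(ref_min), 1.0)
        return -100.0 * np.abs(points - ref_min) / scale
    lo = f == 0
    hi = f == 100
    mid_lo = (f > 0) & (f <= 50)
    mid_hi = (f > 50) & (f < 100)
    sim[lo] = 100.0 * (points[lo] - ref_min) / span
    sim[mid_lo] = 2.0 * f[mid_lo]
    sim[mid_hi] = 2.0 * (100.0 - f[mid_hi])
    sim[hi] = 100.0 * (ref_max - points[hi]) / span
    return sim


def mess(points: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MESS of points (n, k) against a reference sample (m, k).

    Returns (min-similarity per point, per-variable similarities (n, k)).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if points.shape[1] != reference.shape[1]:
        raise ValueError("points and reference need the same variable count")
    per_var = np.stack(
        [
            mess_one_variable(points[:, v], reference[:, v])
            for v in range(points.shape[1])
        ],
        axis=1,
    )
    return per_var.min(axis=1), per_var


@dataclass
class MESSSurface:
    """Cell-wise minimum similarity plus per-variable surfaces."""

    min_raster: Raster
    per_variable: dict[str, Raster]
    reference_description: str = ""

    def extrapolated_fraction(self) -> float:
        vals = self.min_raster.values
        finite = np.isfinite(vals)
        return float((vals[finite] < 0).mean()) if finite.any() else float("nan")


def mess_surface(
    env: EnvStack, reference: np.ndarray, reference_description: str = ""
) -> MESSSurface:
    """MESS over a time slice's masked cells against a reference table."""
    table = env.table()
    min_sim, per_var = mess(table, reference)
    grid = env.grid

    def as_raster(vec, name):
        vals = np.full(grid.shape, np.nan)
        vals[env.mask] = vec
        return Raster(vals, x0=grid.x0, y0=grid.y0, cell=grid.cell, name=name)

    return MESSSurface(
        min_raster=as_raster(min_sim, "mess_min"),
        per_variable={
            name: as_raster(per_var[:, v], f"mess_{name}")
            for v, name in enumerate(env.var_names)
        },
        reference_description=reference_description,
    )
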