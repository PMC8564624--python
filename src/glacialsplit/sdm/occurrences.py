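"""Occurrence thinning and background (pseudo-absence) sampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


@dataclass
class OccurrenceSet:
    """Presence and background points (x, y) with the thinning cell size."""

    presence: np.ndarray
    background: np.ndarray
    thin_cell_km: float = 0.0

    def __post_init__(self) -> None:
        self.presence = np.atleast_2d(np.asarray(self.presence, dtype=float))
        self.background = np.atleast_2d(np.asarray(self.background, dtype=float))
        for arr, name in ((self.presence, "presence"), (self.background, "background")):
            if arr.size and arr.shape[1] != 2:
                raise ValueError(f"{name} points must be (n, 2)")

    def to_csv(self, presence_path, background_path) -> None:
        pd.DataFrame(self.presence, columns=["lon", "lat"]).to_csv(
            presence_path, index=False
        )
        pd.DataFrame(self.background, columns=["lon", "lat"]).to_csv(
            background_path, index=False
        )

    @classmethod
    def from_csv(cls, presence_path, background_path, thin_cell_km=0.0):
        pres = pd.read_csv(presence_path)[["lon", "lat"]].to_numpy()
        back = pd.read_csv(background_path)[["lon", "lat"]].to_numpy()
        return cls(pres, back, thin_cell_km)


def _to_km(points: np.ndarray, metric: str) -> np.ndarray:
    if metric == "planar":
        return points
    if metric == "lonlat":
        lat0 = np.mean(points[:, 1])
        x = points[:, 0] * KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(lat0))
        y = points[:, 1] * KM_PER_DEG_LAT
        return np.stack([x, y], axis=1)
    raise ValueError(f"unknown metric {metric!r}")


def thin_occurrences(
    points: np.ndarray,
    cell_km: float = 50.0,
    seed: int = 0,
    metric: str = "planar",
) -> np.ndarray:
    """Retain one record per cell_km x cell_km cell.

    Points are shuffled with the seed, then the first point seen in each cell
    is kept, so the choice within a cell is random but reproducible. For
    ``metric='lonlat'`` degrees are converted to kilometres with an
    equirectangular approximation at the mean latitude.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if len(points) == 0:
        return points
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(points))
    km = _to_km(points, metric)
    cells = np.floor(km / cell_km).astype(int)
    seen: set[tuple[int, int]] = set()
    keep = []
    for idx in order:
        key = (cells[idx, 0], cells[idx, 1])
        if key not in seen:
            seen.add(key)
            keep.append(idx)
    keep = sorted(keep)
    return points[keep]


def sample_background(env, n: int, seed: int = 0) -> np.ndarray:
    """Uniform sample of masked-cell centers without replacement.

    ``env`` is an :class:`~glacialsplit.sdm.raster.EnvStack` (its land/region
    mask defines the candidate cells).
    """
    mask = env.mask
    cand = np.flatnonzero(mask.ravel())
    if n > cand.size:
        raise ValueError(f"requested {n} background points but only "
                         f"{cand.size} masked cells exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cand, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, mask.shape)
    xg, yg = env.grid.cell_centers()
    return np.stack([xg[rows, cols], yg[rows, cols]], axis=1)
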