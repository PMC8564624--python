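"""Minimal planar raster container with delimited-text + JSON-sidecar I/O.

Grids are row-major 2-D arrays; row 0 is the northernmost (top) row, matching
the usual raster convention. Coordinates are planar cell-center coordinates
derived from an origin (x0, y0 = lower-left corner) and a square cell size.
NaN encodes nodata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Raster:
    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell: float = 1.0
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays of shape == values.shape."""
        nrow, ncol = self.shape
        xs = self.x0 + (np.arange(ncol) + 0.5) * self.cell
        ys = self.y0 + (nrow - np.arange(nrow) - 0.5) * self.cell  # row 0 = top
        return np.meshgrid(xs, ys)

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of points; raises if any point is off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row_from_bottom = np.floor((y - self.y0) / self.cell).astype(int)
        nrow, ncol = self.shape
        row = nrow - 1 - row_from_bottom
        if np.any((col < 0) | (col >= ncol) | (row < 0) | (row >= nrow)):
            raise ValueError("point outside raster extent")
        return row, col

    def extract(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.point_to_cell(x, y)
        return self.values[row, col]

    # ------------------------------------------------------------------- I/O
    def to_text(self, path) -> None:
        """Write the grid as whitespace-delimited text plus a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, np.where(np.isnan(self.values), -9999.0, self.values),
                   fmt="%.8g")
        sidecar = {
            "nrows": self.shape[0],
            "ncols": self.shape[1],
            "x0": self.x0,
            "y0": self.y0,
            "cell": self.cell,
            "nodata": -9999.0,
            "name": self.name,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def from_text(cls, path) -> "Raster":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        vals = np.loadtxt(path).reshape(meta["nrows"], meta["ncols"])
        vals = np.where(vals == meta.get("nodata", -9999.0), np.nan, vals)
        return cls(vals, x0=meta["x0"], y0=meta["y0"], cell=meta["cell"],
                   name=meta.get("name", "layer"))


@dataclass
class EnvStack:
    """Named environmental variable rasters on one grid for one time slice."""

    variables: dict[str, Raster]
    mask: np.ndarray | None = None  # True = usable land cell
    time_bp: float = 0.0

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("EnvStack needs at least one variable")
        rasters = list(self.variables.values())
        for r in rasters[1:]:
            if not rasters[0].same_grid(r):
                raise ValueError("all variables must share one grid")
        if self.mask is None:
            self.mask = np.all(
                [np.isfinite(r.values) for r in rasters], axis=0
            )
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != rasters[0].shape:
            raise ValueError("mask shape must match the grid")

    @property
    def grid(self) -> Raster:
        return next(iter(self.variables.values()))

    @property
    def var_names(self) -> list[str]:
        return list(self.variables)

    def table(self) -> np.ndarray:
        """(n_masked_cells, n_vars) matrix of variable values on the mask."""
        return np.stack(
            [r.values[self.mask] for r in self.variables.values()], axis=1
        )

    def extract(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """(n_points, n_vars) variable values at planar points."""
        return np.stack(
            [r.extract(x, y) for r in self.variables.values()], axis=1
        )

    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, r in self.variables.items():
            r.to_text(directory / f"{name}.txt")
        Raster(self.mask.astype(float), x0=self.grid.x0, y0=self.grid.y0,
               cell=self.grid.cell, name="mask").to_text(directory / "mask.txt")
        (directory / "stack.json").write_text(
            json.dumps({"time_bp": self.time_bp, "variables": self.var_names})
        )

    @classmethod
    def read_dir(cls, directory) -> "EnvStack":
        directory = Path(directory)
        meta = json.loads((directory / "stack.json").read_text())
        variables = {
            name: Raster.from_text(directory / f"{name}.txt")
            for name in meta["variables"]
        }
        mask = Raster.from_text(directory / "mask.txt").values > 0.5
        return cls(variables, mask=mask, time_bp=meta["time_bp"])
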