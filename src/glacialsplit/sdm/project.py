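"""Time-slice projection, range-area series and collapse detection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from glacialsplit.sdm.ensemble import SDMEnsemble
from glacialsplit.sdm.mess import MESSSurface, mess_surface
from glacialsplit.sdm.raster import EnvStack, Raster


@dataclass
class SliceProjection:
    time_bp: float
    suitability: Raster
    binary: Raster
    area_cells: int
    mess: MESSSurface | None = None

    @property
    def fully_extrapolated(self) -> bool:
        if self.mess is None:
            return False
        vals = self.mess.min_raster.values
        finite = np.isfinite(vals)
        return bool(finite.any() and np.all(vals[finite] < 0))


@dataclass
class ProjectionSeries:
    slices: list[SliceProjection] = field(default_factory=list)

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.area_cells for s in self.slices], dtype=float)

    @property
    def times_bp(self) -> np.ndarray:
        return np.array([s.time_bp for s in self.slices])


def project_time_slices(
    ensemble: SDMEnsemble,
    stacks: list[EnvStack],
    mess_reference: np.ndarray | None = None,
) -> ProjectionSeries:
    """Project the ensemble across per-slice climate stacks.

    Per slice: continuous suitability, a binary range map at the ensemble's
    mean max-TSS threshold, a suitable-cell count as the range-area proxy,
    and (when a reference table is given) a MESS surface flagging
    extrapolated cells. Slices whose MESS is negative everywhere are flagged
    via :attr:`SliceProjection.fully_extrapolated`.
    """
    out = ProjectionSeries()
    thr = ensemble.threshold
    for stack in stacks:
        suit = ensemble.predict_raster(stack)
        binary_vals = np.where(np.isfinite(suit.values), (suit.values >= thr) * 1.0, np.nan)
        binary = Raster(binary_vals, x0=suit.x0, y0=suit.y0, cell=suit.cell,
                        name="range_map")
        area = int(np.nansum(binary_vals))
        m = None
        if mess_reference is not None:
            m = mess_surface(stack, mess_reference, "training presence cells")
        out.slices.append(
            SliceProjection(stack.time_bp, suit, binary, area, mess=m)
        )
    return out


def detect_range_collapse(
    areas: np.ndarray, drop_frac: float = 0.5
) -> list[tuple[int, int]]:
    """Slice-index intervals where area < drop_frac * the series median.

    Adjacent collapsed slices merge into one interval. Needs >= 3 slices.
    """
    areas = np.asarray(areas, dtype=float)
    if len(areas) < 3:
        raise ValueError("need at least three slices")
    if not 0 < drop_frac < 1:
        raise ValueError("drop_frac must be in (0, 1)")
    ref = np.median(areas)
    low = areas < drop_frac * ref
    intervals: list[tuple[int, int]] = []
    start = None
    for k, flag in enumerate(low):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            intervals.append((start, k - 1))
            start = None
    if start is not None:
        intervals.append((start, len(low) - 1))
    return intervals
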