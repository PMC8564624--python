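"""Synthetic landscapes with a known logistic climate niche.

Four spatially autocorrelated environmental rasters (Gaussian smoothing of
white noise, kernel width = the correlation length, then re-standardized)
mirror a breeding-season predictor set of precipitation variability, minimum
precipitation, mean temperature and temperature variability. True suitability
is a logistic function of the standardized variables; presences are sampled
without replacement proportional to suitability, background uniformly from
the land mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from glacialsplit.sdm.occurrences import OccurrenceSet
from glacialsplit.sdm.raster import EnvStack, Raster

DEFAULT_VAR_NAMES = (
    "precip_variability",
    "precip_minimum",
    "temp_mean",
    "temp_variability",
)


@dataclass(frozen=True)
class LandscapeSimSpec:
    """Recipe for a synthetic environmental landscape.

    ``niche_coeffs`` are (intercept, beta_1 .. beta_n_vars) of the logistic
    suitability function of the standardized variables; all-zero coefficients
    give suitability 0.5 everywhere. ``spatial_corr_length`` is the Gaussian
    kernel width in cells (0 = independent cells).
    """

    grid_shape: tuple[int, int] = (60, 80)
    n_vars: int = 4
    spatial_corr_length: float = 5.0
    niche_coeffs: tuple = (-24.0, 14.0, 7.0, -9.0, -5.0)
    n_presence: int = 400
    n_background: int = 1000
    seed: int = 0
    var_names: tuple = field(default=DEFAULT_VAR_NAMES)

    def __post_init__(self) -> None:
        if self.n_vars < 1:
            raise ValueError("need at least one variable")
        if len(self.niche_coeffs) != self.n_vars + 1:
            raise ValueError("niche_coeffs must have length n_vars + 1 (intercept first)")
        if len(self.var_names) < self.n_vars:
            object.__setattr__(
                self, "var_names",
                tuple(f"var{k}" for k in range(self.n_vars)),
            )
        if self.spatial_corr_length < 0:
            raise ValueError("spatial_corr_length must be >= 0")
        n_cells = self.grid_shape[0] * self.grid_shape[1]
        if self.n_presence > n_cells or self.n_background > n_cells:
            raise ValueError("more samples requested than grid cells available")


def simulate_landscape(
    spec: LandscapeSimSpec,
) -> tuple[EnvStack, OccurrenceSet, Raster]:
    """Generate (EnvStack, OccurrenceSet, true-suitability raster).

    Bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    nrow, ncol = spec.grid_shape
    variables: dict[str, Raster] = {}
    z_layers = []
    for v in range(spec.n_vars):
        white = rng.normal(size=(nrow, ncol))
        if spec.spatial_corr_length > 0:
            sm = gaussian_filter(white, sigma=spec.spatial_corr_length, mode="wrap")
        else:
            sm = white
        z = (sm - sm.mean()) / sm.std()
        z_layers.append(z)
        name = spec.var_names[v]
        variables[name] = Raster(z, name=name)
    env = EnvStack(variables, time_bp=0.0)

    lin = np.full((nrow, ncol), float(spec.niche_coeffs[0]))
    for v, z in enumerate(z_layers):
        lin += spec.niche_coeffs[v + 1] * z
    suitability = 1.0 / (1.0 + np.exp(-lin))
    truth = Raster(suitability, name="true_suitability")

    xg, yg = truth.cell_centers()
    flat_x, flat_y = xg.ravel(), yg.ravel()
    w = suitability.ravel()
    p = w / w.sum()
    pres_idx = rng.choice(len(p), size=spec.n_presence, replace=False, p=p)
    back_idx = rng.choice(len(p), size=spec.n_background, replace=False)
    presence = np.stack([flat_x[pres_idx], flat_y[pres_idx]], axis=1)
    background = np.stack([flat_x[back_idx], flat_y[back_idx]], axis=1)
    return env, OccurrenceSet(presence, background), truth


def simulate_time_slices(
    spec: LandscapeSimSpec,
    n_slices: int = 10,
    crash_slices: tuple[int, ...] = (),
    crash_shift: float = 6.0,
    drift_sd: float = 0.05,
    seed: int | None = None,
) -> tuple[list[EnvStack], OccurrenceSet, Raster]:
    """A sequence of climate slices sharing one base landscape.

    Each slice adds a small random uniform offset (sd ``drift_sd``) to every
    variable; in ``crash_slices`` the variable with the strongest niche
    coefficient is additionally shifted by ``crash_shift`` standard
    deviations, pushing it outside the species' tolerance and collapsing the
    suitable range there. Slice 0 is the unmodified (training) climate.
    """
    env, occ, truth = simulate_landscape(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    betas = np.asarray(spec.niche_coeffs[1:])
    crash_var = env.var_names[int(np.argmax(np.abs(betas)))]
    sign = -np.sign(betas[int(np.argmax(np.abs(betas)))]) or -1.0
    stacks = []
    for k in range(n_slices):
        variables = {}
        for name, r in env.variables.items():
            vals = r.values.copy()
            if k > 0:
                vals = vals + rng.normal(0.0, drift_sd)
            if k in crash_slices and name == crash_var:
                vals = vals + sign * crash_shift
            variables[name] = Raster(vals, x0=r.x0, y0=r.y0, cell=r.cell, name=name)
        stacks.append(EnvStack(variables, mask=env.mask.copy(), time_bp=1000.0 * k))
    return stacks, occ, truth
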