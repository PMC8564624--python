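"""Conversion between diffusion units and real units (years, individuals).

The unit chain follows the standard diffusion-SFS conventions:

- ``theta = 4 * N_ref * mu_gen * L`` where ``mu_gen`` is the per-generation,
  per-site mutation rate times nothing (per-site) — the per-locus rate is
  ``mu_gen * L`` for effective sequence length ``L``;
- times in units of ``T = 2 * N_ref`` generations;
- migration in units of ``M_ij = 2 * N_ref * m_ij``.

Defaults use a directly estimated avian germ-line mutation rate of
2.3e-9 per site per year and a two-year generation time, so
``mu_gen = mu_site_year * generation_years``. Mixing per-year and
per-generation rates silently would change every date by the generation
time, so the chain is kept explicit.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UnitSystem:
    """Mutation-rate / generation-time / sequence-length unit chain."""

    mu_site_year: float = 2.3e-9
    generation_years: float = 2.0
    L: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_site_year <= 0 or self.generation_years <= 0 or self.L <= 0:
            raise ValueError("all unit-system quantities must be positive")

    @property
    def mu_gen(self) -> float:
        """Per-site, per-generation mutation rate."""
        return self.mu_site_year * self.generation_years

    @property
    def mu_locus_gen(self) -> float:
        """Per-generation mutation rate of the whole analyzed sequence."""
        return self.mu_gen * self.L

    def n_ref(self, theta: float) -> float:
        """Reference diploid size implied by a fitted theta."""
        if theta <= 0:
            raise ValueError("theta must be positive")
        return theta / (4.0 * self.mu_locus_gen)

    def theta(self, n_ref: float) -> float:
        return 4.0 * n_ref * self.mu_locus_gen


def estimate_L(L_unfiltered: float, seg_filtered: float, seg_unfiltered: float) -> float:
    """Effective sequence length after site filtering.

    ``L = L_unfiltered * seg_filtered / seg_unfiltered`` — the filtered
    fraction of segregating sites scales the callable length. A zero filtered
    count yields L = 0, which downstream conversions refuse as degenerate.
    """
    if L_unfiltered <= 0:
        raise ValueError("L_unfiltered must be positive")
    if seg_unfiltered <= 0:
        raise ValueError("unfiltered segregating-site count must be positive")
    if seg_filtered < 0 or seg_filtered > seg_unfiltered:
        raise ValueError("need 0 <= seg_filtered <= seg_unfiltered")
    return L_unfiltered * seg_filtered / seg_unfiltered


def convert_units(params: dict, theta: float, units: UnitSystem) -> dict:
    """Convert diffusion-unit parameters to real units.

    ``params`` maps names to values: keys starting with ``t`` are times (in
    2*N_ref generations), ``nu`` sizes (ratios of N_ref), ``m`` migration
    (M = 2*N_ref*m). Returns a dict with ``N_ref`` plus per-parameter
    ``*_years`` / ``*_individuals`` / ``*_per_gen`` entries.
    """
    n_ref = units.n_ref(theta)
    out = {"N_ref": n_ref, "theta": theta}
    for name, value in params.items():
        if name.startswith("t"):
            out[f"{name}_years"] = value * 2.0 * n_ref * units.generation_years
        elif name.startswith("nu"):
            out[f"{name}_individuals"] = value * n_ref
        elif name.startswith("m"):
            out[f"{name}_per_gen"] = value / (2.0 * n_ref)
        else:
            out[name] = value
    return out


def diffusion_units(real: dict, theta: float, units: UnitSystem) -> dict:
    """Inverse of :func:`convert_units`; exact to floating-point round-off."""
    n_ref = units.n_ref(theta)
    out = {}
    for name, value in real.items():
        if name in ("N_ref", "theta"):
            continue
        if name.endswith("_years"):
            out[name[: -len("_years")]] = value / (2.0 * n_ref * units.generation_years)
        elif name.endswith("_individuals"):
            out[name[: -len("_individuals")]] = value / n_ref
        elif name.endswith("_per_gen"):
            out[name[: -len("_per_gen")]] = value * 2.0 * n_ref
        else:
            out[name] = value
    return out
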