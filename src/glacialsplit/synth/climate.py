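"""Synthetic temperature series with engineered rapid-change events.

Emulates an ice-core temperature record at fixed resolution: a piecewise
linear long-term baseline, superimposed stadial/interstadial-style jump
events (linear ramps of configurable amplitude and duration), and an AR(1)
noise background with a controllable autocorrelation and marginal standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from glacialsplit.climate import ClimateSeries


@dataclass(frozen=True)
class ClimateSimSpec:
    """Ground-truth recipe for a synthetic climate series.

    ``baseline`` is either a constant (deg C) or a list of (age_bp, temp)
    knots interpolated linearly. Each event is (onset_bp, amplitude_C,
    ramp_years): temperature ramps linearly by the amplitude over the ramp
    duration starting at the onset (moving toward the present) and stays
    shifted afterwards. ``noise_sd`` is the stationary marginal standard
    deviation of the AR(1) background.
    """

    duration: float = 120_000.0
    step: float = 1000.0
    baseline: float | list = 0.0
    events: list = field(default_factory=list)
    ar1_coeff: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.duration <= 0 or (self.duration / self.step) % 1 != 0:
            raise ValueError("duration must be a positive multiple of step")
        if not 0 <= self.ar1_coeff < 1:
            raise ValueError("ar1_coeff must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for ev in self.events:
            onset, amp, ramp = ev
            if not 0 <= onset <= self.duration:
                raise ValueError("event onset outside the series span")
            if ramp < 0:
                raise ValueError("event ramp must be >= 0")


def simulate_climate(spec: ClimateSimSpec) -> ClimateSeries:
    """Generate the series (oldest sample first); deterministic under the seed."""
    n = int(spec.duration / spec.step) + 1
    ages = spec.duration - spec.step * np.arange(n)  # descending, ends at 0 BP
    if isinstance(spec.baseline, (int, float)):
        temp = np.full(n, float(spec.baseline))
    else:
        knots = sorted(spec.baseline)  # ascending age
        ka = np.array([k[0] for k in knots], dtype=float)
        kv = np.array([k[1] for k in knots], dtype=float)
        temp = np.interp(ages, ka, kv)
    for onset, amp, ramp in spec.events:
        elapsed = onset - ages  # years since onset, negative before the event
        if ramp > 0:
            frac = np.clip(elapsed / ramp, 0.0, 1.0)
        else:
            frac = (elapsed >= 0).astype(float)
        temp = temp + amp * frac
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        a = spec.ar1_coeff
        innov_sd = spec.noise_sd * np.sqrt(1.0 - a * a)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, spec.noise_sd)
        shocks = rng.normal(0.0, innov_sd, size=n - 1)
        for k in range(1, n):
            noise[k] = a * noise[k - 1] + shocks[k - 1]
        temp = temp + noise
    return ClimateSeries(ages, temp, label="temp_c")
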