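"""Fit a split-with-migration model and date the split in calendar years.

Simulates a two-population history with one coherent mutation-rate chain
(2.3e-9 per site per year, 2-year generations), fits the
size-change + split + migration model by Poisson composite likelihood with
multi-start Nelder-Mead, and converts the fitted split time to thousands of
years before present.
"""

from glacialsplit.demog import (
    UnitSystem,
    estimate_L,
    fit_model,
    summarize_split_times,
)
from glacialsplit.synth import SimDemography, simulate_coalescent

MU, GEN = 2.3e-9, 2.0
N_REF = 200_000
truth = SimDemography(n_pops=2, nu_anc=1.0, t_anc=0.05, t_split=0.025,
                      m12=1.0, m21=1.0, N_ref=N_REF)
true_kya = truth.t_split * 2 * N_REF * GEN / 1000.0
theta_site = 4 * N_REF * MU * GEN

table, sfs = simulate_coalescent(truth, (12, 12), 1_000_000, theta_site, seed=4)
print(f"simulated {int(sfs.total())} segregating sites; "
      f"true split {true_kya:.0f} kya")

fit = fit_model(sfs, "two_pop_sizechange_split_mig", n_starts=8, seed=5,
                maxiter=1500)
best = fit.best
print(f"best composite log-likelihood {best.loglik:.1f}; "
      f"t_split = {best.params['t_split']:.4f} (diffusion units), "
      f"theta-hat = {best.theta:.1f}")

units = UnitSystem(mu_site_year=MU, generation_years=GEN,
                   L=estimate_L(1_000_000, sfs.total(), sfs.total()))
summary = summarize_split_times(fit, units)
print(f"split time: median {summary['median_kya']:.1f} kya, "
      f"IQR {summary['q25_kya']:.1f}-{summary['q75_kya']:.1f} kya "
      f"across {len(summary['runs_kya'])} optimization runs")
print(f"(truth {true_kya:.0f} kya; the median/IQR summarize across-run "
      f"scatter exactly as split-time density curves are reported)")
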