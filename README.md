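# glacialsplit

Inference tools for linking population splits to rapid climate change in
structured species — built around the study system of European pied
flycatchers (*Ficedula hypoleuca*), whose southern (Spanish) and UK lineages
diverged from the central/northern European cluster during episodes of
pronounced climate instability rather than at glacial maxima.

The package chains four independently usable stages:

1. **`glacialsplit.afs`** — maximum-likelihood minor-allele frequencies and
   polymorphism tests directly from genotype likelihoods (no genotype
   calls), the coverage / p-value / MAF site-filter chain with attrition
   accounting, BED region masks, and 1-3 dimensional joint site-frequency
   spectra (SFS), folded or unfolded, in dadi-style `.fs` text.
2. **`glacialsplit.demog`** — expected joint SFS under
   size-change + split(s)-with-migration models via a deterministic
   moment-system integrator (drift, migration, mutation on Bernstein
   moments with a quadratic jackknife closure), Poisson composite-likelihood
   fitting with multi-start Nelder-Mead, and conversion of diffusion-unit
   estimates to years and individuals through
   `theta = 4 N_ref mu_gen L`, `T = 2 N_ref` generations,
   `M = 2 N_ref m`, with `mu = 2.3e-9` per site per year and a 2-year
   generation time as defaults.
3. **`glacialsplit.climate`** — temperature rate of change over 1000-year
   intervals, `ROC_t = (T_t - T_{t-1}) / T_{t-1} x 100`, loess-style
   smoothing (span 0.05), quantile-based rapid-episode detection, and
   circular-shift permutation tests for the overlap between split-time
   intervals and episodes.
4. **`glacialsplit.sdm`** — occurrence thinning (one record per 50 km
   cell), random background sampling, cross-evaluated learners gated at
   TSS >= 0.8 into a median ensemble, MESS extrapolation surfaces, and
   range-area series with collapse detection across paleoclimate time
   slices.

A fifth module, **`glacialsplit.synth`**, simulates every input with known
ground truth (msprime coalescent genotypes, GATK-style read likelihoods,
AR(1) climate series with engineered jump events, autocorrelated landscapes
with a known logistic niche), so the full chain runs and is verified
offline. `docs/methods.md` describes the models and numerical choices.

## Worked example

Simulate a two-population split, estimate the SFS from genotype
likelihoods, fit the demographic model, and date the split:

```python
from glacialsplit.demog import (UnitSystem, estimate_L, fit_model,
                                summarize_split_times)
from glacialsplit.synth import SimDemography, simulate_coalescent

MU, GEN, N_REF = 2.3e-9, 2.0, 200_000
truth = SimDemography(n_pops=2, nu_anc=1.0, t_anc=0.05, t_split=0.025,
                      m12=1.0, m21=1.0, N_ref=N_REF)
theta_site = 4 * N_REF * MU * GEN          # one coherent mutation-rate chain
table, sfs = simulate_coalescent(truth, (12, 12), 1_000_000, theta_site, seed=4)

fit = fit_model(sfs, "two_pop_sizechange_split_mig", n_starts=8, seed=5,
                maxiter=1500)
units = UnitSystem(mu_site_year=MU, generation_years=GEN,
                   L=estimate_L(1_000_000, sfs.total(), sfs.total()))
summary = summarize_split_times(fit, units)
print(summary["median_kya"], summary["q25_kya"], summary["q75_kya"])
```

This is `examples/02_demographic_fit.py`, which prints:

```
simulated 14279 segregating sites; true split 20 kya
best composite log-likelihood -478.1; t_split = 0.0631 (diffusion units), theta-hat = 1600.6
split time: median 23.9 kya, IQR 20.7-657.5 kya across 8 optimization runs
```

The median and 25-75% quartiles are across multi-start optimization runs —
the fitted median lands near the 20 kya truth, while the wide upper
quartile reflects runs trapped in distant modes of the composite-likelihood
surface, which is exactly why split times are reported as across-run
medians with quartile bands rather than single optima. The other scripts in
`examples/` walk through the remaining capabilities (coalescent + SFS,
climate episodes, SDM ensemble + range collapse, full pipeline) and print
what each number means.

The same chain runs from the shell:

```bash
glacialsplit run --seed 1 --out runs/demo          # full synthetic pipeline
glacialsplit afs sfs --beagle gl.beagle --pops pops.tsv --out obs.fs
glacialsplit fit --fs obs.fs --mu 2.3e-9 --gen-years 2 --L 4.47e6 \
    --n-starts 50 --seed 1 --out fit.json
glacialsplit climate roc --csv epica.csv --interval 1000 --out roc.csv
```

Each run writes a `manifest.json` echoing the fully resolved configuration;
re-running an unchanged configuration reuses cached stage outputs, and the
manifest alone reproduces a run bit-identically.

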