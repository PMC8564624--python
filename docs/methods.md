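# Methods

`glacialsplit` implements an inference chain for dating population splits in
a structured species and relating them to rapid climate change: (1) maximum-
likelihood allele frequencies and joint site-frequency spectra (SFS) from
genotype likelihoods, (2) composite-likelihood fitting of
split-with-migration demographic models with conversion to calendar years
through a direct mutation-rate estimate, (3) rate-of-change statistics and
rapid-episode detection on paleotemperature series, and (4) a TSS-gated
species-distribution-model (SDM) ensemble projected across paleoclimate time
slices with MESS extrapolation surfaces. A synthetic-data layer generates
every input with known ground truth so each stage is testable offline.

## Allele frequencies and spectra from genotype likelihoods

Genotype calls are never made. For a biallelic site with per-individual
likelihoods GL(g) of the three diploid genotypes (Beagle text layout,
normalized so the per-individual maximum is 1; a flat triple means no data),
the population frequency f of the second allele maximizes

    l(f) = sum_i log sum_g GL_i(g) * C(2, g) f^g (1 - f)^(2 - g).

The maximizer is found by EM — the update is the mean posterior allele
dosage divided by 2 — with convergence at |delta f| < 1e-8 and an iteration
cap of 2000. Because the mixture likelihood can be multimodal for
pathological likelihood triples, EM runs from three spread starts (0.1,
0.5, 0.9) plus the argmax of a 41-point coarse likelihood scan and keeps
the best mode; each individual trace is non-decreasing.
Polymorphism is tested with LRT = 2(l(f-hat) - l(0)) against the
chi-square(1) upper tail. The null lies on the parameter boundary, so the
full chi-square tail (the convention of the standard GL-based tools) is
conservative; the test suite verifies super-uniform null p-values.

Site filters follow the pipeline's reference settings: coverage in at least a
fraction 2/3 of individuals (ceil-scaled to the cohort rather than
hard-coded to 60/90), polymorphism p below 1e-6, and minor-allele frequency
strictly above 0.05, applied in that order with per-rule attrition counts.
Region masks are BED intervals (0-based, half-open); a 1-based site is
removed on any 1-bp overlap. One practical caveat the pipeline encodes: at
desk-scale sample sizes the 0.05 MAF threshold exceeds the singleton
frequency (1/2N), so feeding the MAF-filtered set into the SFS deletes the
rare-variant cells and pushes the demographic fit toward a spurious
bottleneck. The pipeline therefore builds spectra from the coverage +
p-value set by default and uses the MAF-filtered set only as the reported
variable-site list; `sfs_use_maf_filter` flips this.

Joint spectra over 1-3 populations are built by posterior-expectation
binning (per site and population, the rounded sum of posterior dosages
under that population's ML frequency) or, optionally, a joint EM over
spectrum cells using exact per-population allele-count likelihoods computed
by polynomial convolution of the genotype-likelihood triples. The two modes
agree on high-depth data; binning is faster and slightly biased at low
depth. Absorbing corners are always masked. Folding merges each cell with
its allele-label complement onto the canonical half-lattice (smaller total
derived count; lexicographic tie-break), is idempotent and conserves the
site total.

## Expected spectra under split-with-migration models

The expected joint SFS is computed by a deterministic moment system. Entry
(i_1, ..., i_d) of the expected spectrum is a Bernstein moment
E[prod_a C(n_a, i_a) x_a^{i_a} (1 - x_a)^{n_a - i_a}] of the population
allele-frequency density. Applying the diffusion generator to this basis
gives exact linear dynamics for drift (a per-axis tridiagonal operator
scaled by 1/(2 nu)) and mutation (influx n_a theta / 2 at each singleton
entry, which makes the single-population equilibrium exactly theta/i).
Migration at scaled rate M_ab = 2 N_ref m_ab couples the receiving axis to
moments one sample larger on the source axis; these are closed with a
quadratic jackknife: each size-(n+1) entry is a three-point linear
functional of the size-n spectrum, exact whenever the underlying density is
locally quadratic. Population splits redistribute the spectrum exactly,
Phi2(i, j) = C(n1, i) C(n2, j) / C(n, i + j) * Phi1(i + j).

Each epoch has constant coefficients, so the state is propagated with the
matrix exponential of the affine-augmented operator — dense
scaling-and-squaring when the scaled norm is large (stiff epochs: small nu,
long durations), Krylov-free `expm_multiply` otherwise. Columns of the two
absorbing corners are zeroed so fixed and lost sites cannot leak back into
segregating entries through the closure. Closure error falls quickly with
sample size while hypergeometric projection is exact, so spectra are
integrated at `oversample` (default 4) extra haploids per population and
projected down; at (6, 6) with strong migration the default gives total-
variation error around 3e-3 against a high-precision coalescent mean, and
oversample=8 roughly 1e-3. Spectra are exactly linear in theta; tiny
negative ringing from the closure is clipped to zero before use.

Two model families are provided. `two_pop_sizechange_split_mig`: ancestral
size change nu_anc lasting t_anc, then a split into daughters nu1/nu2
exchanging migrants at M12/M21 for t_split. `three_pop_two_splits_mig`: the
same with two successive splits; the intermediate ancestor of populations 2
and 3 needs a size (nu23) and migration with population 1 (m1_23, m23_1)
that the headline parameter set does not pin down — they default to nu2,
m12 and m21 and are configurable. The default topology has population 1
splitting first, matching a history where the southern lineage diverged
long before the remaining pair separated.

## Fitting and unit conversion

Model fit uses a Poisson composite likelihood over unmasked cells with
theta profiled analytically (theta-hat = sum observed / sum expected at
theta = 1). Optimization is multi-start Nelder-Mead in log10 space for
sizes and times (bounds nu in [1e-3, 1e2], t in [1e-4, 10]) and linear
space for migration (M in [0, 20], so exact zero is reachable); random
starts are drawn from a moderate interior region (nu in [0.05, 5], t in
[5e-3, 1], M in [0, 5]) while the optimizer may walk to the full bounds.
The library default is 50 starts; the bundled demo uses 12. A run that
exhausts its iteration budget still ends at a usable point and is included
in summaries; only non-finite likelihoods disqualify a run. Split times are
summarized as the median and 25-75% interquartile range of converted
per-run optima (linear-interpolation quantiles), each run converted with
its own profiled theta. With tight convergence all runs can collapse onto
one optimum and the IQR degenerates to zero width — the across-run scatter
is an optimization-uncertainty summary, not a confidence interval.

Real units use theta = 4 N_ref mu_gen L with mu_gen the per-site
per-generation rate: the headline chain multiplies a direct mutation-rate
estimate of 2.3e-9 per site per year by a two-year generation time. Times
convert as t * 2 N_ref * g years and migration as M / (2 N_ref) per
generation; conversions invert to machine precision. The effective length
is L = L_unfiltered * (segregating sites after filtering) / (segregating
sites before filtering). Mixing per-year and per-generation rates silently
would shift every date by the generation time, so the chain is explicit
everywhere, including the simulator: the demo derives its theta per site
from the same mu and N_ref it later uses for conversion.

## Climate rate of change and episode linkage

Temperature series (age BP, degrees C) are resampled to a 1000-year lattice
(nearest sample by default, linear interpolation optionally), then
converted to a percent rate of change ROC_t = (T_t - T_{t-1}) / T_{t-1} *
100 with the previous, older sample as the lag. On anomaly series the
denominator crosses zero; lags with magnitude below a guard (default 0.1
degrees C) yield NaN rather than silently exploding, and an
absolute-difference mode (degrees per interval) is the labeled alternative.
Smoothing is a loess-style local linear regression with tricube weights
over the ceil(span * n) nearest neighbours (span default 0.05); constants
and straight lines are reproduced exactly, and equivalence with any
particular statistics package is not claimed beyond tolerance tests.

"Rapid" is operationalized as |ROC| above a quantile (default 0.90) of the
finite |ROC| values; runs of flagged samples separated by at most
`merge_gap` sub-threshold samples merge into episodes whose edges extend
half a step. The overlap between a split-time interval (for example the
fitted IQR) and the episode set is the covered fraction of the interval;
its null distribution comes from uniform circular shifts of the episode
mask along the time axis, p being the fraction of shifts with at least the
observed coverage. The suite verifies the null is super-uniform.

## SDM ensemble, MESS and range collapse

Occurrences are thinned to one record per 50 x 50 km cell (seeded shuffle,
first-in-cell); background points are a uniform sample of masked-cell
centers without replacement. Two transparent learners implement the
ensemble contract: an L2-penalized logistic regression on standardized
linear + squared terms of the four climate variables, and a per-variable
percentile-distance envelope (1 at the presence median, 0 at or beyond the
presence range, aggregated by the minimum). Members are cross-evaluated by
random 70/30 calibration/validation splits repeated twice; skill is the
maximum over a 101-point threshold grid of sensitivity + specificity - 1
(max-TSS), and final members are refit on all occurrences. The ensemble is
the cell-wise median over members with TSS >= 0.8 (configurable gate); no
passing member is an explicit failure, never a silent fallback. Binary
range maps threshold the ensemble at the mean of passing members' max-TSS
thresholds; range area is the suitable-cell count, with cells treated as
equal-area at fixture scale (no spherical weighting — a documented
limitation).

MESS follows the canonical percentile formula per variable (with f the
percentage of reference values strictly below the point value: 2f for f <=
50, 2(100 - f) above, linear negative extensions beyond the reference
range) and takes the minimum across variables; the reference sample is the
variable values at presence cells. Degenerate references (max = min) score
0 at the reference value and negative linearly away from it, with a
warning. Range collapses are slices whose area falls below half the series
median (configurable), merged across adjacent slices.

## Synthetic data: what it emulates and what it does not

The coalescent generator wraps msprime behind the same demographic
parameterization as the inference models (times in 2 N_ref generations,
sizes as ratios, migration as 2 N_ref m) and is the engine's independent
oracle. Sequence data are independent non-recombining loci of RAD-like
length (default 150 bp) under a binary mutation model; multi-hit sites are
dropped. Genotype likelihoods are simulated from the same independent-read
model the estimator inverts: Poisson depth (default 20), per-read error
(default 0.01) to one of the three other bases uniformly, GATK-style
per-read mixture likelihoods. The climate generator superimposes linear-
ramp jump events on a piecewise-linear baseline with AR(1) noise
(marginal-sd parameterization). Landscapes are Gaussian-smoothed white
noise standardized per variable, with a logistic niche whose default
coefficients (-24, 14, 7, -9, -5) give a sharp-boundary species occupying
roughly 5-10% of the domain — chosen so that presence data carry
discrimination comparable to a well-sampled breeding-range atlas, with
uniform background sampling capping achievable TSS near one minus the
suitable fraction. Time slices add a small uniform drift per variable
(sd 0.05); crash slices shift the strongest-coefficient variable by 6 sd
against its niche sign.

None of the generators emulate RAD allele dropout, PCR duplicates,
reference bias, recombination within loci, selection, ice-core chronology
error, or spatially biased occurrence sampling; passing tests therefore
demonstrate correctness of the inference machinery under its own model
assumptions, not robustness to these real-data pathologies.

## Desk-scale problem sizes and numerical choices

The bundled demo and the verification suite run at desk scale, chosen as
the package's own defaults: spectra up to (12, 12) haploids (engine
contract: at most 40 per population), 1-5 Mb of simulated sequence (tens of
thousands of segregating sites), 8-12 optimizer starts, 1e5 coalescent
replicates for oracle comparisons, 60 x 80 landscape grids, and 1000-trial
permutation calibrations. Deterministic seeding flows from one global seed
through a CRC-based per-stage hash; identical configurations reuse cached
stage outputs keyed by a configuration hash, and a manifest echoing the
fully resolved configuration reproduces a run bit-identically.
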