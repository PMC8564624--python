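"""Simulate a two-population split and build the joint SFS from genotype likelihoods.

Shows the first pipeline stage: coalescent genotypes with known truth, a
read-sampling model producing Beagle-style genotype likelihoods, EM
allele-frequency estimation, the standard site-filter chain, and the folded
joint spectrum that feeds demographic inference.
"""

import numpy as np

from glacialsplit.afs import apply_site_filters, build_joint_sfs, estimate_all
from glacialsplit.synth import (
    ReadModel,
    SimDemography,
    simulate_coalescent,
    simulate_genotype_likelihoods,
)

truth = SimDemography(n_pops=2, nu_anc=1.0, t_anc=0.1, t_split=0.1,
                      m12=1.0, m21=1.0, N_ref=10_000)
table, true_sfs = simulate_coalescent(
    truth, sample_sizes=(8, 8), n_sites=200_000, theta_per_site=0.01, seed=1
)
print(f"simulated {table.genotypes.shape[0]} segregating sites "
      f"for {len(table.individuals)} diploid individuals in two demes")

glm = simulate_genotype_likelihoods(table, ReadModel(mean_depth=20.0,
                                                     error_rate=0.01, seed=2))
est = estimate_all(glm)
retained, attrition = apply_site_filters(est, glm.n_individuals)
print(f"site filters (coverage 2/3, p<1e-6, MAF>0.05): kept {len(retained)} "
      f"of {len(est)}; removed per rule: {attrition}")

fs = build_joint_sfs(glm, ["p1", "p2"], folded=True)
tv = 0.5 * np.abs(
    np.where(fs.mask, 0, fs.data) / fs.total()
    - np.where(true_sfs.fold().mask, 0, true_sfs.fold().data) / true_sfs.fold().total()
).sum()
print(f"folded joint SFS: {int(fs.total())} sites; total-variation distance "
      f"to the simulator's exact tabulation = {tv:.4f}")
print("(small TV means GL-based estimation recovers the spectrum without "
      "ever calling genotypes)")
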