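"""Run the full synthetic pipeline end to end and read the run manifest.

simulate -> genotype likelihoods -> filters + SFS -> demographic fit ->
climate rate-of-change + episode overlap -> SDM ensemble + range collapse,
all from one seed, with cached stages and a manifest that reproduces the
run bit-identically. Equivalent shell command:
``glacialsplit run --seed 7 --out runs/demo``.
"""

import json
from pathlib import Path

from glacialsplit.pipeline import run_pipeline

outdir = Path("runs/demo")
cfg = {
    "simulate": {"n_sites": 150_000, "sample_sizes": [8, 8]},
    "fit": {"n_starts": 6, "maxiter": 1200},
    "climate": {"step": 500.0},
}
run = run_pipeline(cfg, outdir, global_seed=7)

split = json.loads((run / "fit" / "split_times.json").read_text())
print(f"fitted split time: median {split['split_time']['median_kya']:.1f} kya "
      f"(IQR {split['split_time']['q25_kya']:.1f}-"
      f"{split['split_time']['q75_kya']:.1f})")
print(f"effective sequence length L = {split['L_bp']:.3g} bp; "
      f"N_ref = {split['best_real_units']['N_ref']:.3g} individuals")

overlap = json.loads((run / "climate" / "overlap.json").read_text())
print(f"climate: {overlap['n_episodes']} rapid-change episodes; "
      f"split-interval overlap: {overlap.get('overlap')}")

collapse = json.loads((run / "sdm" / "collapse.json").read_text())
print(f"SDM range collapse detected in slices: {collapse['collapse_slices']} "
      f"(engineered at [5, 6])")
print(f"manifest: {run / 'manifest.json'} — rerunning with the same "
      f"configuration reuses cached stages and reproduces outputs byte-for-byte")
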