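"""End-to-end orchestration: config validation, seeding, caching, manifest.

A run executes stages in dependency order on a single output directory:

    simulate -> afs -> fit -> climate -> sdm

Defaults carry the analysis settings the pipeline is built around (coverage 2/3 of
individuals, polymorphism p < 1e-6, MAF > 0.05, mu = 2.3e-9 per site per
year, 2-year generations, 1000-year ROC interval, smoothing span 0.05, TSS
gate 0.8, 70/30 evaluation split repeated twice) on synthetic inputs with
known truth. The global seed fans out to per-stage seeds through a CRC-based
hash of the stage name, so stages are independently reproducible; per-stage
overrides are allowed via ``<stage>.seed``.

Each stage writes its outputs plus a ``stage_manifest.json`` keyed by the
hash of its resolved configuration (and its upstream hashes); re-running
with an unchanged configuration reuses the cached outputs. The run manifest
echoes the fully resolved configuration and the package version, which
together reproduce the run bit-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from glacialsplit import __version__
from glacialsplit import afs as afs_mod
from glacialsplit import climate as climate_mod
from glacialsplit import sdm as sdm_mod
from glacialsplit.demog import (
    UnitSystem,
    convert_units,
    estimate_L,
    fit_model,
    summarize_split_times,
)
from glacialsplit.spectrum import FrequencySpectrum
from glacialsplit.synth import (
    ClimateSimSpec,
    LandscapeSimSpec,
    ReadModel,
    SimDemography,
    simulate_climate,
    simulate_coalescent,
    simulate_genotype_likelihoods,
    simulate_time_slices,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Unknown key, wrong type or inconsistent pipeline configuration."""


STAGES = ("simulate", "afs", "fit", "climate", "sdm")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": list(STAGES),
    "simulate": {
        "seed": None,
        "n_pops": 2,
        "sample_sizes": [12, 12],
        "n_sites": 300_000,
        # None: theta per site is derived from mu_site_year * generation_years
        # and N_ref, so simulated data and the real-unit conversion chain share
        # one mutation-rate assumption
        "theta_per_site": None,
        "mu_site_year": 2.3e-9,
        "generation_years": 2.0,
        "N_ref": 200_000.0,
        "nu_anc": 1.0,
        "t_anc": 0.05,
        "nu1": 1.0,
        "nu2": 1.0,
        "nu3": 1.0,
        "t_split": 0.025,
        "t_split2": 0.0,
        "m12": 1.0,
        "m21": 1.0,
        "m13": 0.0,
        "m31": 0.0,
        "m23": 0.0,
        "m32": 0.0,
        "locus_length": 150,
        "mean_depth": 20.0,
        "error_rate": 0.01,
    },
    "afs": {
        "seed": None,
        "min_ind_frac": 2.0 / 3.0,
        "p_max": 1.0e-6,
        "maf_min": 0.05,
        "folded": True,
        "sfs_mode": "posterior",
        # the MAF filter defines the reported variable-site list; feeding it
        # into the SFS would delete the rare-variant cells the demographic
        # model needs, so the spectrum uses the coverage + p-value set unless
        # this is flipped
        "sfs_use_maf_filter": False,
        "bed_mask": None,
    },
    "fit": {
        "seed": None,
        "model": "two_pop_sizechange_split_mig",
        # the library default is 50 starts; the demo configuration uses 12 so
        # the full synthetic run stays within a coffee break on one CPU
        "n_starts": 12,
        "oversample": 4,
        "maxiter": None,
        "mu_site_year": 2.3e-9,
        "generation_years": 2.0,
    },
    "climate": {
        "seed": None,
        "duration": 120_000.0,
        "step": 200.0,
        "baseline": [[120_000.0, -44.0], [20_000.0, -48.0], [0.0, -40.0]],
        "events": [[105_000.0, 8.0, 1000.0], [90_000.0, -6.0, 1000.0],
                   [15_000.0, 10.0, 1000.0]],
        "ar1_coeff": 0.6,
        "noise_sd": 0.4,
        "interval": 1000.0,
        "span": 0.05,
        "roc_mode": "percent",
        "eps_guard": 0.1,
        "quantile_threshold": 0.90,
        "merge_gap": 1,
        "n_permutations": 1000,
        "split_interval_kya": None,
    },
    "sdm": {
        "seed": None,
        "grid_shape": [60, 80],
        "spatial_corr_length": 5.0,
        "n_presence": 400,
        "n_background": 1000,
        "n_slices": 10,
        "crash_slices": [5, 6],
        "crash_shift": 6.0,
        "gate": 0.8,
        "split": 0.70,
        "repeats": 2,
        "learners": ["logistic_quadratic", "range_envelope"],
        "drop_frac": 0.5,
    },
}


def _check_keys(user: dict, defaults: dict, path: str = "") -> None:
    for key, val in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            _check_keys(val, defaults[key], f"{path}{key}.")


def resolve_config(user: dict | None) -> dict:
    """Merge a user configuration over the defaults; unknown keys are rejected."""
    user = user or {}
    if not isinstance(user, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(user, DEFAULT_CONFIG)
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in user.items():
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    return cfg


def stage_seed(global_seed: int, stage: str, override: int | None = None) -> int:
    """Per-stage seed: SeedSequence(global_seed, crc32(stage)), < 2**31."""
    if override is not None:
        return int(override)
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _cached(stage_dir: Path, key: str) -> bool:
    mpath = stage_dir / "stage_manifest.json"
    if not mpath.exists():
        return False
    try:
        return json.loads(mpath.read_text()).get("key") == key
    except json.JSONDecodeError:
        return False


def _write_stage_manifest(stage_dir: Path, key: str, seed: int, elapsed: float) -> None:
    (stage_dir / "stage_manifest.json").write_text(
        json.dumps({"key": key, "seed": seed, "elapsed_s": round(elapsed, 3)},
                   indent=2, sort_keys=True)
    )


# ------------------------------------------------------------------- stages
def _run_simulate(cfg: dict, seed: int, out: Path) -> None:
    c = cfg["simulate"]
    sim = SimDemography(
        n_pops=c["n_pops"], N_ref=c["N_ref"], nu_anc=c["nu_anc"], t_anc=c["t_anc"],
        nu1=c["nu1"], nu2=c["nu2"], nu3=c["nu3"], t_split=c["t_split"],
        t_split2=c["t_split2"], m12=c["m12"], m21=c["m21"], m13=c["m13"],
        m31=c["m31"], m23=c["m23"], m32=c["m32"],
    )
    theta_site = c["theta_per_site"]
    if theta_site is None:
        theta_site = 4.0 * c["N_ref"] * c["mu_site_year"] * c["generation_years"]
    table, true_sfs = simulate_coalescent(
        sim, tuple(c["sample_sizes"]), c["n_sites"], theta_site,
        seed=seed, locus_length=c["locus_length"],
    )
    glm = simulate_genotype_likelihoods(
        table, ReadModel(c["mean_depth"], c["error_rate"], seed=seed + 1)
    )
    glm.write_beagle(out / "genotype_likelihoods.beagle",
                     populations_path=out / "populations.tsv")
    table.to_tsv(out / "genotypes.tsv")
    true_sfs.to_file(out / "true.fs")
    table.sites.assign(
        count=table.genotypes.sum(axis=1)
    ).to_csv(out / "true_sites.tsv", sep="\t", index=False)


def _run_afs(cfg: dict, seed: int, out: Path, updir: Path) -> None:
    c = cfg["afs"]
    glm = afs_mod.GenotypeLikelihoodMatrix.read_beagle(
        updir / "genotype_likelihoods.beagle", populations=updir / "populations.tsv"
    )
    if c["bed_mask"]:
        bed = afs_mod.read_bed(c["bed_mask"])
        keep = afs_mod.apply_region_mask(glm.sites, bed)
        glm = glm.subset_sites(np.flatnonzero(keep))
    estimates = afs_mod.estimate_all(glm)
    estimates.to_csv(out / "site_estimates.tsv", sep="\t", index=False)
    retained, attrition = afs_mod.apply_site_filters(
        estimates, glm.n_individuals,
        min_ind_frac=c["min_ind_frac"], p_max=c["p_max"], maf_min=c["maf_min"],
    )
    (out / "attrition.json").write_text(json.dumps(
        {"input_sites": len(estimates), "retained": len(retained),
         "attrition": attrition}, indent=2, sort_keys=True))
    if c["sfs_use_maf_filter"]:
        sfs_sites = retained
    else:
        sfs_sites, _ = afs_mod.apply_site_filters(
            estimates, glm.n_individuals,
            min_ind_frac=c["min_ind_frac"], p_max=c["p_max"], maf_min=0.0,
        )
    (out / "sfs_site_count.json").write_text(
        json.dumps({"sfs_sites": len(sfs_sites)})
    )
    key = pd.MultiIndex.from_frame(glm.sites[["chrom", "pos"]])
    keep_idx = np.flatnonzero(
        key.isin(pd.MultiIndex.from_frame(sfs_sites[["chrom", "pos"]]))
    )
    filtered = glm.subset_sites(keep_idx)
    pops = list(dict.fromkeys(filtered.populations))
    fs = afs_mod.build_joint_sfs(
        filtered, pops, folded=c["folded"], mode=c["sfs_mode"]
    )
    fs.to_file(out / "observed.fs")


def _run_fit(cfg: dict, seed: int, out: Path, updir: Path, simdir: Path) -> None:
    c = cfg["fit"]
    fs = FrequencySpectrum.from_file(updir / "observed.fs")
    fit = fit_model(
        fs, c["model"], n_starts=c["n_starts"], seed=seed,
        oversample=c["oversample"], maxiter=c["maxiter"],
    )
    attr = json.loads((updir / "attrition.json").read_text())
    sfs_n = json.loads((updir / "sfs_site_count.json").read_text())["sfs_sites"]
    L = estimate_L(cfg["simulate"]["n_sites"], sfs_n, attr["input_sites"])
    units = UnitSystem(c["mu_site_year"], c["generation_years"], L)
    split_summary = summarize_split_times(fit, units)
    best_real = convert_units(fit.best.params, fit.best.theta, units)
    fit.to_json(out / "fit.json")
    pd.DataFrame([r.params | {"loglik": r.loglik, "theta": r.theta,
                              "converged": r.converged} for r in fit.runs]).to_csv(
        out / "runs.tsv", sep="\t", index=False)
    (out / "split_times.json").write_text(json.dumps(
        {"L_bp": L, "mu_site_year": c["mu_site_year"],
         "generation_years": c["generation_years"],
         "split_time": split_summary, "best_real_units": best_real},
        indent=2, sort_keys=True))


def _run_climate(cfg: dict, seed: int, out: Path, fitdir: Path | None) -> None:
    c = cfg["climate"]
    spec = ClimateSimSpec(
        duration=c["duration"], step=c["step"],
        baseline=[tuple(k) for k in c["baseline"]]
        if isinstance(c["baseline"], list) else c["baseline"],
        events=[tuple(e) for e in c["events"]],
        ar1_coeff=c["ar1_coeff"], noise_sd=c["noise_sd"], seed=seed,
    )
    series = simulate_climate(spec)
    series.to_csv(out / "climate.csv")
    res = climate_mod.resample_series(series, interval=c["interval"])
    roc = climate_mod.rate_of_change(res, eps_guard=c["eps_guard"],
                                     mode=c["roc_mode"])
    pd.DataFrame({"age_bp": roc.age_bp, roc.label: roc.temp}).to_csv(
        out / "roc.csv", index=False)
    smooth = climate_mod.smooth_series(series, span=c["span"])
    smooth.to_csv(out / "smoothed.csv")
    episodes = climate_mod.detect_episodes(
        roc, quantile_threshold=c["quantile_threshold"], merge_gap=c["merge_gap"]
    )
    episodes.to_tsv(out / "episodes.tsv")
    interval_kya = c["split_interval_kya"]
    if interval_kya is None and fitdir is not None and (
        fitdir / "split_times.json"
    ).exists():
        split = json.loads((fitdir / "split_times.json").read_text())["split_time"]
        interval_kya = [split["q25_kya"], split["q75_kya"]]
    result = {"threshold": episodes.threshold,
              "n_episodes": len(episodes.intervals)}
    if interval_kya is not None:
        lo, hi = sorted(1000.0 * v for v in interval_kya)
        lo_c = max(lo, episodes.axis_span[0])
        hi_c = min(hi, episodes.axis_span[1])
        if hi_c <= lo_c:
            result["overlap"] = None
            result["note"] = "split interval outside climate span"
        else:
            overlap, p = climate_mod.interval_episode_overlap(
                (lo_c, hi_c), episodes,
                n_permutations=c["n_permutations"], seed=seed + 1,
            )
            result["overlap"] = {"interval_bp": [lo_c, hi_c],
                                 "fraction": overlap, "p_value": p}
    (out / "overlap.json").write_text(json.dumps(result, indent=2, sort_keys=True))


def _run_sdm(cfg: dict, seed: int, out: Path) -> None:
    c = cfg["sdm"]
    spec = LandscapeSimSpec(
        grid_shape=tuple(c["grid_shape"]),
        spatial_corr_length=c["spatial_corr_length"],
        n_presence=c["n_presence"], n_background=c["n_background"], seed=seed,
    )
    stacks, occ, truth = simulate_time_slices(
        spec, n_slices=c["n_slices"],
        crash_slices=tuple(c["crash_slices"]), crash_shift=c["crash_shift"],
    )
    training = stacks[0]
    members = []
    for k, kind in enumerate(c["learners"]):
        members.append(sdm_mod.evaluate_and_finalize(
            kind, occ, training, split=c["split"], repeats=c["repeats"],
            seed=seed + 10 + k,
        ))
    ensemble = sdm_mod.build_ensemble(members, gate=c["gate"])
    reference = training.extract(occ.presence[:, 0], occ.presence[:, 1])
    proj = sdm_mod.project_time_slices(ensemble, stacks, mess_reference=reference)
    collapses = sdm_mod.detect_range_collapse(proj.areas, drop_frac=c["drop_frac"])
    pd.DataFrame({
        "time_bp": proj.times_bp, "area_cells": proj.areas.astype(int),
        "extrapolated_fraction": [s.mess.extrapolated_fraction()
                                  for s in proj.slices],
    }).to_csv(out / "areas.csv", index=False)
    proj.slices[0].suitability.to_text(out / "suitability_slice0.txt")
    (out / "ensemble.json").write_text(json.dumps({
        "members": [{"kind": m.kind, "tss": m.tss, "threshold": m.threshold}
                    for m in members],
        "gate": c["gate"],
        "passing": [m.kind for m in ensemble.passing],
        "binary_threshold": ensemble.threshold,
    }, indent=2, sort_keys=True))
    (out / "collapse.json").write_text(json.dumps(
        {"collapse_slices": [list(iv) for iv in collapses]},
        indent=2, sort_keys=True))


def run_pipeline(config: dict | None, outdir, global_seed: int | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    Cached stage outputs (matching configuration hash) are reused. Any stage
    failure propagates after the manifest records the error.
    """
    cfg = resolve_config(config)
    if global_seed is not None:
        cfg["seed"] = int(global_seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg, "stages": {}}
    upstream_key = ""
    stage_dirs = {s: outdir / s for s in STAGES}
    try:
        for stage in STAGES:
            if stage not in cfg["stages"]:
                continue
            seed = stage_seed(cfg["seed"], stage, cfg[stage].get("seed"))
            key = _hash({"stage": stage, "cfg": cfg[stage], "seed": seed,
                         "upstream": upstream_key})
            sdir = stage_dirs[stage]
            sdir.mkdir(exist_ok=True)
            if _cached(sdir, key):
                logger.info("stage %s: cached (%s)", stage, key)
            else:
                t0 = time.time()
                logger.info("stage %s: running (seed %d)", stage, seed)
                if stage == "simulate":
                    _run_simulate(cfg, seed, sdir)
                elif stage == "afs":
                    _run_afs(cfg, seed, sdir, stage_dirs["simulate"])
                elif stage == "fit":
                    _run_fit(cfg, seed, sdir, stage_dirs["afs"],
                             stage_dirs["simulate"])
                elif stage == "climate":
                    _run_climate(cfg, seed, sdir, stage_dirs["fit"])
                elif stage == "sdm":
                    _run_sdm(cfg, seed, sdir)
                _write_stage_manifest(sdir, key, seed, time.time() - t0)
            manifest["stages"][stage] = {"key": key, "seed": seed}
            upstream_key = key
    finally:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return outdir


def load_config_file(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}
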