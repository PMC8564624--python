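"""Coalescent simulation of split-with-migration histories (msprime-backed).

The simulator is the independent oracle for the deterministic expected-SFS
engine: it draws genealogies under the same piecewise-constant
size-change + split(s) + continuous-migration histories, in the same
diffusion units (times in 2*N_ref generations, sizes as ratios of N_ref,
migration as M = 2*N_ref*m), and tabulates exact joint allele counts.

Sequence data are generated as independent non-recombining loci of RAD-like
length (default 150 bp) under an infinite-sites-style binary mutation model;
sites are biallelic with the ancestral state known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from glacialsplit.spectrum import FrequencySpectrum


@dataclass
class SimDemography:
    """Ground-truth demography for 1-3 populations.

    Sizes are ratios of ``N_ref``; times are in units of 2*N_ref generations
    before present; migration rates are scaled, ``M = 2*N_ref*m``, oriented
    forward in time (``m12`` = fraction of population 1 replaced by migrants
    from population 2 per generation, times 2*N_ref).
    """

    n_pops: int = 2
    nu_anc: float = 1.0
    t_anc: float = 0.0
    nu1: float = 1.0
    nu2: float = 1.0
    nu3: float = 1.0
    t_split: float = 0.1
    t_split2: float = 0.0
    m12: float = 0.0
    m21: float = 0.0
    m13: float = 0.0
    m31: float = 0.0
    m23: float = 0.0
    m32: float = 0.0
    nu23: float | None = None
    m1_23: float | None = None
    m23_1: float | None = None
    N_ref: float = 1.0e4

    def __post_init__(self) -> None:
        if self.n_pops not in (1, 2, 3):
            raise ValueError("n_pops must be 1, 2 or 3")
        for name in ("nu_anc", "nu1", "nu2", "nu3", "N_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("t_anc", "t_split", "t_split2",
                     "m12", "m21", "m13", "m31", "m23", "m32"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pops == 3 and self.t_split2 >= self.t_split:
            raise ValueError("split times must decrease toward the present")

    @classmethod
    def from_model(cls, model, N_ref: float = 1.0e4) -> "SimDemography":
        """Build from a :mod:`glacialsplit.demog` model instance."""
        kwargs = {p: getattr(model, p) for p in model.free_params}
        extra = {}
        for name in ("nu23", "m1_23", "m23_1"):
            if hasattr(model, name):
                extra[name] = getattr(model, name)
        return cls(n_pops=model.n_pops, N_ref=N_ref, **kwargs, **extra)

    @property
    def split_topology(self) -> list[dict]:
        """Ordered split events, oldest first (introspection/reporting)."""
        events = []
        if self.n_pops >= 2:
            events.append(
                {"time": self.t_split, "parent": "anc",
                 "children": ("p1", "p23" if self.n_pops == 3 else "p2")}
            )
        if self.n_pops == 3:
            events.append(
                {"time": self.t_split2, "parent": "p23", "children": ("p2", "p3")}
            )
        for a, b in zip(events, events[1:]):
            if not a["time"] > b["time"]:
                raise ValueError("split times must strictly decrease toward present")
        return events

    # ------------------------------------------------------------- msprime
    def to_msprime(self) -> msprime.Demography:
        N = self.N_ref
        two_n = 2.0 * N
        dem = msprime.Demography()
        if self.n_pops == 1:
            dem.add_population(name="p1", initial_size=self.nu_anc * N)
            if self.t_anc > 0:
                dem.add_population_parameters_change(
                    time=self.t_anc * two_n, population="p1", initial_size=N
                )
            return dem
        nu23 = self.nu23 if self.nu23 is not None else self.nu2
        m1_23 = self.m1_23 if self.m1_23 is not None else self.m12
        m23_1 = self.m23_1 if self.m23_1 is not None else self.m21

        dem.add_population(name="p1", initial_size=self.nu1 * N)
        dem.add_population(name="p2", initial_size=self.nu2 * N)
        if self.n_pops == 3:
            dem.add_population(name="p3", initial_size=self.nu3 * N)
            dem.add_population(name="p23", initial_size=nu23 * N)
        dem.add_population(name="anc", initial_size=self.nu_anc * N)

        # msprime's migration_matrix[a][b] is the backwards rate of lineages
        # moving a -> b, i.e. the forward rate of individuals b -> a, which is
        # exactly the diffusion convention for M_ab = 2*N_ref*m_ab.
        def mig(a: str, b: str, M: float) -> None:
            if M > 0:
                dem.set_migration_rate(a, b, M / two_n)

        if self.n_pops == 2:
            mig("p1", "p2", self.m12)
            mig("p2", "p1", self.m21)
            dem.add_population_split(
                time=self.t_split * two_n, derived=["p1", "p2"], ancestral="anc"
            )
        else:
            mig("p1", "p2", self.m12)
            mig("p2", "p1", self.m21)
            mig("p1", "p3", self.m13)
            mig("p3", "p1", self.m31)
            mig("p2", "p3", self.m23)
            mig("p3", "p2", self.m32)
            t2 = self.t_split2 * two_n
            dem.add_population_split(time=t2, derived=["p2", "p3"], ancestral="p23")
            for a, b, M in (("p1", "p23", m1_23), ("p23", "p1", m23_1)):
                dem.add_migration_rate_change(time=t2, source=a, dest=b, rate=M / two_n)
            dem.add_population_split(
                time=self.t_split * two_n, derived=["p1", "p23"], ancestral="anc"
            )
        if self.t_anc > 0:
            dem.add_population_parameters_change(
                time=(self.t_split + self.t_anc) * two_n,
                population="anc",
                initial_size=N,
            )
        dem.sort_events()
        return dem

    def pop_names(self) -> list[str]:
        return [f"p{k + 1}" for k in range(self.n_pops)]


@dataclass
class GenotypeTable:
    """Biallelic diploid genotypes (copies of the derived allele) per site."""

    sites: pd.DataFrame  # chrom, pos (1-based), allele1 (ancestral), allele2 (derived)
    genotypes: np.ndarray  # (n_sites, n_individuals) values 0/1/2
    individuals: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.individuals)):
            raise ValueError("genotype matrix shape mismatch")
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label per individual")

    def to_tsv(self, path) -> None:
        """Plain-text genotype table: site columns then one column per individual."""
        df = self.sites.copy()
        for k, ind in enumerate(self.individuals):
            df[f"{self.populations[k]}:{ind}"] = self.genotypes[:, k]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"allele1": str, "allele2": str})
        meta_cols = ["chrom", "pos", "allele1", "allele2"]
        ind_cols = [c for c in df.columns if c not in meta_cols]
        populations = [c.split(":", 1)[0] for c in ind_cols]
        individuals = [c.split(":", 1)[1] for c in ind_cols]
        return cls(df[meta_cols].copy(), df[ind_cols].to_numpy(dtype=np.int8),
                   individuals, populations)

    def derived_counts(self, pops: list[str] | None = None) -> np.ndarray:
        """(n_sites, n_pops) derived allele counts per population."""
        pops = pops or list(dict.fromkeys(self.populations))
        plab = np.array(self.populations)
        return np.stack(
            [self.genotypes[:, plab == p].sum(axis=1) for p in pops], axis=1
        )

    def true_sfs(self, pops: list[str] | None = None) -> FrequencySpectrum:
        """Exact joint tabulation of derived allele counts (unfolded)."""
        pops = pops or list(dict.fromkeys(self.populations))
        plab = np.array(self.populations)
        sizes = [2 * int((plab == p).sum()) for p in pops]
        counts = np.zeros([n + 1 for n in sizes])
        idx = self.derived_counts(pops)
        np.add.at(counts, tuple(idx.T), 1)
        return FrequencySpectrum(counts, folded=False, pop_ids=tuple(pops))


def _check_samples(sim: SimDemography, sample_sizes: tuple[int, ...]) -> dict:
    names = sim.pop_names()
    if len(sample_sizes) != sim.n_pops:
        raise ValueError(
            f"{sim.n_pops}-population demography needs {sim.n_pops} sample sizes"
        )
    for n in sample_sizes:
        if n < 2 or n % 2:
            raise ValueError("haploid sample sizes must be even and >= 2")
    return {name: n // 2 for name, n in zip(names, sample_sizes)}


def simulate_coalescent(
    sim: SimDemography,
    sample_sizes: tuple[int, ...],
    n_sites: int,
    theta_per_site: float,
    seed: int,
    locus_length: int = 150,
) -> tuple[GenotypeTable, FrequencySpectrum]:
    """Simulate biallelic genotypes at independent RAD-like loci.

    ``n_sites`` is the total simulated sequence length (bp), split into
    independent non-recombining loci of ``locus_length`` bp — most positions
    are monomorphic; only segregating sites are returned. ``theta_per_site``
    is 4*N_ref*mu per site. Returns the genotype table and the exact joint
    SFS tabulation of the realized variants.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if theta_per_site <= 0:
        raise ValueError("theta_per_site must be > 0")
    samples = _check_samples(sim, sample_sizes)
    mu = theta_per_site / (4.0 * sim.N_ref)
    n_loci = math.ceil(n_sites / locus_length)
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)

    individuals, populations = [], []
    for name, n_ind in samples.items():
        individuals += [f"{name}_i{k}" for k in range(n_ind)]
        populations += [name] * n_ind

    chroms, positions, geno_rows = [], [], []
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=sim.to_msprime(),
        sequence_length=locus_length,
        recombination_rate=0.0,
        ploidy=2,
        num_replicates=n_loci,
        random_seed=int(anc_seed),
    )
    mut_rng = np.random.default_rng(mut_seed)
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            model=msprime.BinaryMutationModel(),
            random_seed=int(mut_rng.integers(1, 2**31 - 1)),
        )
        if mts.num_sites == 0:
            continue
        gm = mts.genotype_matrix()  # (n_var, n_haplotypes), derived state = 1
        seg = (gm.sum(axis=1) > 0) & (gm.sum(axis=1) < gm.shape[1])
        if not seg.any():
            continue
        gm = gm[seg]
        pos = mts.tables.sites.position[seg].astype(int) + 1
        chroms += [f"locus{k}"] * len(pos)
        positions += pos.tolist()
        geno_rows.append(gm.reshape(gm.shape[0], -1, 2).sum(axis=2))
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "allele1": ["0"] * len(chroms),
            "allele2": ["1"] * len(chroms),
        }
    )
    geno = (
        np.concatenate(geno_rows, axis=0).astype(np.int8)
        if geno_rows
        else np.zeros((0, len(individuals)), dtype=np.int8)
    )
    table = GenotypeTable(sites, geno, individuals, populations)
    return table, table.true_sfs(list(samples))


def simulated_expected_sfs(
    sim: SimDemography,
    sample_sizes: tuple[int, ...],
    n_replicates: int,
    seed: int,
) -> tuple[FrequencySpectrum, np.ndarray]:
    """Monte-Carlo expected joint SFS from replicate genealogies (branch mode).

    Averages the branch-length allele-frequency spectrum over independent
    single-tree replicates; the expectation equals the expected SFS up to the
    overall mutation-rate scale. Returns the mean spectrum and the per-cell
    Monte-Carlo standard error of that mean.
    """
    samples = _check_samples(sim, sample_sizes)
    shape = tuple(n + 1 for n in sample_sizes)
    total = np.zeros(shape)
    total_sq = np.zeros(shape)
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=sim.to_msprime(),
        sequence_length=1,
        ploidy=2,
        num_replicates=n_replicates,
        random_seed=seed,
    )
    for ts in reps:
        afs = ts.allele_frequency_spectrum(
            sample_sets=[ts.samples(k) for k in range(sim.n_pops)],
            mode="branch",
            polarised=True,
            span_normalise=False,
        )
        total += afs
        total_sq += afs**2
    mean = total / n_replicates
    var = total_sq / n_replicates - mean**2
    se = np.sqrt(np.maximum(var, 0.0) / n_replicates)
    fs = FrequencySpectrum(mean, folded=False, pop_ids=tuple(samples))
    return fs, se
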