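"""Allele-frequency estimation from genotype likelihoods, site filters and SFS building.

Sites are never genotype-called: each analysis integrates over the three
diploid genotype likelihoods. The per-site minor-allele frequency maximizes

    l(f) = sum_i log sum_g GL_i(g) Binom(g; 2, f)

by EM (the update is the mean posterior allele dosage / 2), polymorphism is
tested by a likelihood-ratio statistic against the monomorphic boundary with
a chi-square(1 df) tail, and joint spectra are built either by per-site
posterior-expectation binning or by a joint EM over spectrum cells.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from glacialsplit.spectrum import FrequencySpectrum

logger = logging.getLogger(__name__)

FLAT_TOL = 1e-9


@dataclass
class GenotypeLikelihoodMatrix:
    """Per-site, per-individual likelihoods of the three diploid genotypes.

    ``likelihoods`` has shape (n_sites, n_individuals, 3) ordered as
    (homozygous allele1, heterozygous, homozygous allele2) and is normalized
    so the per-(site, individual) maximum is 1; an all-equal triple means no
    data for that individual at that site.
    """

    sites: pd.DataFrame  # columns: chrom, pos (1-based), allele1, allele2
    individuals: list[str]
    populations: list[str]  # population label per individual
    likelihoods: np.ndarray

    def __post_init__(self) -> None:
        req = {"chrom", "pos", "allele1", "allele2"}
        if not req.issubset(self.sites.columns):
            raise ValueError(f"sites frame needs columns {sorted(req)}")
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if self.likelihoods.shape != (len(self.sites), len(self.individuals), 3):
            raise ValueError("likelihood array shape mismatch")
        if np.any(self.likelihoods < 0):
            raise ValueError("negative genotype likelihood")
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label per individual required")
        self.normalize()

    def normalize(self) -> None:
        mx = self.likelihoods.max(axis=2, keepdims=True)
        mx[mx == 0] = 1.0
        self.likelihoods = self.likelihoods / mx

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def missing(self) -> np.ndarray:
        """Boolean (n_sites, n_individuals): flat likelihood triple = no data."""
        return np.ptp(self.likelihoods, axis=2) < FLAT_TOL

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.array([k for k, p in enumerate(self.populations) if p == pop])
        if idx.size == 0:
            raise ValueError(f"no individuals in population {pop!r}")
        return idx

    def subset_sites(self, keep: np.ndarray) -> "GenotypeLikelihoodMatrix":
        return GenotypeLikelihoodMatrix(
            self.sites.iloc[keep].reset_index(drop=True),
            list(self.individuals),
            list(self.populations),
            self.likelihoods[keep],
        )

    # ------------------------------------------------------------------- I/O
    def write_beagle(self, path, populations_path=None) -> None:
        """Beagle GL text: marker, allele1, allele2, three columns per individual."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            header = ["marker", "allele1", "allele2"]
            for ind in self.individuals:
                header += [ind] * 3
            fh.write("\t".join(header) + "\n")
            for s in range(self.n_sites):
                row = self.sites.iloc[s]
                fields = [
                    f"{row.chrom}_{row.pos}",
                    str(row.allele1),
                    str(row.allele2),
                ]
                fields += [f"{v:.6g}" for v in self.likelihoods[s].ravel()]
                fh.write("\t".join(fields) + "\n")
        if populations_path is not None:
            pd.DataFrame(
                {"individual": self.individuals, "population": self.populations}
            ).to_csv(populations_path, sep="\t", index=False)

    @classmethod
    def read_beagle(cls, path, populations=None) -> "GenotypeLikelihoodMatrix":
        """Read Beagle GL text (gzip allowed).

        ``populations`` maps individual id -> population label (or a path to
        a two-column TSV); unlisted individuals get population 'pop0'.
        """
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            inds = header[3::3]
            markers, a1, a2, gls = [], [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3 + 3 * len(inds):
                    raise ValueError(f"malformed beagle row for marker {parts[0]}")
                markers.append(parts[0])
                a1.append(parts[1])
                a2.append(parts[2])
                gls.append([float(v) for v in parts[3:]])
        chrom = [m.rsplit("_", 1)[0] for m in markers]
        pos = [int(m.rsplit("_", 1)[1]) for m in markers]
        sites = pd.DataFrame({"chrom": chrom, "pos": pos, "allele1": a1, "allele2": a2})
        lik = np.array(gls).reshape(len(markers), len(inds), 3)
        if isinstance(populations, (str, bytes)) or hasattr(populations, "read_text"):
            pmap = pd.read_csv(populations, sep="\t").set_index("individual")[
                "population"
            ].to_dict()
        else:
            pmap = dict(populations or {})
        pops = [pmap.get(i, "pop0") for i in inds]
        return cls(sites, inds, pops, lik)


# ----------------------------------------------------------------- estimation
@dataclass
class SiteEstimate:
    f_hat: float  # minor-allele frequency in [0, 0.5]
    f_alt: float  # frequency of allele2 in [0, 1]
    lrt: float
    p_value: float
    n_informative: int
    major: str
    minor: str
    converged: bool


def _site_loglik(gls: np.ndarray, f: np.ndarray) -> np.ndarray:
    """log L(f) for informative GL triples, vectorized over an array of f."""
    f = np.atleast_1d(np.asarray(f, dtype=float))
    prior = np.stack(
        [(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1
    )  # (..., 3)
    mix = gls[:, None, :] * prior[None, :, :]
    return np.log(np.maximum(mix.sum(axis=2), 1e-300)).sum(axis=0)


def estimate_maf(
    site_gls: np.ndarray,
    alleles: tuple[str, str] = ("0", "1"),
    tol: float = 1e-8,
    max_iter: int = 2000,
    return_trace: bool = False,
):
    """ML minor-allele frequency from one site's genotype-likelihood triples.

    EM update: ``f <- mean posterior dosage / 2``; converged when the change
    in f drops below ``tol`` (default 1e-8). The iteration cap (2000) is
    generous because EM approaches boundary optima (f near 0 or 1)
    geometrically slowly, and each iteration is a handful of flops. Individuals with a flat triple are uninformative and are
    excluded. Returns a :class:`SiteEstimate` (optionally with the
    log-likelihood trace, which is non-decreasing).
    """
    gls = np.asarray(site_gls, dtype=float)
    if gls.ndim != 2 or gls.shape[1] != 3:
        raise ValueError("site_gls must be (n_individuals, 3)")
    mx = gls.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    gls = gls / mx
    informative = np.ptp(gls, axis=1) >= FLAT_TOL
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError("all individuals missing: site unestimable")
    g = gls[informative]

    def em(f0: float):
        f = f0
        tr = []
        conv = False
        for _ in range(max_iter):
            prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
            post = g * prior
            denom = post.sum(axis=1, keepdims=True)
            denom[denom == 0] = 1e-300
            post = post / denom
            tr.append(float(_site_loglik(g, f)[0]))
            f_new = float((post * np.array([0.0, 1.0, 2.0])).sum() / (2 * len(g)))
            if abs(f_new - f) < tol:
                f = f_new
                conv = True
                break
            f = f_new
        tr.append(float(_site_loglik(g, f)[0]))
        return f, tr, conv

    # the mixture likelihood can be multimodal for adversarial GL triples;
    # EM is a local ascent, so seed it from three spread starts plus the
    # argmax of a coarse likelihood scan, and keep the best mode (each trace
    # is individually non-decreasing)
    coarse = np.linspace(0.005, 0.995, 41)
    f_coarse = float(coarse[int(np.argmax(_site_loglik(g, coarse)))])
    f, trace, converged = em(0.1)
    for f0 in (0.5, 0.9, f_coarse):
        f_alt2, tr2, conv2 = em(f0)
        if tr2[-1] > trace[-1] + 1e-12:
            f, trace, converged = f_alt2, tr2, conv2

    ll_hat = trace[-1]
    # polymorphism test against the monomorphic-major boundary
    if f <= 0.5:
        ll_null = float(np.log(np.maximum(g[:, 0], 1e-300)).sum())
        major, minor = alleles
        f_minor = f
    else:
        ll_null = float(np.log(np.maximum(g[:, 2], 1e-300)).sum())
        major, minor = alleles[1], alleles[0]
        f_minor = 1.0 - f
    if f == 0.5:
        major, minor = sorted(alleles)
        logger.info("exact f=0.5 tie; major/minor set lexicographically: %s/%s",
                    major, minor)
    lrt = max(0.0, 2.0 * (ll_hat - ll_null))
    p = 1.0 if lrt == 0 else float(chi2.sf(lrt, df=1))
    est = SiteEstimate(
        f_hat=f_minor, f_alt=f, lrt=lrt, p_value=p,
        n_informative=n_inf, major=major, minor=minor, converged=converged,
    )
    return (est, trace) if return_trace else est


def polymorphism_test(site_gls: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi-square(1) p-value for f > 0.

    The null frequency sits on the parameter boundary; using the full
    chi-square(1) tail (rather than the half-mixture) is conservative.
    """
    est = estimate_maf(site_gls)
    return est.lrt, est.p_value


def infer_major_minor(site_gls: np.ndarray, alleles: tuple[str, str] = ("0", "1")):
    """Major/minor allele labels from genotype likelihoods (higher f = major)."""
    est = estimate_maf(site_gls, alleles=alleles)
    return est.major, est.minor


def estimate_all(glm: GenotypeLikelihoodMatrix) -> pd.DataFrame:
    """Per-site estimates table (chrom, pos, major, minor, f_hat, lrt, p, n_ind)."""
    rows = []
    for s in range(glm.n_sites):
        site = glm.sites.iloc[s]
        try:
            est = estimate_maf(
                glm.likelihoods[s], alleles=(str(site.allele1), str(site.allele2))
            )
        except ValueError:
            rows.append((site.chrom, site.pos, site.allele1, site.allele2,
                         np.nan, np.nan, np.nan, 0))
            continue
        rows.append((site.chrom, site.pos, est.major, est.minor, est.f_hat,
                     est.lrt, est.p_value, est.n_informative))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "major", "minor", "f_hat", "lrt", "p", "n_ind"]
    )


# -------------------------------------------------------------------- filters
def read_bed(path) -> pd.DataFrame:
    """Parse BED (0-based half-open); malformed lines raise with line number."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{ln}: BED end < start")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def apply_region_mask(sites: pd.DataFrame, bed: pd.DataFrame) -> np.ndarray:
    """Boolean keep-vector: a site is removed iff its single base overlaps a mask interval.

    Sites are 1-based positions; BED intervals are 0-based half-open, so
    1-based position p overlaps [start, end) iff start <= p - 1 < end.
    """
    keep = np.ones(len(sites), dtype=bool)
    if len(bed) == 0:
        return keep
    for chrom, sub in bed.groupby("chrom"):
        iv = sub.sort_values("start")[["start", "end"]].to_numpy()
        # merge overlapping intervals
        merged = []
        for s_, e_ in iv:
            if merged and s_ <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e_)
            else:
                merged.append([s_, e_])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        on_chrom = sites["chrom"].to_numpy() == chrom
        pos0 = sites.loc[on_chrom, "pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        hit = (j >= 0) & (pos0 < ends[np.clip(j, 0, None)])
        keep[np.flatnonzero(on_chrom)[hit]] = False
    return keep


def apply_site_filters(
    estimates: pd.DataFrame,
    n_total: int,
    min_ind_frac: float = 2.0 / 3.0,
    p_max: float = 1e-6,
    maf_min: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Coverage, polymorphism-p and MAF filters with per-rule attrition counts.

    Applied in order: (1) informative individuals >= ceil(min_ind_frac * N);
    (2) p < p_max; (3) f_hat > maf_min (strict, 'above'). The attrition dict
    counts removals by the first rule each site fails.
    """
    min_ind = math.ceil(min_ind_frac * n_total)
    cov_ok = estimates["n_ind"] >= min_ind
    p_ok = estimates["p"] < p_max
    maf_ok = estimates["f_hat"] > maf_min
    attrition = {
        "coverage": int((~cov_ok).sum()),
        "p_value": int((cov_ok & ~p_ok).sum()),
        "maf": int((cov_ok & p_ok & ~maf_ok).sum()),
    }
    retained = estimates[cov_ok & p_ok & maf_ok].reset_index(drop=True)
    assert len(retained) + sum(attrition.values()) == len(estimates)
    return retained, attrition


# ------------------------------------------------------------- SFS construction
def _pop_count_likelihoods(gls: np.ndarray) -> np.ndarray:
    """P(data | j derived copies among 2N chromosomes) up to a constant.

    Polynomial convolution of per-individual genotype terms
    ``GL(g) * C(2, g) z^g``, normalized by C(2N, j): the probability of the
    data given j derived alleles assigned exchangeably to the 2N chromosomes.
    """
    n_ind = gls.shape[0]
    poly = np.array([1.0])
    for i in range(n_ind):
        term = np.array([gls[i, 0], 2.0 * gls[i, 1], gls[i, 2]])
        poly = np.convolve(poly, term)
    j = np.arange(2 * n_ind + 1)
    from scipy.special import comb

    denom = comb(2 * n_ind, j)
    out = poly / denom
    tot = out.sum()
    return out / tot if tot > 0 else np.full_like(out, 1.0 / len(out))


def build_joint_sfs(
    glm: GenotypeLikelihoodMatrix,
    pops: list[str],
    folded: bool = False,
    mode: str = "posterior",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> FrequencySpectrum:
    """Joint SFS over 1-3 populations from genotype likelihoods.

    ``posterior`` (default): per site and population, allele counts are the
    rounded sum of posterior genotype expectations under that population's
    ML frequency — fast, slightly biased at low depth. ``joint_em``: an EM
    over spectrum cells using exact per-population allele-count likelihoods;
    both modes agree on high-depth data. Corners are masked; folding merges
    complementary cells onto the canonical half.
    """
    if not 1 <= len(pops) <= 3:
        raise ValueError("1-3 populations supported")
    idxs = [glm.pop_indices(p) for p in pops]
    shape = tuple(2 * len(ix) + 1 for ix in idxs)
    missing = glm.missing()
    for ax, (p, ix) in enumerate(zip(pops, idxs)):
        frac_empty = (missing[:, ix].all(axis=1)).mean()
        if frac_empty > 0.5:
            logger.warning(
                "population %s has zero informative individuals at %.0f%% of sites",
                p, 100 * frac_empty,
            )

    if mode == "posterior":
        counts = np.zeros(shape)
        dosage_vec = np.array([0.0, 1.0, 2.0])
        for s in range(glm.n_sites):
            cell = []
            for ix in idxs:
                g = glm.likelihoods[s, ix]
                try:
                    est = estimate_maf(g)
                    f = est.f_alt
                except ValueError:
                    f = 0.0
                prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
                post = g * prior
                denom = post.sum(axis=1, keepdims=True)
                denom[denom == 0] = 1.0
                post = post / denom
                cell.append(int(round(float((post @ dosage_vec).sum()))))
            counts[tuple(cell)] += 1
    elif mode == "joint_em":
        n_sites = glm.n_sites
        cell_lik = np.ones((n_sites,) + shape)
        for s in range(n_sites):
            per_pop = [_pop_count_likelihoods(glm.likelihoods[s, ix]) for ix in idxs]
            outer = per_pop[0]
            for arr in per_pop[1:]:
                outer = np.multiply.outer(outer, arr)
            cell_lik[s] = outer
        flat = cell_lik.reshape(n_sites, -1)
        p_cell = np.full(flat.shape[1], 1.0 / flat.shape[1])
        for _ in range(max_iter):
            w = flat * p_cell
            w /= np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
            p_new = w.mean(axis=0)
            if np.abs(p_new - p_cell).max() < tol:
                p_cell = p_new
                break
            p_cell = p_new
        counts = (p_cell * n_sites).reshape(shape)
    else:
        raise ValueError(f"unknown SFS mode {mode!r}")

    fs = FrequencySpectrum(counts, folded=False, pop_ids=tuple(pops))
    if folded:
        fs = fs.fold()
    return fs
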