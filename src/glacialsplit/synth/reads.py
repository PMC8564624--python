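"""Forward simulation of genotype likelihoods under an independent-read model.

This simulates the model the estimator inverts: per site and individual the
read depth is Poisson, each read reports the true base with probability
1 - epsilon and one of the three other bases uniformly otherwise, and the
likelihood of each diploid genotype is the product over reads of
``0.5 * P(base | allele_a) + 0.5 * P(base | allele_b)`` (GATK-style GL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glacialsplit.afs import GenotypeLikelihoodMatrix
from glacialsplit.synth.coalescent import GenotypeTable


@dataclass(frozen=True)
class ReadModel:
    """Poisson depth + uniform base-error sequencing model."""

    mean_depth: float = 20.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


def read_base_prob(base_is_allele: bool, epsilon: float) -> float:
    """P(read base | true allele): 1 - eps on match, eps/3 per mismatch base."""
    return 1.0 - epsilon if base_is_allele else epsilon / 3.0


def genotype_log_likelihoods(
    n_a1: np.ndarray, n_a2: np.ndarray, n_other: np.ndarray, epsilon: float
) -> np.ndarray:
    """Log GL of (hom-a1, het, hom-a2) from per-base read counts (vectorized).

    Reads matching neither site allele contribute the same factor eps/3 to
    every genotype and cancel after normalization; they are included for
    completeness.
    """
    e3 = epsilon / 3.0
    p_match = 1.0 - epsilon
    # P(read = a1 | genotype), P(read = a2 | genotype)
    probs = np.array(
        [
            [p_match, e3],
            [0.5 * (p_match + e3), 0.5 * (p_match + e3)],
            [e3, p_match],
        ]
    )
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
        log_other = np.log(e3) if epsilon > 0 else -np.inf
    def xlogy(n, logv):
        # 0 reads contribute 0 even when the per-read log-prob is -inf
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, n * logv, 0.0)

    out = np.empty(n_a1.shape + (3,))
    for g in range(3):
        term = xlogy(n_a1, logp[g, 0]) + xlogy(n_a2, logp[g, 1])
        term = term + xlogy(n_other, log_other)
        out[..., g] = term
    return out


def simulate_genotype_likelihoods(
    table: GenotypeTable, read_model: ReadModel
) -> GenotypeLikelihoodMatrix:
    """Sample reads over a genotype table and emit normalized GL triples.

    Zero-depth (site, individual) pairs get a flat triple (missing data).
    Deterministic under the read model's seed.
    """
    rng = np.random.default_rng(read_model.seed)
    g = table.genotypes.astype(np.int64)  # (S, I) copies of allele2
    eps = read_model.error_rate
    depth = rng.poisson(read_model.mean_depth, size=g.shape)
    # reads whose true template base is allele2
    m2 = rng.binomial(depth, g / 2.0)
    m1 = depth - m2
    # sequencing errors: each read flips to one of the 3 other bases uniformly
    correct1 = rng.binomial(m1, 1.0 - eps)
    correct2 = rng.binomial(m2, 1.0 - eps)
    err1 = m1 - correct1
    err2 = m2 - correct2
    err1_to_2 = rng.binomial(err1, 1.0 / 3.0)
    err2_to_1 = rng.binomial(err2, 1.0 / 3.0)
    n_a1 = correct1 + err2_to_1
    n_a2 = correct2 + err1_to_2
    n_other = (err1 - err1_to_2) + (err2 - err2_to_1)

    loggl = genotype_log_likelihoods(n_a1, n_a2, n_other, eps)
    # the true genotype always has finite log-likelihood, so the max is finite
    rel = loggl - loggl.max(axis=2, keepdims=True)
    gl = np.where(np.isfinite(rel), np.exp(np.clip(rel, -745.0, 0.0)), 0.0)
    flat = depth == 0
    gl[flat] = 1.0
    return GenotypeLikelihoodMatrix(
        table.sites.copy(), list(table.individuals), list(table.populations), gl
    )
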