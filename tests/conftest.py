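"""Shared fixtures: small genotype-likelihood and landscape test objects."""

import numpy as np
import pytest

from glacialsplit.synth import (
    LandscapeSimSpec,
    ReadModel,
    SimDemography,
    simulate_coalescent,
    simulate_genotype_likelihoods,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210)


@pytest.fixture(scope="session")
def small_glm():
    """GL matrix for a small 2-population sample at moderate depth."""
    sim = SimDemography(n_pops=2, t_split=0.1, m12=1.0, m21=1.0)
    table, true_sfs = simulate_coalescent(
        sim, (8, 8), 40_000, theta_per_site=0.01, seed=11
    )
    glm = simulate_genotype_likelihoods(
        table, ReadModel(mean_depth=20.0, error_rate=0.01, seed=12)
    )
    return glm, table, true_sfs


@pytest.fixture(scope="session")
def landscape():
    from glacialsplit.synth import simulate_landscape

    return simulate_landscape(LandscapeSimSpec(seed=7))
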