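"""EM allele-frequency estimation, polymorphism test, filters, SFS building."""

import numpy as np
import pandas as pd
import pytest

from glacialsplit import afs
from glacialsplit.afs import (
    GenotypeLikelihoodMatrix,
    apply_region_mask,
    apply_site_filters,
    build_joint_sfs,
    estimate_maf,
    infer_major_minor,
    polymorphism_test,
    read_bed,
)


def grid_search_f(gls, step=1e-5):
    """Independent oracle: exhaustive likelihood scan over f in [0, 1]."""
    gls = np.asarray(gls, dtype=float)
    mx = gls.max(axis=1, keepdims=True)
    gls = gls / np.where(mx == 0, 1, mx)
    keep = np.ptp(gls, axis=1) >= 1e-9
    gls = gls[keep]
    f = np.arange(0.0, 1.0 + step, step)
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)  # (F, 3)
    ll = np.zeros(len(f))
    for row in gls:
        ll += np.log(np.maximum(prior @ row, 1e-300))
    return f[np.argmax(ll)], ll.max()


def test_certain_homozygous_major_gives_zero_frequency():
    gls = np.tile([1.0, 0.0, 0.0], (10, 1))
    est = estimate_maf(gls)
    assert est.f_hat == pytest.approx(0.0, abs=1e-6)
    lrt, p = polymorphism_test(gls)
    assert lrt == pytest.approx(0.0, abs=1e-9)
    assert p == 1.0


def test_all_heterozygous_gives_half():
    gls = np.tile([0.0, 1.0, 0.0], (12, 1))
    est = estimate_maf(gls)
    assert est.f_hat == pytest.approx(0.5, abs=1e-6)


def test_em_matches_grid_search_on_the_two_individual_fixture():
    gls = np.array([[0.9, 0.1, 0.0], [0.2, 0.7, 0.1]])
    est = estimate_maf(gls)
    f_star, ll_star = grid_search_f(gls)
    assert abs(est.f_alt - f_star) < 1e-4
    # LRT equals twice the gap to the monomorphic boundary, by direct evaluation
    ll0 = np.log(0.9 / 0.9) + np.log(0.2 / 0.7)
    assert est.lrt == pytest.approx(2 * (ll_star - ll0), abs=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_em_matches_grid_search_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        n = rng.integers(2, 12)
        gls = rng.dirichlet(np.ones(3) * 0.4, size=n)
        est = estimate_maf(gls)
        f_star, _ = grid_search_f(gls, step=1e-5)
        assert abs(est.f_alt - f_star) < 1e-4


def test_em_loglik_is_monotone():
    rng = np.random.default_rng(3)
    for _ in range(25):
        gls = rng.dirichlet(np.ones(3), size=int(rng.integers(2, 15)))
        _, trace = estimate_maf(gls, return_trace=True)
        diffs = np.diff(trace)
        assert np.all(diffs > -1e-10)


def test_overwhelming_evidence_passes_polymorphism_filter():
    gls = np.tile([0.0, 1.0, 0.0], (90, 1))
    _, p = polymorphism_test(gls)
    assert p < 1e-6


def test_null_sites_are_conservative(small_glm):
    """Fraction of monomorphic sites with p < alpha stays at or below alpha."""
    rng = np.random.default_rng(4)
    n_sites, n_ind = 2000, 20
    # truth: f = 0 everywhere; shallow depth 4, 1% errors
    from glacialsplit.synth.coalescent import GenotypeTable
    from glacialsplit.synth.reads import ReadModel, simulate_genotype_likelihoods

    table = GenotypeTable(
        pd.DataFrame({"chrom": "c", "pos": np.arange(1, n_sites + 1),
                      "allele1": "0", "allele2": "1"}),
        np.zeros((n_sites, n_ind), dtype=np.int8),
        [f"i{k}" for k in range(n_ind)], ["p1"] * n_ind,
    )
    glm = simulate_genotype_likelihoods(table, ReadModel(4.0, 0.01, seed=5))
    ps = afs.estimate_all(glm)["p"].to_numpy()
    for alpha in (0.05, 1e-3):
        assert (ps < alpha).mean() <= alpha + 3 * np.sqrt(alpha / n_sites)


def test_major_minor_inference_and_swap():
    low = np.tile([0.5, 1.0, 0.1], (20, 1))  # f_alt < 0.5
    est = estimate_maf(low, alleles=("A", "C"))
    assert (est.major, est.minor) == ("A", "C")
    high = np.tile([0.1, 1.0, 0.5], (20, 1))  # mirrored: f_alt > 0.5
    est2 = estimate_maf(high, alleles=("A", "C"))
    assert (est2.major, est2.minor) == ("C", "A")
    assert est2.f_hat == pytest.approx(est.f_hat, abs=1e-6)
    assert est2.f_hat <= 0.5


def test_all_missing_site_is_unestimable():
    with pytest.raises(ValueError, match="unestimable"):
        estimate_maf(np.ones((5, 3)))


# ------------------------------------------------------------------ BED mask
def test_region_mask_coordinate_conventions(tmp_path):
    bed = tmp_path / "mask.bed"
    bed.write_text("chr1\t99\t100\nchr1\t100\t200\n")
    intervals = read_bed(bed)
    sites = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "pos": [99, 100, 150],
         "allele1": "0", "allele2": "1"}
    )
    keep = apply_region_mask(sites, intervals)
    # pos 100 hits [99,100) (its 0-based coordinate is 99); pos 150 hits
    # [100,200); pos 99 (0-based 98) precedes both intervals
    assert list(keep) == [True, False, False]


def test_empty_mask_keeps_everything():
    sites = pd.DataFrame({"chrom": ["c"], "pos": [5], "allele1": "0",
                          "allele2": "1"})
    keep = apply_region_mask(sites, pd.DataFrame(columns=["chrom", "start", "end"]))
    assert keep.all()


def test_malformed_bed_reports_line_number(tmp_path):
    bed = tmp_path / "bad.bed"
    bed.write_text("chr1\t0\t10\nchr1\toops\t20\n")
    with pytest.raises(ValueError, match="bad.bed:2"):
        read_bed(bed)


# ------------------------------------------------------------------- filters
def filter_fixture():
    """Six sites: exactly 2 fail coverage, 1 fails p, 1 fails MAF, 2 survive."""
    return pd.DataFrame(
        {
            "chrom": ["c"] * 6,
            "pos": range(1, 7),
            "major": "0", "minor": "1",
            "f_hat": [0.30, 0.20, 0.10, 0.25, 0.05, 0.40],
            "lrt": [50.0] * 6,
            "p": [1e-9, 1e-9, 1e-9, 1e-3, 1e-9, 1e-9],
            "n_ind": [59, 30, 90, 88, 75, 60],
        }
    )


def test_six_site_filter_fixture_attrition():
    retained, attrition = apply_site_filters(
        filter_fixture(), n_total=90,
        min_ind_frac=2.0 / 3.0, p_max=1e-6, maf_min=0.05,
    )
    assert len(retained) == 2
    assert attrition == {"coverage": 2, "p_value": 1, "maf": 1}
    assert list(retained["pos"]) == [3, 6]


def test_coverage_boundary_59_of_90_dropped():
    est = filter_fixture().iloc[[0]]  # n_ind = 59
    retained, attrition = apply_site_filters(est, n_total=90)
    assert len(retained) == 0 and attrition["coverage"] == 1


def test_maf_boundary_is_strict():
    est = filter_fixture().iloc[[4]]  # f_hat = 0.05 exactly
    retained, attrition = apply_site_filters(est, n_total=90)
    assert len(retained) == 0 and attrition["maf"] == 1


def test_attrition_counts_sum_to_input(small_glm):
    glm, table, _ = small_glm
    est = afs.estimate_all(glm)
    retained, attrition = apply_site_filters(est, glm.n_individuals)
    assert len(retained) + sum(attrition.values()) == len(est)


# --------------------------------------------------------------------- SFS
def test_sfs_exact_at_high_depth_and_modes_agree():
    from glacialsplit.synth import (
        ReadModel,
        SimDemography,
        simulate_coalescent,
        simulate_genotype_likelihoods,
    )

    sim = SimDemography(n_pops=2, t_split=0.1, m12=1.0, m21=1.0)
    table, true_sfs = simulate_coalescent(sim, (4, 4), 15_000, 0.01, seed=21)
    glm = simulate_genotype_likelihoods(table, ReadModel(40.0, 0.0, seed=22))
    fs_post = build_joint_sfs(glm, ["p1", "p2"], mode="posterior")
    assert np.allclose(fs_post.data, true_sfs.data)
    fs_em = build_joint_sfs(glm, ["p1", "p2"], mode="joint_em")
    keep = ~fs_post.mask
    assert np.abs(fs_em.data[keep] - fs_post.data[keep]).max() < 0.5


def test_sfs_close_to_truth_at_moderate_depth(small_glm):
    glm, table, true_sfs = small_glm
    fs = build_joint_sfs(glm, ["p1", "p2"], mode="posterior")
    a = np.where(fs.mask, 0, fs.data)
    b = np.where(true_sfs.mask, 0, true_sfs.data)
    tv = 0.5 * np.abs(a / a.sum() - b / b.sum()).sum()
    assert tv < 0.02


def test_folded_sfs_conserves_sites(small_glm):
    glm, *_ = small_glm
    unfolded = build_joint_sfs(glm, ["p1", "p2"], folded=False)
    folded = build_joint_sfs(glm, ["p1", "p2"], folded=True)
    assert folded.total() == pytest.approx(unfolded.total())


def test_beagle_round_trip(tmp_path, small_glm):
    glm, *_ = small_glm
    sub = glm.subset_sites(np.arange(50))
    path = tmp_path / "gl.beagle.gz"
    sub.write_beagle(path, populations_path=tmp_path / "pops.tsv")
    back = GenotypeLikelihoodMatrix.read_beagle(path, populations=tmp_path / "pops.tsv")
    assert back.individuals == sub.individuals
    assert back.populations == sub.populations
    assert np.allclose(back.likelihoods, sub.likelihoods, atol=1e-5)
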