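"""Rate-of-change chain: resampling, ROC, smoothing, episodes, overlap."""

import numpy as np
import pytest

from glacialsplit.climate import (
    ClimateSeries,
    detect_episodes,
    interval_episode_overlap,
    rate_of_change,
    resample_series,
    smooth_series,
)
from glacialsplit.synth import ClimateSimSpec, simulate_climate


# ------------------------------------------------------------------ resample
def test_resample_identity_on_lattice():
    ages = np.arange(50_000, -1, -1000.0)
    s = ClimateSeries(ages, np.sin(ages / 7000.0))
    r = resample_series(s, 1000.0)
    assert np.array_equal(r.age_bp, ages)
    assert np.array_equal(r.temp, s.temp)


def test_resample_picks_every_tenth_sample():
    ages = np.arange(20_000, -1, -100.0)
    temp = np.arange(len(ages), dtype=float)
    r = resample_series(ClimateSeries(ages, temp), 1000.0)
    assert np.array_equal(r.age_bp, np.arange(20_000, -1, -1000.0))
    assert np.array_equal(r.temp, temp[::10])


def test_resample_linear_interpolation_matches_hand_values():
    s = ClimateSeries([3800.0, 2500.0, 1400.0, 200.0], [4.0, 2.0, 1.0, 5.0])
    r = resample_series(s, 1000.0, mode="linear")
    assert np.array_equal(r.age_bp, [3000.0, 2000.0, 1000.0])
    hand = [
        2.0 + (4.0 - 2.0) * (3000 - 2500) / (3800 - 2500),
        1.0 + (2.0 - 1.0) * (2000 - 1400) / (2500 - 1400),
        5.0 + (1.0 - 5.0) * (1000 - 200) / (1400 - 200),
    ]
    assert np.allclose(r.temp, hand)


def test_resample_requires_two_intervals():
    with pytest.raises(ValueError):
        resample_series(ClimateSeries([900.0, 100.0], [1.0, 2.0]), 1000.0)


# ----------------------------------------------------------------------- ROC
def test_roc_of_constant_series_is_zero():
    s = ClimateSeries(np.arange(10_000, -1, -1000.0), np.full(11, 7.5))
    roc = rate_of_change(s)
    assert np.allclose(roc.temp, 0.0)


def test_roc_of_ten_to_eleven_is_ten_percent():
    s = ClimateSeries([1000.0, 0.0], [10.0, 11.0])
    roc = rate_of_change(s)
    assert roc.temp[0] == pytest.approx(10.0)
    assert roc.age_bp[0] == 0.0  # value attaches to the younger sample


def test_roc_guards_small_denominators():
    s = ClimateSeries([2000.0, 1000.0, 0.0], [5.0, 0.0, 3.0])
    roc = rate_of_change(s, eps_guard=0.1)
    assert np.isfinite(roc.temp[0])
    assert np.isnan(roc.temp[1])  # lag value 0 flagged, not propagated


def test_roc_scale_free_in_percent_mode():
    ages = np.arange(9000, -1, -1000.0)
    temp = np.linspace(4.0, 9.0, 10)
    a = rate_of_change(ClimateSeries(ages, temp)).temp
    b = rate_of_change(ClimateSeries(ages, 3.0 * temp)).temp
    assert np.allclose(a, b)


# ------------------------------------------------------------------ smoothing
def test_smoothing_reproduces_linear_series_exactly():
    ages = np.arange(100_000, -1, -500.0)
    temp = -3.0 + ages * 2e-5
    out = smooth_series(ClimateSeries(ages, temp), span=0.05)
    assert np.max(np.abs(out.temp - temp)) < 1e-10


def test_smoothing_constant_series_is_constant():
    ages = np.arange(20_000, -1, -1000.0)
    out = smooth_series(ClimateSeries(ages, np.full(len(ages), 2.0)), span=0.3)
    assert np.allclose(out.temp, 2.0)


def naive_local_linear(x, y, span):
    """Independent per-point weighted-least-squares oracle."""
    import math

    n = len(x)
    k = max(3, math.ceil(span * n))
    out = np.empty(n)
    for j in range(n):
        d = np.abs(x - x[j])
        nbr = np.sort(np.argsort(d, kind="stable")[:k])
        h = np.abs(x[nbr] - x[j]).max()
        if h == 0:
            out[j] = y[nbr].mean()
            continue
        w = np.clip(1 - (np.abs(x[nbr] - x[j]) / h) ** 3, 0, None) ** 3
        if np.count_nonzero(w) < 2:
            w = np.ones_like(w)
        coeffs = np.polyfit(x[nbr] - x[j], y[nbr], 1, w=np.sqrt(w))
        out[j] = coeffs[1]
    return out


def test_smoothing_matches_independent_wls_oracle():
    rng = np.random.default_rng(6)
    ages = np.arange(60_000, -1, -500.0)
    temp = np.sin(ages / 5000.0) + rng.normal(0, 0.3, len(ages))
    s = ClimateSeries(ages, temp)
    ours = smooth_series(s, span=0.05).temp
    # oracle runs on the past-to-present ordering the smoother uses
    ss = s.sorted_past_to_present()
    theirs = naive_local_linear(ss.age_bp, ss.temp, 0.05)
    rms = np.sqrt(np.mean((ours - theirs) ** 2))
    assert rms < 1e-6


def test_smoothing_near_statsmodels_lowess():
    """Loose cross-check against an established lowess implementation."""
    import statsmodels.api as sm

    rng = np.random.default_rng(8)
    ages = np.arange(40_000, -1, -500.0)
    temp = np.cos(ages / 6000.0) + rng.normal(0, 0.2, len(ages))
    ours = smooth_series(ClimateSeries(ages, temp), span=0.1).temp
    ref = sm.nonparametric.lowess(
        temp[::-1], ages[::-1], frac=0.1, it=0, return_sorted=False
    )[::-1]
    # interior agreement (window conventions differ slightly at the edges)
    inner = slice(10, -10)
    assert np.sqrt(np.mean((ours[inner] - ref[inner]) ** 2)) < 0.02


def test_smoothing_requires_enough_points():
    with pytest.raises(ValueError):
        smooth_series(ClimateSeries([3000.0, 2000, 1000, 0], np.ones(4)), 0.05)


# ------------------------------------------------------------------ episodes
def test_single_spike_yields_single_one_step_episode():
    ages = np.arange(20_000, -1, -1000.0)
    roc = np.zeros(len(ages))
    roc[7] = 50.0
    eps = detect_episodes(ClimateSeries(ages, roc, label="roc_pct"), 0.90)
    assert len(eps.intervals) == 1
    start, end = eps.intervals[0]
    assert start - end == pytest.approx(1000.0)
    assert start > ages[7] > end


def test_two_spikes_merge_across_one_gap():
    ages = np.arange(20_000, -1, -1000.0)
    roc = np.zeros(len(ages))
    roc[5] = 40.0
    roc[7] = 45.0  # one sub-threshold step between
    eps = detect_episodes(ClimateSeries(ages, roc, label="roc"), 0.90, merge_gap=1)
    assert len(eps.intervals) == 1
    eps2 = detect_episodes(ClimateSeries(ages, roc, label="roc"), 0.90, merge_gap=0)
    assert len(eps2.intervals) == 2


def test_injected_events_recovered_within_one_step():
    """Three engineered jumps produce episodes at their onsets, 5/5 seeds."""
    onsets = (90_000.0, 55_000.0, 20_000.0)
    for seed in range(5):
        spec = ClimateSimSpec(
            duration=120_000, step=1000,
            events=[(o, 14.0, 1000.0) for o in onsets],
            ar1_coeff=0.6, noise_sd=0.4, seed=seed,
        )
        series = simulate_climate(spec)
        roc = rate_of_change(series, mode="absolute")
        eps = detect_episodes(roc, quantile_threshold=0.97)
        for onset in onsets:
            hit = any(
                start + 1000.0 >= onset >= end - 1000.0
                for start, end in eps.intervals
            )
            assert hit, f"seed {seed}: onset {onset} missed: {eps.intervals}"


def test_episode_intervals_disjoint_and_bounded(rng):
    ages = np.arange(100_000, -1, -1000.0)
    roc = rng.normal(0, 1, len(ages))
    eps = detect_episodes(ClimateSeries(ages, roc, label="roc"), 0.8, merge_gap=2)
    ordered = sorted(eps.intervals, reverse=True)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        assert e1 > s2  # no overlap after merging
    assert eps.total_width() <= ages.max() - ages.min() + 1000.0


# ------------------------------------------------------------------- overlap
def _episodes_fixture():
    ages = np.arange(100_000, -1, -1000.0)
    roc = np.zeros(len(ages))
    roc[20:30] = 10.0
    return detect_episodes(ClimateSeries(ages, roc, label="roc"), 0.80)


def test_interval_fully_inside_episode_has_overlap_one():
    eps = _episodes_fixture()
    (start, end), = eps.intervals
    obs, p = interval_episode_overlap((end + 1000, start - 1000), eps, 200, seed=1)
    assert obs == pytest.approx(1.0)


def test_no_episodes_gives_zero_overlap_p_one():
    ages = np.arange(50_000, -1, -1000.0)
    roc = np.zeros(len(ages))
    eps = detect_episodes(ClimateSeries(ages, roc, label="roc"), 0.90)
    assert eps.intervals == []
    obs, p = interval_episode_overlap((10_000.0, 20_000.0), eps, 100, seed=0)
    assert obs == 0.0 and p == 1.0


def test_null_mean_overlap_matches_episode_coverage():
    """Random circular shifts cover the interval in proportion to episode mass."""
    eps = _episodes_fixture()
    frac_covered = eps.total_width() / (eps.axis_span[1] - eps.axis_span[0])
    rng = np.random.default_rng(2)
    overlaps = []
    for _ in range(300):
        lo = rng.uniform(5_000, 80_000)
        obs, _ = interval_episode_overlap((lo, lo + 5_000), eps, 1, seed=int(rng.integers(1e6)))
        overlaps.append(obs)
    # the average observed overlap over random intervals ~ episode coverage
    se = np.std(overlaps, ddof=1) / np.sqrt(len(overlaps))
    assert abs(np.mean(overlaps) - frac_covered) < 4 * se + 0.02


def test_permutation_pvalues_superuniform_under_null():
    """P(p <= alpha) <= alpha (within MC error) when the interval is random."""
    eps = _episodes_fixture()
    rng = np.random.default_rng(3)
    pvals = []
    for k in range(400):
        lo = rng.uniform(2_000, 90_000)
        _, p = interval_episode_overlap(
            (lo, lo + 4_000), eps, n_permutations=99, seed=k
        )
        pvals.append(p)
    pvals = np.array(pvals)
    for alpha in (0.05, 0.1, 0.25):
        frac = (pvals <= alpha).mean()
        assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(pvals))


def test_interval_outside_span_rejected():
    eps = _episodes_fixture()
    with pytest.raises(ValueError):
        interval_episode_overlap((150_000.0, 160_000.0), eps, 10, seed=0)
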