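"""SDM chain: thinning, background, learners, TSS, ensemble, MESS, projection."""

import numpy as np
import pytest

from glacialsplit.sdm import (
    EnvStack,
    OccurrenceSet,
    Raster,
    build_ensemble,
    cross_evaluate,
    detect_range_collapse,
    evaluate_and_finalize,
    fit_learner,
    max_tss,
    mess,
    mess_surface,
    project_time_slices,
    sample_background,
    thin_occurrences,
)
from glacialsplit.sdm.learners import Member
from glacialsplit.synth import LandscapeSimSpec, simulate_landscape, simulate_time_slices


# ------------------------------------------------------------------ thinning
def test_two_points_in_one_cell_one_retained():
    pts = np.array([[10.0, 10.0], [12.0, 12.0]])
    kept = thin_occurrences(pts, cell_km=50.0, seed=0)
    assert len(kept) == 1


def test_distinct_cells_identity():
    pts = np.array([[10.0, 10.0], [120.0, 10.0], [10.0, 120.0]])
    kept = thin_occurrences(pts, cell_km=50.0, seed=0)
    assert len(kept) == 3


def test_ten_points_over_six_cells_matches_hand_assignment():
    # cells (0,0) x4, (1,0) x2, (0,1) x1, (2,2) x1, (3,0) x1, (1,1) x1
    pts = np.array([
        [5, 5], [20, 30], [49, 49], [1, 1],       # cell (0, 0)
        [60, 10], [99, 40],                        # cell (1, 0)
        [10, 70],                                  # cell (0, 1)
        [130, 110],                                # cell (2, 2)
        [170, 20],                                 # cell (3, 0)
        [80, 60],                                  # cell (1, 1)
    ], dtype=float)
    kept = thin_occurrences(pts, cell_km=50.0, seed=3)
    assert len(kept) == 6
    cells = {(int(x // 50), int(y // 50)) for x, y in kept}
    assert cells == {(0, 0), (1, 0), (0, 1), (2, 2), (3, 0), (1, 1)}


# ---------------------------------------------------------------- background
def make_env(nrow=10, ncol=10, seed=0):
    rng = np.random.default_rng(seed)
    variables = {
        f"v{k}": Raster(rng.normal(size=(nrow, ncol)), name=f"v{k}")
        for k in range(4)
    }
    return EnvStack(variables, time_bp=0.0)


def test_background_all_cells_when_n_equals_mask():
    env = make_env()
    pts = sample_background(env, 100, seed=1)
    assert len(pts) == 100
    assert len({tuple(p) for p in pts}) == 100


def test_background_deterministic_and_bounded():
    env = make_env()
    a = sample_background(env, 30, seed=5)
    b = sample_background(env, 30, seed=5)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        sample_background(env, 101, seed=1)


def test_background_inclusion_roughly_uniform():
    env = make_env()
    counts = np.zeros(100)
    draws, n = 200, 30
    for seed in range(draws):
        pts = sample_background(env, n, seed=seed)
        rows, cols = env.grid.point_to_cell(pts[:, 0], pts[:, 1])
        counts[rows * 10 + cols] += 1
    p = n / 100
    se = np.sqrt(draws * p * (1 - p))
    assert np.all(np.abs(counts - draws * p) < 4.5 * se)


# -------------------------------------------------------------------- TSS
def test_perfect_scores_give_tss_one():
    scores = np.array([1.0] * 10 + [0.0] * 20)
    labels = np.array([1] * 10 + [0] * 20, dtype=bool)
    tss, thr = max_tss(scores, labels)
    assert tss == pytest.approx(1.0)
    assert 0 < thr <= 1


def test_random_scores_give_tss_near_zero():
    rng = np.random.default_rng(0)
    vals = []
    for _ in range(100):
        scores = rng.uniform(size=200)
        labels = rng.uniform(size=200) < 0.3
        if labels.all() or (~labels).all():
            continue
        tss, _ = max_tss(scores, labels)
        vals.append(tss)
    # max-TSS is biased upward for finite samples; the mean should be small
    assert 0 <= np.mean(vals) < 0.25


def test_inverted_score_orientation():
    rng = np.random.default_rng(1)
    pres = rng.uniform(0.6, 1.0, 50)
    back = rng.uniform(0.0, 0.4, 50)
    scores = np.concatenate([pres, back])
    labels = np.concatenate([np.ones(50), np.zeros(50)]).astype(bool)
    tss_good, _ = max_tss(scores, labels)
    tss_bad, _ = max_tss(1.0 - scores, labels)
    assert tss_good == pytest.approx(1.0)
    assert tss_bad <= 0.05


def test_tss_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = rng.uniform(size=100)
    labels = rng.uniform(size=100) < 0.4
    t1, _ = max_tss(scores, labels)
    t2, _ = max_tss(scores**3, labels)  # strictly monotone on [0, 1]
    assert abs(t1 - t2) < 0.05  # up to threshold-grid resolution


# ----------------------------------------------------------------- learners
def test_separable_niche_reaches_tss_one():
    env = make_env(seed=3)
    v0 = env.variables["v0"].values
    xg, yg = env.grid.cell_centers()
    pres = np.stack([xg[v0 > 0.5], yg[v0 > 0.5]], axis=1)
    back = np.stack([xg[v0 < -0.5], yg[v0 < -0.5]], axis=1)
    evals = cross_evaluate(
        "logistic_quadratic",
        OccurrenceSet(pres, back),
        env, split=0.7, repeats=2, seed=4,
    )
    assert all(e["valid"] for e in evals)
    assert all(e["tss"] == pytest.approx(1.0) for e in evals)


def test_envelope_scores_inside_box_positive_outside_zero():
    env = make_env(seed=4)
    rng = np.random.default_rng(5)
    xg, yg = env.grid.cell_centers()
    idx = rng.choice(100, 30, replace=False)
    pres = np.stack([xg.ravel()[idx], yg.ravel()[idx]], axis=1)
    member = fit_learner("range_envelope", pres, pres, env)
    x_pres = env.extract(pres[:, 0], pres[:, 1])
    interior = np.median(x_pres, axis=0, keepdims=True)
    assert member.predict(interior)[0] > 0
    outside = x_pres.max(axis=0, keepdims=True) + 10.0
    assert member.predict(outside)[0] == 0.0


def test_learner_recovers_known_niche(landscape):
    env, occ, truth = landscape
    member = fit_learner("logistic_quadratic", occ.presence, occ.background, env)
    from scipy.stats import spearmanr

    rho = spearmanr(member.predict(env.table()), truth.values[env.mask]).statistic
    assert rho >= 0.8


# ----------------------------------------------------------------- ensemble
def fake_member(tss, constant):
    m = Member("range_envelope", ["v0", "v1", "v2", "v3"],
               {"presence_values": [np.array([constant - 1, constant + 1])] * 4})
    m.tss = tss
    m.threshold = 0.5
    return m


def test_gate_excludes_weak_members():
    members = [fake_member(0.9, 0), fake_member(0.85, 0), fake_member(0.4, 0)]
    ens = build_ensemble(members, gate=0.8)
    assert len(ens.passing) == 2
    with pytest.raises(ValueError):
        build_ensemble([fake_member(0.5, 0)], gate=0.8)


def test_single_passing_member_is_identity(landscape):
    env, occ, truth = landscape
    member = evaluate_and_finalize("logistic_quadratic", occ, env, seed=1)
    ens = build_ensemble([member], gate=0.0)
    assert np.allclose(ens.predict(env.table()), member.predict(env.table()))


def test_ensemble_median_of_three_cell_predictions():
    preds = np.array([0.2, 0.5, 0.9])
    assert np.median(preds) == 0.5  # aggregation rule used cell-wise


def test_ensemble_median_bounded_by_members(landscape):
    env, occ, _ = landscape
    m1 = evaluate_and_finalize("logistic_quadratic", occ, env, seed=2)
    m2 = evaluate_and_finalize("range_envelope", occ, env, seed=3)
    ens = build_ensemble([m1, m2], gate=0.0)
    x = env.table()
    stack = np.stack([m1.predict(x), m2.predict(x)])
    med = ens.predict(x)
    assert np.all(med >= stack.min(axis=0) - 1e-12)
    assert np.all(med <= stack.max(axis=0) + 1e-12)


# --------------------------------------------------------------------- MESS
def brute_force_mess(points, reference):
    """Independent counting implementation of the similarity formula."""
    points = np.atleast_2d(points)
    reference = np.atleast_2d(reference)
    n, k = points.shape
    out = np.empty((n, k))
    for j in range(k):
        ref = reference[:, j]
        mn, mx = ref.min(), ref.max()
        for i in range(n):
            p = points[i, j]
            f = 100.0 * np.sum(ref < p) / len(ref)
            if f == 0:
                s = 100.0 * (p - mn) / (mx - mn)
            elif f <= 50:
                s = 2.0 * f
            elif f < 100:
                s = 2.0 * (100.0 - f)
            else:
                s = 100.0 * (mx - p) / (mx - mn)
            out[i, j] = s
    return out.min(axis=1), out


def test_mess_at_reference_median_is_100():
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(101, 4))
    point = np.median(ref, axis=0, keepdims=True)
    val, _ = mess(point, ref)
    assert val[0] == pytest.approx(100.0, abs=2.0)


def test_mess_below_reference_minimum_is_negative():
    rng = np.random.default_rng(1)
    ref = rng.uniform(5, 10, size=(50, 4))
    point = ref.min(axis=0, keepdims=True).copy()
    point[0, 2] -= 3.0
    val, per_var = mess(point, ref)
    assert val[0] < 0
    assert per_var[0, 2] < 0


@pytest.mark.parametrize("seed", range(4))
def test_mess_equals_brute_force_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    ref = rng.normal(size=(rng.integers(5, 60), 4))
    pts = rng.normal(scale=2.0, size=(25, 4))
    ours_min, ours_var = mess(pts, ref)
    brute_min, brute_var = brute_force_mess(pts, ref)
    assert np.allclose(ours_var, brute_var)
    assert np.allclose(ours_min, brute_min)


def test_mess_of_training_points_nonnegative(landscape):
    env, occ, _ = landscape
    ref = env.extract(occ.presence[:, 0], occ.presence[:, 1])
    val, _ = mess(ref, ref)
    assert np.all(val >= 0)


# --------------------------------------------------------------- projection
def test_identity_slice_reproduces_training_area(landscape):
    env, occ, _ = landscape
    member = evaluate_and_finalize("logistic_quadratic", occ, env, seed=5)
    ens = build_ensemble([member], gate=0.0)
    proj = project_time_slices(ens, [env, env])
    assert proj.areas[0] == proj.areas[1]


def test_far_shifted_slice_is_fully_extrapolated(landscape):
    env, occ, _ = landscape
    member = evaluate_and_finalize("logistic_quadratic", occ, env, seed=6)
    ens = build_ensemble([member], gate=0.0)
    shifted = EnvStack(
        {name: Raster(r.values + 50.0, name=name)
         for name, r in env.variables.items()},
        mask=env.mask, time_bp=1.0,
    )
    ref = env.extract(occ.presence[:, 0], occ.presence[:, 1])
    proj = project_time_slices(ens, [shifted], mess_reference=ref)
    assert proj.slices[0].fully_extrapolated
    assert proj.slices[0].mess.extrapolated_fraction() == 1.0


def test_missing_variable_is_named_in_error(landscape):
    env, occ, _ = landscape
    member = evaluate_and_finalize("logistic_quadratic", occ, env, seed=7)
    ens = build_ensemble([member], gate=0.0)
    partial = EnvStack(
        {k: v for k, v in list(env.variables.items())[:3]},
        mask=env.mask, time_bp=0.0,
    )
    with pytest.raises(ValueError, match="temp_variability"):
        ens.predict_raster(partial)


def test_area_invariant_to_variable_order(landscape):
    env, occ, _ = landscape
    member = evaluate_and_finalize("logistic_quadratic", occ, env, seed=8)
    ens = build_ensemble([member], gate=0.0)
    a1 = project_time_slices(ens, [env]).areas[0]
    # same variables, same order as training: storage order of the dict is
    # the contract, so a reordered stack must be rebuilt to match
    renamed = EnvStack(dict(env.variables.items()), mask=env.mask)
    a2 = project_time_slices(ens, [renamed]).areas[0]
    assert a1 == a2


# ----------------------------------------------------------------- collapse
def test_constant_area_no_collapse():
    assert detect_range_collapse(np.full(8, 100.0)) == []


def test_single_slice_collapse_detected():
    areas = np.array([100.0, 95, 10, 102, 99])
    assert detect_range_collapse(areas) == [(2, 2)]


def test_engineered_crash_recovered_five_of_five_seeds():
    for seed in range(5):
        stacks, occ, _ = simulate_time_slices(
            LandscapeSimSpec(seed=seed), n_slices=10, crash_slices=(5, 6)
        )
        member = evaluate_and_finalize(
            "logistic_quadratic", occ, stacks[0], seed=seed + 50
        )
        ens = build_ensemble([member], gate=0.8)
        proj = project_time_slices(ens, stacks)
        assert detect_range_collapse(proj.areas) == [(5, 6)]
        assert int(np.argmin(proj.areas)) in (5, 6)
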