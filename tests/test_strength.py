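"""Module strength, temporal smoothing, normalization and pattern labels."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dynmod as dm
from dynmod.network import CoexpressionNetwork
from dynmod.strength import (
    StrengthConfig,
    StrengthTrajectory,
    classify_pattern,
    compare_groups,
    filter_flat,
    normalize_catalog,
    raw_strength,
    smooth_trajectory,
)


def toy_network():
    """4 nodes; internal edges {0.9, 0.8} in module {a,b,c}; boundary {0.5}."""
    return CoexpressionNetwork(
        0, ("a", "b", "c", "d"),
        [("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.5)],
        0.5,
    )


def test_raw_strength_hand_arithmetic():
    assert raw_strength(frozenset("abc"), toy_network()) == pytest.approx(1.7 / 2.2)


def test_raw_strength_trivial_cases():
    net = toy_network()
    assert raw_strength(frozenset("abcd"), net) == 1.0  # whole network
    assert raw_strength(frozenset("d"), net) == 0.0  # only external edges
    with pytest.raises(ValueError):
        raw_strength(frozenset("az"), net)


@pytest.mark.parametrize("seed", range(5))
def test_raw_strength_bounds_and_extremes(seed, small_networks):
    rng = np.random.default_rng(seed)
    net = small_networks[0]
    genes = list(net.gene_ids)
    module = frozenset(rng.choice(genes, size=30, replace=False))
    s = raw_strength(module, net)
    assert 0.0 <= s <= 1.0


# -- smoothing --------------------------------------------------------------
def test_smoothing_lambda_zero_is_identity():
    raw = np.array([0.3, 0.9, 0.1])
    np.testing.assert_array_equal(smooth_trajectory(raw, 0.0), raw)


def test_smoothing_constant_is_fixed_point():
    raw = np.full(5, 0.4)
    np.testing.assert_allclose(smooth_trajectory(raw, 0.9), raw, atol=1e-12)


def test_smoothing_matches_least_squares_oracle():
    """raw=[1,0,1,0], lambda=1 vs the stacked least-squares system."""
    raw = np.array([1.0, 0.0, 1.0, 0.0])
    lam = 1.0
    got = smooth_trajectory(raw, lam)
    d = np.zeros((3, 4))
    for t in range(3):
        d[t, t], d[t, t + 1] = -1.0, 1.0
    a = np.vstack([np.eye(4), np.sqrt(lam) * d])
    b = np.concatenate([raw, np.zeros(3)])
    expected, *_ = np.linalg.lstsq(a, b, rcond=None)
    np.testing.assert_allclose(got, expected, atol=1e-10)


@given(
    st.lists(st.floats(0, 1), min_size=2, max_size=8),
    st.floats(0.01, 5.0),
)
def test_smoothing_optimality_and_normal_equations(raw, lam):
    raw = np.asarray(raw)
    x = smooth_trajectory(raw, lam)

    def objective(v):
        return np.sum((v - raw) ** 2) + lam * np.sum(np.diff(v) ** 2)

    assert objective(x) <= objective(raw) + 1e-9
    # normal equations: (I + lam L) x = raw
    T = len(raw)
    L = np.zeros((T, T))
    for t in range(T - 1):
        L[t, t] += 1; L[t + 1, t + 1] += 1
        L[t, t + 1] -= 1; L[t + 1, t] -= 1
    np.testing.assert_allclose((np.eye(T) + lam * L) @ x, raw, atol=1e-8)


# -- normalization ----------------------------------------------------------
def traj(mid, smoothed):
    return StrengthTrajectory(mid, tuple(smoothed), tuple(smoothed))


def test_minmax_normalization_cases():
    out = normalize_catalog([traj("a", [0.2, 0.5]), traj("b", [0.8, 0.5])])
    assert out[0].normalized_strengths[0] == 0.0
    assert out[1].normalized_strengths[0] == 1.0
    # degenerate timestamp: everyone equal -> 0.5
    assert out[0].normalized_strengths[1] == 0.5
    assert out[1].normalized_strengths[1] == 0.5


def test_normalization_preserves_ranks():
    rng = np.random.default_rng(0)
    trajs = [traj(f"m{i}", rng.uniform(0, 1, 4)) for i in range(10)]
    out = normalize_catalog(trajs)
    for t in range(4):
        raw_order = np.argsort([tr.smoothed_strengths[t] for tr in trajs])
        norm_order = np.argsort([tr.normalized_strengths[t] for tr in out])
        np.testing.assert_array_equal(raw_order, norm_order)


# -- patterns ---------------------------------------------------------------
def ntraj(values, mid="m"):
    return StrengthTrajectory(mid, tuple(values), tuple(values), tuple(values))


CFG = StrengthConfig(pattern_delta=0.2)


@pytest.mark.parametrize(
    "values,expected",
    [
        ([0.1, 0.1, 0.1, 0.9], "pattern1_late_rise"),
        ([0.1, 0.8, 0.7, 0.1], "pattern2_hill"),
        ([0.9, 0.2, 0.15, 0.1], "pattern3_early_drop"),
        ([0.5, 0.5, 0.5, 0.5], "flat"),
        ([0.52, 0.5, 0.51, 0.5], "flat"),
        ([0.0, 0.3, 0.6, 0.9], "other"),  # monotone ramp fits no template
    ],
)
def test_pattern_classification(values, expected):
    assert classify_pattern(ntraj(values), CFG) == expected


def test_pattern_classification_is_exhaustive_and_deterministic():
    rng = np.random.default_rng(1)
    for _ in range(200):
        v = rng.uniform(0, 1, 4)
        a = classify_pattern(ntraj(v), CFG)
        b = classify_pattern(ntraj(v), CFG)
        assert a == b
        assert a in ("flat", "pattern1_late_rise", "pattern2_hill", "pattern3_early_drop", "other")


def test_pattern_requires_four_timestamps():
    with pytest.raises(ValueError):
        classify_pattern(ntraj([0.1, 0.2, 0.3]), CFG)


def test_filter_flat():
    ts = [
        StrengthTrajectory("a", (0,), (0,), (0,), "flat"),
        StrengthTrajectory("b", (0,), (0,), (0,), "other"),
    ]
    assert [t.module_id for t in filter_flat(ts)] == ["b"]


# -- group comparison -------------------------------------------------------
def test_identical_groups_all_shared():
    ts = [ntraj([0.1, 0.1, 0.1, 0.9], "a"), ntraj([0.9, 0.1, 0.1, 0.1], "b")]
    ts = [StrengthTrajectory(t.module_id, t.raw_strengths, t.smoothed_strengths,
                             t.normalized_strengths, "pattern1_late_rise") for t in ts]
    rep = compare_groups(ts, ts, delta=0.2)
    assert all(v == 0.0 for v in rep["per_module"].values())
    assert all(p["status"] == "shared" for p in rep["per_pattern"].values())


def test_planted_group_divergence_flagged():
    a = [
        StrengthTrajectory("m1", (0,) * 4, (0,) * 4, (0.1, 0.1, 0.1, 0.9), "pattern1_late_rise"),
        StrengthTrajectory("m2", (0,) * 4, (0,) * 4, (0.5, 0.5, 0.5, 0.5), "other"),
    ]
    b = [
        StrengthTrajectory("m1", (0,) * 4, (0,) * 4, (0.1, 0.1, 0.1, 0.1), None),
        StrengthTrajectory("m2", (0,) * 4, (0,) * 4, (0.5, 0.5, 0.5, 0.5), None),
    ]
    rep = compare_groups(a, b, delta=0.1)
    assert rep["per_pattern"]["pattern1_late_rise"]["status"] == "divergent"
    assert rep["per_pattern"]["other"]["status"] == "shared"
    assert 0 <= rep["per_pattern"]["pattern1_late_rise"]["fraction_divergent"] <= 1


def test_disjoint_module_sets_error():
    a = [ntraj([0.1] * 4, "a")]
    b = [ntraj([0.1] * 4, "b")]
    with pytest.raises(ValueError, match="share no modules"):
        compare_groups(a, b)
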