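"""Mutual information, conditional MI, max-MI discretization, permutation baseline."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import peakbn as pb
from peakbn.info import apply_boundaries, discretize_max_mi


# --- independent oracles -----------------------------------------------------

def brute_mi(x, y):
    """Direct double sum over the contingency table (independent of peakbn)."""
    x, y = list(x), list(y)
    n = len(x)
    out = 0.0
    for xv in set(x):
        px = x.count(xv) / n
        for yv in set(y):
            py = y.count(yv) / n
            pxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv) / n
            if pxy > 0:
                out += pxy * math.log2(pxy / (px * py))
    return out


def brute_best_threebin(values, labels):
    """Exhaustive search over all midpoint boundary pairs, brute-force MI."""
    v = np.asarray(values, float)
    s = np.unique(v)
    cuts = (s[:-1] + s[1:]) / 2
    best = 0.0
    for lo, hi in itertools.combinations(cuts, 2):
        bins = np.where(v < lo, 0, np.where(v > hi, 2, 1))
        best = max(best, brute_mi(bins.tolist(), list(labels)))
    return best


# --- mutual_information ------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([0, 0, 1, 1], [0, 1, 0, 1], 0.0),          # independent
        ([0, 0, 1, 1], [1, 1, 0, 0], 1.0),          # deterministic binary
        ([0, 1, 0, 1, 0, 1], [0, 1, 0, 1, 0, 1], 1.0),
    ],
)
def test_mi_known_values(x, y, expected):
    assert pb.mutual_information(x, y) == pytest.approx(expected, abs=1e-12)


def test_mi_matches_brute_force_on_mixed_alphabets():
    x, y = [0, 0, 1, 2], [0, 1, 1, 0]
    assert pb.mutual_information(x, y) == pytest.approx(brute_mi(x, y), abs=1e-12)


def test_mi_errors():
    with pytest.raises(ValueError):
        pb.mutual_information([0, 1], [0, 1, 2])
    with pytest.raises(ValueError):
        pb.mutual_information([], [])


@given(st.data())
def test_mi_symmetry_and_bounds(data):
    n = data.draw(st.integers(2, 40))
    x = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
    y = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
    mi_xy = pb.mutual_information(x, y)
    mi_yx = pb.mutual_information(y, x)
    assert abs(mi_xy - mi_yx) < 1e-12
    kmin = min(len(set(x)), len(set(y)))
    assert -1e-12 <= mi_xy <= math.log2(max(kmin, 2)) + 1e-12


# --- conditional_mutual_information -----------------------------------------

def test_cmi_serial_chain_is_zero():
    # C -> V1 -> V2 with deterministic copies: conditioning on V1 removes
    # all class information from V2
    c = np.repeat([0, 1], 50)
    v1 = c.copy()
    v2 = v1.copy()
    assert pb.conditional_mutual_information(c, v2, v1) == pytest.approx(0.0, abs=1e-12)
    assert pb.conditional_mutual_information(c, v1, v2) == pytest.approx(0.0, abs=1e-12)


def test_cmi_noisy_chain_is_asymmetric():
    # with label noise only on V2, conditioning on the noisy V2 retains more
    # class information in V1 than vice versa
    rng = np.random.default_rng(3)
    n = 10000
    c = rng.integers(0, 2, n)
    v1 = c.copy()
    flip = rng.random(n) < 0.05
    v2 = np.where(flip, 1 - v1, v1)
    cmi_12 = pb.conditional_mutual_information(c, v1, v2)
    cmi_21 = pb.conditional_mutual_information(c, v2, v1)
    assert cmi_12 > cmi_21
    assert cmi_21 == pytest.approx(0.0, abs=1e-9)


def test_cmi_constant_conditioner_reduces_to_mi():
    rng = np.random.default_rng(1)
    c = rng.integers(0, 2, 200)
    v2 = rng.integers(0, 3, 200)
    v1 = np.zeros(200, dtype=int)
    assert pb.conditional_mutual_information(c, v2, v1) == pytest.approx(
        pb.mutual_information(c, v2), abs=1e-12
    )


@given(st.data())
def test_chain_rule_identity(data):
    # MI(c; (v1,v2)) = MI(c; v1) + CMI(c; v2 | v1)
    n = data.draw(st.integers(4, 60))
    c = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    v1 = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
    v2 = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
    joint = [a * 3 + b for a, b in zip(v1, v2)]
    lhs = pb.mutual_information(c, joint)
    rhs = pb.mutual_information(c, v1) + pb.conditional_mutual_information(c, v2, v1)
    assert lhs == pytest.approx(rhs, abs=1e-9)


# --- discretize_max_mi -------------------------------------------------------

def test_discretizer_exhaustive_matches_brute_force():
    rng = np.random.default_rng(5)
    vals = rng.choice(np.linspace(0, 10, 12), size=40)
    labels = rng.integers(0, 2, 40)
    res = discretize_max_mi(vals, labels)
    assert res.mode == "exhaustive"
    assert res.mi == pytest.approx(brute_best_threebin(vals, labels), abs=1e-9)


def test_discretizer_separated_gaussians_isolate_central_bin():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1, 200)])
    y = np.repeat([0, 1], 200)
    res = discretize_max_mi(x, y)
    assert res.mi == pytest.approx(1.0, abs=0.05)
    assert (res.bins == 1).mean() < 0.10


def test_discretizer_class_independent_feature_scores_low():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 400)
    y = np.repeat([0, 1], 200)
    res = discretize_max_mi(x, y)
    thr = pb.permutation_baseline(
        x[:, None], class_labels=y, n_perm=50, seed=0
    )
    # a single null feature cannot beat 3.2x the max over 50 permutations
    assert res.mi < thr.effective_threshold


def test_discretizer_boundary_equal_values_go_to_middle_bin():
    bins = apply_boundaries(np.array([1.0, 2.0, 3.0]), 1.0, 3.0)
    assert bins.tolist() == [1, 1, 1]


def test_discretizer_degenerate_inputs_flagged():
    y = [0, 1, 0, 1]
    const = discretize_max_mi([5.0, 5.0, 5.0, 5.0], y)
    assert const.mode == "constant" and const.mi == 0.0
    two = discretize_max_mi([1.0, 1.0, 2.0, 2.0], y)
    assert two.mode == "two-level"
    assert set(two.bins.tolist()) <= {0, 1}
    assert two.b_low < two.b_high


def test_quantile_grid_agrees_with_exhaustive_within_tolerance():
    rng = np.random.default_rng(9)
    for trial in range(5):
        x = rng.normal(0, 1, 150)  # ~150 distinct values
        y = (x + rng.normal(0, 1, 150) > 0).astype(int)
        exact = discretize_max_mi(x, y, exhaustive_cap=200)
        approx = discretize_max_mi(x, y, exhaustive_cap=64, n_quantiles=64)
        assert exact.mode == "exhaustive" and approx.mode == "quantile"
        assert exact.mi >= approx.mi - 1e-12
        assert exact.mi - approx.mi < 0.01


@given(st.data())
def test_exhaustive_never_beaten_by_manual_boundaries(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    n = data.draw(st.integers(6, 30))
    vals = rng.choice(np.arange(8.0), size=n)
    if np.unique(vals).size < 3:
        vals[:3] = [0.0, 1.0, 2.0]
    labels = rng.integers(0, 2, n)
    res = discretize_max_mi(vals, labels)
    lo = data.draw(st.floats(-1, 8))
    hi = data.draw(st.floats(-1, 8))
    if lo >= hi:
        lo, hi = hi - 1e-6, lo + 1e-6
    manual = apply_boundaries(vals, lo, hi)
    assert res.mi >= pb.mutual_information(manual, labels) - 1e-9


# --- permutation_baseline ----------------------------------------------------

def test_threshold_spec_is_exact_product():
    thr = pb.ThresholdSpec(baseline_mi=0.0523, multiplier=3.2)
    assert thr.effective_threshold == 0.0523 * 3.2


def test_threshold_spec_validation():
    with pytest.raises(ValueError):
        pb.ThresholdSpec(-0.1)
    with pytest.raises(ValueError):
        pb.ThresholdSpec(0.1, multiplier=0.0)


def test_baseline_constant_feature_is_zero():
    X = np.full((20, 1), 3.0)
    y = np.repeat([0, 1], 10)
    thr = pb.permutation_baseline(X, class_labels=y, n_perm=1, seed=0)
    assert thr.baseline_mi == 0.0


def test_baseline_monotone_in_n_perm():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (60, 4))
    y = rng.integers(0, 2, 60)
    baselines = [
        pb.permutation_baseline(X, class_labels=y, n_perm=m, seed=11).baseline_mi
        for m in (1, 5, 20, 40)
    ]
    assert baselines == sorted(baselines)


def test_baseline_requires_permutations():
    with pytest.raises(ValueError):
        pb.permutation_baseline(np.zeros((4, 1)), class_labels=[0, 0, 1, 1], n_perm=0)
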