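import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germkin import (
    WardMinkowskiClustering,
    assign_letters,
    classify_quality,
    minkowski_ward_cluster,
    proportion_t_test,
)

# ---------------------------------------------------------------------------
# proportion t test
# ---------------------------------------------------------------------------


def test_equal_proportions_zero_statistic():
    r = proportion_t_test(30, 50, 30, 50)
    assert r.t_stat == 0.0
    assert r.significant is False


def test_known_comparison_significant():
    # 60% vs 28% germinated at n = 50 per sample
    r = proportion_t_test(30, 50, 14, 50)
    assert r.t_stat == pytest.approx(3.405, abs=2e-3)
    assert r.normality_ok and r.significant
    assert r.df == 98


def test_normality_guard_warns():
    with pytest.warns(UserWarning, match="normal approximation"):
        r = proportion_t_test(49, 50, 30, 50)
    assert not r.normality_ok
    assert r.significant is None


def test_guard_triggers_exactly_at_five():
    import warnings

    for X1, ok in ((44, True), (45, False)):  # n*q = 6 vs 5 (not > 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = proportion_t_test(X1, 50, 25, 50)
        assert r.normality_ok is ok


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        proportion_t_test(51, 50, 10, 50)
    with pytest.raises(ValueError):
        proportion_t_test(1, 0, 1, 10)


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 60), st.integers(1, 60), st.integers(0, 60), st.integers(1, 60))
def test_antisymmetry_under_sample_swap(X1, n1, X2, n2):
    import warnings

    X1, X2 = min(X1, n1), min(X2, n2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = proportion_t_test(X1, n1, X2, n2)
        b = proportion_t_test(X2, n2, X1, n1)
    assert a.t_stat == pytest.approx(-b.t_stat, abs=1e-12) or (
        np.isinf(a.t_stat) and a.t_stat == -b.t_stat
    )


# ---------------------------------------------------------------------------
# letters and quality classes
# ---------------------------------------------------------------------------


def test_letters_fully_separated_column():
    assert assign_letters([96, 60, 28], 50) == ["a", "b", "c"]


def test_letters_equal_proportions_share():
    letters = assign_letters([80, 80], 50)
    assert letters[0] == letters[1]


def test_letters_partial_grouping():
    assert assign_letters([90, 88, 30], 50) == ["a", "a", "b"]


def test_letters_input_order_preserved():
    assert assign_letters([28, 96, 60], 50) == ["c", "a", "b"]


def test_letters_need_two_samples():
    with pytest.raises(ValueError):
        assign_letters([50], 50)


@pytest.mark.parametrize(
    "V,G,expected",
    [
        (100, 100, "high"),
        (92, 92, "high"),
        (58, 28, "low"),
        (60, 50, "low"),
        (70, 68, "intermediate"),
        (64, 60, "intermediate"),
        (100, 40, "intermediate"),
    ],
)
def test_quality_classes(V, G, expected):
    assert classify_quality(V, G) == expected


def test_quality_range_checked():
    with pytest.raises(ValueError):
        classify_quality(101, 50)


@settings(derandomize=True, max_examples=200)
@given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 30), st.floats(0, 30))
def test_quality_monotone(V, G, dV, dG):
    order = {"low": 0, "intermediate": 1, "high": 2}
    lo = classify_quality(V, G)
    hi = classify_quality(min(V + dV, 100.0), min(G + dG, 100.0))
    assert order[hi] >= order[lo]


# ---------------------------------------------------------------------------
# Ward-Minkowski clustering
# ---------------------------------------------------------------------------


def brute_force_ward(X):
    """Exhaustive classic Ward agglomeration (SSE-increase objective).

    Returns merge steps as (members_a, members_b, height) with the scipy
    height convention sqrt(2 * delta SSE).
    """
    clusters = {i: [i] for i in range(X.shape[0])}
    steps = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ia, ib = clusters[a], clusters[b]
            ca, cb = X[ia].mean(axis=0), X[ib].mean(axis=0)
            d_sse = (len(ia) * len(ib)) / (len(ia) + len(ib)) * np.sum((ca - cb) ** 2)
            if best is None or d_sse < best[0]:
                best = (d_sse, a, b)
        d_sse, a, b = best
        steps.append((frozenset(clusters[a]), frozenset(clusters[b]),
                      np.sqrt(2.0 * d_sse)))
        clusters[a] = clusters[a] + clusters.pop(b)
    return steps


def linkage_steps(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    steps = []
    for k, (i, j, h, _) in enumerate(Z):
        a, b = members[int(i)], members[int(j)]
        steps.append((a, b, h))
        members[n + k] = a | b
    return steps


@pytest.mark.parametrize("trial", range(10))
def test_p2_linkage_matches_brute_force_ward(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(4, 8))
    X = rng.normal(size=(n, 3))
    res = minkowski_ward_cluster(X, p=2.0, standardize=False)
    got = linkage_steps(res.linkage, n)
    want = brute_force_ward(X)
    for (ga, gb, gh), (wa, wb, wh) in zip(got, want):
        assert {ga, gb} == {wa, wb}
        assert gh == pytest.approx(wh, rel=1e-10)


def test_identical_rows_merge_at_zero_height():
    X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
    res = minkowski_ward_cluster(X, standardize=False)
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert res.labels[0] == res.labels[1] != res.labels[2]


def test_two_near_one_far_geometry():
    eps = 1e-3
    X = np.array([[0.0, 0.0, 0.0], [eps, 0.0, 0.0], [10.0, 10.0, 10.0]])
    res = minkowski_ward_cluster(X, p=2.0, cut_fraction=0.10, standardize=False)
    assert res.labels.tolist() == [1, 1, 2]


def test_merge_heights_non_decreasing(rng):
    X = rng.normal(size=(9, 3))
    res = minkowski_ward_cluster(X, p=3.0)
    assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)


def test_labels_invariant_to_row_order_and_scaling(rng):
    X = np.vstack([
        rng.normal(0.0, 0.1, size=(4, 3)),
        rng.normal(5.0, 0.1, size=(4, 3)),
    ])
    base = minkowski_ward_cluster(X).labels
    perm = rng.permutation(8)
    permuted = minkowski_ward_cluster(X[perm]).labels
    # same partition up to relabeling
    for i in range(8):
        for j in range(8):
            same_base = base[perm[i]] == base[perm[j]]
            assert same_base == (permuted[i] == permuted[j])
    scaled = minkowski_ward_cluster(X * np.array([1e3, 1.0, 1e-3])).labels
    assert np.array_equal(base, scaled)  # z-standardization absorbs scale


def test_p_below_one_rejected(rng):
    with pytest.raises(ValueError):
        minkowski_ward_cluster(rng.normal(size=(4, 3)), p=0.5)


def test_cluster_estimator(rng):
    X = np.vstack([rng.normal(0, 0.05, (3, 3)), rng.normal(4, 0.05, (3, 3))])
    est = WardMinkowskiClustering(p=2.0)
    labels = est.fit_predict(X)
    assert est.n_clusters_ == 2
    assert np.array_equal(labels, est.labels_)
    assert est.get_params()["cut_fraction"] == 0.10
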