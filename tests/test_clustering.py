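"""k-means, Calinski-Harabasz, k-selection, HCL, group means, patterns."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from mircodereg import clustering as cl
from mircodereg.ingest import SampleMetadata


def _blobs(rng, k, n_per=15, d=6, sep=10.0):
    centers = np.zeros((k, d))
    centers[:, 0] = np.arange(k) * sep
    pts = np.vstack([c + rng.normal(0, 1, (n_per, d)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return pd.DataFrame(pts, index=[f"f{i}" for i in range(len(pts))]), labels


# ---- k-means --------------------------------------------------------------

def test_kmeans_recovers_separated_clouds(rng):
    m, truth = _blobs(rng, 2)
    model = cl.kmeans_cluster(m, 2, seed=0)
    got = model.assignments.to_numpy()
    # same partition up to label swap
    agree = max((got == truth + 1).mean(), (got == 2 - truth).mean())
    assert agree == 1.0


def test_kmeans_rejects_k_above_distinct_rows():
    m = pd.DataFrame([[1.0, 2.0]] * 5)
    with pytest.raises(ValueError, match="distinct"):
        cl.kmeans_cluster(m, 2, seed=0)


def test_kmeans_rejects_nan_input():
    m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
    with pytest.raises(ValueError, match="NaN"):
        cl.kmeans_cluster(m, 2, seed=0)


def test_kmeans_wcss_matches_exhaustive_enumeration(rng):
    """Best 2-partition of 12 points in 2D, by brute force."""
    m, _ = _blobs(rng, 2, n_per=6, d=2, sep=4.0)
    x = m.to_numpy()
    best = np.inf
    for assign in itertools.product([0, 1], repeat=12):
        assign = np.array(assign)
        if assign.min() == assign.max():
            continue
        wcss = sum(
            ((x[assign == c] - x[assign == c].mean(axis=0)) ** 2).sum()
            for c in (0, 1)
        )
        best = min(best, wcss)
    model = cl.kmeans_cluster(m, 2, seed=1, n_restarts=10)
    assert model.inertia == pytest.approx(best, rel=1e-9)


def test_kmeans_agrees_with_sklearn(rng):
    m, _ = _blobs(rng, 3, n_per=10)
    ours = cl.kmeans_cluster(m, 3, seed=2, n_restarts=10)
    sk = KMeans(n_clusters=3, n_init=10, random_state=2).fit(m.to_numpy())
    assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-6)


def test_kmeans_deterministic_under_seed(rng):
    m, _ = _blobs(rng, 3)
    a = cl.kmeans_cluster(m, 3, seed=5)
    b = cl.kmeans_cluster(m, 3, seed=5)
    pd.testing.assert_series_equal(a.assignments, b.assignments)
    np.testing.assert_array_equal(a.centroids, b.centroids)


def test_sorted_centroids_are_row_sorted(rng):
    m, _ = _blobs(rng, 2)
    model = cl.kmeans_cluster(m, 2, seed=0)
    arr = model.sorted_centroids.to_numpy()
    assert (np.diff(arr, axis=1) >= 0).all()
    np.testing.assert_allclose(np.sort(model.centroids.to_numpy(), axis=1),
                               arr)


# ---- Calinski-Harabasz ----------------------------------------------------

def test_ch_hand_computed_eight_points():
    m = pd.DataFrame([[0.0], [1.0], [0.5], [1.5],
                      [10.0], [11.0], [10.5], [11.5]])
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    x = m.to_numpy().ravel()
    grand = x.mean()
    b = sum(4 * (x[labels == c].mean() - grand) ** 2 for c in (1, 2))
    w = sum(((x[labels == c] - x[labels == c].mean()) ** 2).sum()
            for c in (1, 2))
    expected = (b / 1) / (w / 6)
    assert cl.calinski_harabasz(m, labels) == pytest.approx(expected)


def test_ch_matches_sklearn(rng):
    m, truth = _blobs(rng, 3)
    ours = cl.calinski_harabasz(m, truth)
    theirs = calinski_harabasz_score(m.to_numpy(), truth)
    assert ours == pytest.approx(theirs, rel=1e-9)


def test_ch_perfect_separation_is_infinite():
    m = pd.DataFrame([[0.0], [0.0], [5.0], [5.0]])
    assert cl.calinski_harabasz(m, [1, 1, 2, 2]) == np.inf


def test_ch_single_cluster_fails():
    with pytest.raises(ValueError):
        cl.calinski_harabasz(pd.DataFrame([[0.0], [1.0]]), [1, 1])


def test_ch_near_one_for_random_assignment(rng):
    scores = []
    for _ in range(30):
        x = pd.DataFrame(rng.normal(0, 1, (60, 4)))
        labels = rng.integers(0, 3, 60)
        if len(np.unique(labels)) < 2:
            continue
        scores.append(cl.calinski_harabasz(x, labels))
    assert 0.5 < np.mean(scores) < 1.6


# ---- k selection ----------------------------------------------------------

@pytest.mark.parametrize("k_true", [2, 3, 4])
def test_select_k_recovers_planted_k(rng, k_true):
    m, _ = _blobs(rng, k_true)
    k_star, model = cl.select_k(m, range(2, 9), seed=11)
    assert k_star == k_true
    assert set(model.ch_scores) == set(range(2, 9))


# ---- hierarchical ---------------------------------------------------------

def test_hcl_first_merge_is_nearest_pair():
    m = pd.DataFrame([[0.0], [1.0], [6.0]], index=["A", "B", "C"])
    res = cl.hierarchical_cluster(m)
    first = res.linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}  # A and B
    assert first[2] == pytest.approx(1.0)


def test_hcl_duplicate_rows_merge_at_height_zero():
    m = pd.DataFrame([[2.0, 3.0], [2.0, 3.0], [9.0, 9.0]])
    res = cl.hierarchical_cluster(m)
    assert res.linkage[0, 2] == pytest.approx(0.0)


def test_hcl_average_linkage_matches_hand_trace():
    """Six collinear points; average-linkage heights computed by hand."""
    pts = [0.0, 1.0, 5.0, 6.0, 20.0, 21.0]
    m = pd.DataFrame({"x": pts}, index=list("ABCDEF"))
    res = cl.hierarchical_cluster(m, linkage="average")
    heights = res.linkage[:, 2]
    # merges: {A,B}@1, {C,D}@1, {E,F}@1,
    # {AB,CD}@avg(|0-5|,|0-6|,|1-5|,|1-6|) = (5+6+4+5)/4 = 5.0,
    # {ABCD,EF}@avg of 8 distances = (20+21+19+20+15+16+14+15)/8 = 17.5
    np.testing.assert_allclose(sorted(heights), [1, 1, 1, 5.0, 17.5])


def test_hcl_merge_heights_nondecreasing(rng):
    m = pd.DataFrame(rng.normal(0, 1, (25, 5)))
    res = cl.hierarchical_cluster(m)
    assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()


def test_hcl_excludes_all_nan_rows():
    m = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]],
                     index=list("ABC"))
    with pytest.warns(UserWarning, match="all-NaN"):
        res = cl.hierarchical_cluster(m)
    assert res.labels == ["A", "C"]


def test_hcl_cut_and_newick_export(rng):
    m, _ = _blobs(rng, 2, n_per=5)
    res = cl.hierarchical_cluster(m)
    sub = res.cut(2)
    assert set(sub.unique()) == {1, 2}
    nwk = res.to_newick()
    assert nwk.endswith(";") and nwk.count("(") == len(m) - 1


# ---- group means ----------------------------------------------------------

def _meta_for(columns, variable, values):
    t = pd.DataFrame({variable: values}, index=columns)
    return SampleMetadata(t)


def test_group_means_identical_categories_give_identical_columns(rng):
    m = pd.DataFrame(rng.normal(0, 1, (5, 4)),
                     columns=["a", "b", "c", "d"])
    m["b"] = m["a"]
    m["d"] = m["c"]
    meta = _meta_for(list("abcd"), "grade", ["I", "II", "I", "II"])
    out = cl.group_mean_profiles(m, meta, "grade")
    np.testing.assert_allclose(out["I"], (m["a"] + m["c"]) / 2)


def test_group_means_singleton_category_is_that_sample(rng):
    m = pd.DataFrame(rng.normal(0, 1, (4, 3)), columns=list("abc"))
    meta = _meta_for(list("abc"), "grade", ["I", "I", "IV"])
    out = cl.group_mean_profiles(m, meta, "grade")
    np.testing.assert_allclose(out["IV"], m["c"])


def test_group_means_match_scalar_loop(rng):
    m = pd.DataFrame(rng.normal(0, 1, (6, 9)),
                     columns=[f"s{i}" for i in range(9)])
    m.iloc[2, 4] = np.nan
    cats = ["I", "II", "III"] * 3
    meta = _meta_for(list(m.columns), "grade", cats)
    out = cl.group_mean_profiles(m, meta, "grade")
    for cat in ("I", "II", "III"):
        cols = [c for c, g in zip(m.columns, cats) if g == cat]
        for i in range(6):
            vals = [m.loc[m.index[i], c] for c in cols]
            vals = [v for v in vals if np.isfinite(v)]
            assert out.loc[m.index[i], cat] == pytest.approx(np.mean(vals))


def test_group_means_rejects_unknown_variable(rng):
    m = pd.DataFrame(rng.normal(0, 1, (2, 2)), columns=["a", "b"])
    meta = _meta_for(["a", "b"], "grade", ["I", "II"])
    with pytest.raises(ValueError, match="diagnosis2"):
        cl.group_mean_profiles(m, meta, "outcome")


# ---- ordered patterns -----------------------------------------------------

def _graded_matrix(rng, order, step=1.0, noise=0.05, n_per=6, n_feat=8):
    cols, cats = [], []
    for rank, g in enumerate(order):
        for i in range(n_per):
            cols.append(f"{g}_{i}")
            cats.append(g)
    base = rng.normal(0, noise, (n_feat, len(cols)))
    for j, g in enumerate(cats):
        base[:, j] += order.index(g) * step
    m = pd.DataFrame(base, columns=cols)
    meta = _meta_for(cols, "grade", cats)
    return m, meta


def test_ordered_pattern_recovers_planted_order(rng):
    order = ["CONTROL", "IV", "I", "II", "III"]
    m, meta = _graded_matrix(rng, order)
    res = cl.detect_ordered_pattern(m, meta, "grade",
                                    candidate_orders=[order])[0]
    assert res.monotone
    assert res.order == order
    assert res.matched_candidate == tuple(order)
    assert res.anova_p < 1e-6


def test_ordered_pattern_flat_categories_not_monotone(rng):
    order = ["I", "II", "III"]
    m, meta = _graded_matrix(rng, order, step=0.0, noise=0.05)
    res = cl.detect_ordered_pattern(m, meta, "grade")[0]
    assert not res.monotone
    assert res.anova_p > 0.05


def test_bonferroni_multiplies_and_caps(rng):
    order = ["I", "II", "III", "IV", "CONTROL"]
    m, meta = _graded_matrix(rng, order, step=1.0)
    res = cl.detect_ordered_pattern(m, meta, "grade")[0]
    pw = res.pairwise_p
    assert (pw.to_numpy() <= 1.0 + 1e-12).all()
    # symmetric with unit diagonal
    np.testing.assert_allclose(pw.to_numpy(), pw.to_numpy().T)
    # 10 comparisons for 5 categories: recompute one raw p and check x10 cap
    a = m[[c for c in m.columns if c.startswith("I_")]].mean(axis=0)
    b = m[[c for c in m.columns if c.startswith("II_")]].mean(axis=0)
    raw = stats.ttest_ind(a, b).pvalue
    assert pw.loc["I", "II"] == pytest.approx(min(1.0, raw * 10))


def test_ordered_pattern_needs_three_categories(rng):
    m, meta = _graded_matrix(rng, ["I", "II"])
    with pytest.raises(ValueError, match="3 categories"):
        cl.detect_ordered_pattern(m, meta, "grade")


# ---- completion helper ----------------------------------------------------

def test_complete_for_clustering_imputes_row_median():
    m = pd.DataFrame([[1.0, 2.0, np.nan, 3.0],
                      [4.0, 4.0, 4.0, np.nan]],
                     columns=list("abcd"))
    out = cl.complete_for_clustering(m, min_coverage=0.5)
    assert not out.isna().any().any()
    assert out.loc[0, "c"] == pytest.approx(2.0)
    assert out.loc[1, "d"] == pytest.approx(4.0)


def test_complete_for_clustering_drops_sparse_columns():
    m = pd.DataFrame([[1.0, np.nan], [2.0, np.nan], [3.0, 4.0]],
                     columns=["a", "b"])
    out = cl.complete_for_clustering(m, min_coverage=0.8)
    assert list(out.columns) == ["a"]
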