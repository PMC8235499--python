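"""Unsupervised structure discovery on the ratio matrix.

k-means (squared Euclidean, k-means++ seeding, best of several restarts)
with Calinski-Harabasz selection of k, agglomerative sub-clustering,
sorted centroids for pattern display, descriptive (group-mean) clustering
over metadata categories, and detection of ordered expression patterns
across diagnosis/grade categories (ANOVA + Bonferroni post hoc).

The Lloyd loop is written out explicitly so that the within-cluster
sum-of-squares can be asserted non-increasing at every iteration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "ClusterModel",
    "PatternResult",
    "HclResult",
    "complete_for_clustering",
    "kmeans_cluster",
    "calinski_harabasz",
    "select_k",
    "hierarchical_cluster",
    "group_mean_profiles",
    "detect_ordered_pattern",
]

GROUPING_VARIABLES = ("diagnosis2", "diagnosis3", "grade")


def complete_for_clustering(m: pd.DataFrame,
                            min_coverage: float = 0.8) -> pd.DataFrame:
    """Make a complete matrix for distance-based methods.

    Keeps columns observed in at least ``min_coverage`` of rows, then
    imputes any remaining NaN with the row median.  Rows still lacking a
    finite median are dropped with a warning.
    """
    cov = m.notna().mean(axis=0)
    kept = m.loc[:, cov >= min_coverage]
    if kept.shape[1] == 0:
        raise ValueError(
            f"no column reaches {min_coverage:.0%} coverage; cannot cluster"
        )
    med = kept.median(axis=1)
    bad = med.isna()
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} all-NaN rows before clustering"
        )
        kept = kept.loc[~bad]
        med = med.loc[~bad]
    out = kept.apply(lambda col: col.fillna(med), axis=0)
    return out


@dataclass
class ClusterModel:
    """A fitted k-means partition.

    ``assignments`` maps each symbol to a 1-based cluster id; ``centroids``
    is k x samples; ``sorted_centroids`` has each centroid's entries
    reordered by value (for pattern display); ``ch_scores`` is filled by
    :func:`select_k` with the Calinski-Harabasz score per candidate k.
    """

    k: int
    assignments: pd.Series
    centroids: pd.DataFrame
    sorted_centroids: pd.DataFrame
    inertia: float
    seed: int | None = None
    n_restarts: int = 10
    ch_scores: dict = field(default_factory=dict)

    def members(self, cluster_id: int) -> list:
        return list(self.assignments.index[self.assignments == cluster_id])


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator,
           n_iterations: int) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means restart; asserts the WCSS never increases."""
    seed_int = int(rng.integers(0, 2**31 - 1))
    centers, _ = kmeans_plusplus(x, n_clusters=k, random_state=seed_int)
    prev_wcss = np.inf
    labels = np.zeros(len(x), dtype=int)
    for _ in range(n_iterations):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(len(x)), new_labels].sum())
        # Lloyd guarantee: each assignment/update step cannot raise the WCSS
        assert wcss <= prev_wcss + 1e-8 * max(1.0, abs(prev_wcss)), (
            "WCSS increased across Lloyd iterations"
        )
        for c in range(k):
            mask = new_labels == c
            if mask.any():
                centers[c] = x[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                worst = d2[np.arange(len(x)), new_labels].argmax()
                centers[c] = x[worst]
        if np.array_equal(new_labels, labels) and np.isfinite(prev_wcss):
            labels = new_labels
            prev_wcss = wcss
            break
        labels = new_labels
        prev_wcss = wcss
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(x)), labels].sum())
    return labels, centers, wcss


def kmeans_cluster(m: pd.DataFrame, k: int, n_iterations: int = 100,
                   n_restarts: int = 10, seed: int | None = None
                   ) -> ClusterModel:
    """k-means with squared-Euclidean distance, best of ``n_restarts``.

    Deterministic under ``seed``.  Requires k >= 2 and at least k distinct
    rows; the returned model never has an empty cluster.
    """
    x = m.to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError(
            "k-means input contains NaN; run complete_for_clustering first"
        )
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = len(np.unique(x, axis=0))
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct rows ({n_distinct})"
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        labels, centers, wcss = _lloyd(x, k, rng, n_iterations)
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss)
    labels, centers, wcss = best
    # relabel clusters by first appearance for stable, order-free ids
    remap = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.array([remap[lab] for lab in labels])
    order = sorted(remap, key=remap.get)
    centers = centers[order]
    centroids = pd.DataFrame(centers, index=range(1, k + 1),
                             columns=m.columns)
    sorted_centroids = pd.DataFrame(
        np.sort(centers, axis=1), index=centroids.index,
        columns=[f"rank{i + 1}" for i in range(centers.shape[1])],
    )
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=m.index, name="cluster"),
        centroids=centroids,
        sorted_centroids=sorted_centroids,
        inertia=wcss,
        seed=seed,
        n_restarts=n_restarts,
    )


def calinski_harabasz(m: pd.DataFrame, assignments) -> float:
    """Variance-ratio criterion: [B/(k-1)] / [W/(n-k)].

    B and W are the between- and within-cluster sums of squares about the
    global and cluster centroids.  Returns ``inf`` for perfectly separated
    clusters (W = 0).
    """
    x = np.asarray(m, dtype=float)
    labels = np.asarray(assignments)
    clusters = np.unique(labels)
    k, n = len(clusters), len(x)
    if k < 2:
        raise ValueError("Calinski-Harabasz needs at least 2 clusters")
    grand = x.mean(axis=0)
    b = 0.0
    w = 0.0
    for c in clusters:
        xc = x[labels == c]
        cen = xc.mean(axis=0)
        b += len(xc) * float(((cen - grand) ** 2).sum())
        w += float(((xc - cen) ** 2).sum())
    if w == 0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def select_k(m: pd.DataFrame, k_range=range(2, 11), seed: int | None = None,
             n_restarts: int = 10) -> tuple[int, ClusterModel]:
    """Pick k by maximizing the Calinski-Harabasz score over ``k_range``.

    Returns ``(k_star, model)`` where the model is the winning fit with
    the full score table attached in ``ch_scores``.
    """
    scores: dict[int, float] = {}
    models: dict[int, ClusterModel] = {}
    for i, k in enumerate(k_range):
        sub_seed = None if seed is None else (seed * 1000003 + k) % (2**31)
        model = kmeans_cluster(m, k, seed=sub_seed, n_restarts=n_restarts)
        scores[k] = calinski_harabasz(m, model.assignments)
        models[k] = model
    k_star = max(scores, key=lambda k: (scores[k], -k))
    winner = models[k_star]
    winner.ch_scores = scores
    return k_star, winner


@dataclass
class HclResult:
    """Agglomerative clustering output: SciPy linkage matrix + leaf order."""

    linkage: np.ndarray
    labels: list
    leaf_order: list
    method: str

    def cut(self, n_clusters: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=n_clusters,
                                  criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="subcluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return str(self.labels[node.id])
            left, right = rec(node.left), rec(node.right)
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return rec(tree) + ";"


def hierarchical_cluster(m: pd.DataFrame,
                         linkage: str = "average") -> HclResult:
    """Agglomerative clustering with Euclidean distance.

    Rows that are entirely NaN are excluded with a warning; any remaining
    NaN is row-median imputed so distances are defined.
    """
    if linkage not in ("single", "complete", "average", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    df = m.copy()
    all_nan = df.isna().all(axis=1)
    if all_nan.any():
        warnings.warn(f"excluding {int(all_nan.sum())} all-NaN rows")
        df = df.loc[~all_nan]
    if df.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if df.isna().any().any():
        med = df.median(axis=1)
        df = df.apply(lambda col: col.fillna(med), axis=0)
    z = hierarchy.linkage(pdist(df.to_numpy(float)), method=linkage)
    order = list(hierarchy.leaves_list(z))
    return HclResult(linkage=z, labels=list(df.index),
                     leaf_order=[df.index[i] for i in order], method=linkage)


def group_mean_profiles(m: pd.DataFrame, meta, variable: str) -> pd.DataFrame:
    """Collapse sample columns to category-wise NaN-ignoring means.

    ``variable`` is one of diagnosis2 / diagnosis3 / grade; the output
    (features x categories) feeds the descriptive k-means.
    """
    table = meta.table if hasattr(meta, "table") else meta
    if variable not in GROUPING_VARIABLES:
        raise ValueError(
            f"unknown grouping variable {variable!r}; "
            f"valid: {list(GROUPING_VARIABLES)}"
        )
    if variable not in table.columns:
        raise ValueError(f"metadata lacks column {variable!r}")
    cats = table.loc[m.columns, variable]
    out = {}
    for cat, cols in cats.groupby(cats).groups.items():
        out[cat] = m[list(cols)].mean(axis=1)
    return pd.DataFrame(out)


@dataclass
class PatternResult:
    """Ordered-pattern diagnostics for one cluster's mean profile."""

    cluster_id: int
    order: list  # categories sorted by ascending mean
    category_means: pd.Series
    category_sds: pd.Series
    anova_p: float
    pairwise_p: pd.DataFrame  # Bonferroni-adjusted, symmetric
    monotone: bool
    matched_candidate: tuple | None
    excluded_categories: list = field(default_factory=list)


def detect_ordered_pattern(m: pd.DataFrame, meta, variable: str,
                           assignments: pd.Series | None = None,
                           candidate_orders=None) -> list[PatternResult]:
    """Test each cluster's profile for a strictly ordered category pattern.

    For every cluster (or the whole matrix if ``assignments`` is None) the
    per-sample cluster mean is grouped by the metadata category; a one-way
    ANOVA spans the categories and all pairwise comparisons are
    Bonferroni-adjusted.  ``monotone`` is True when the category means are
    strictly ordered under one of the candidate orderings (default: any
    strict ordering) and the ANOVA is significant at 0.05.
    """
    table = meta.table if hasattr(meta, "table") else meta
    if variable not in table.columns:
        raise ValueError(f"metadata lacks column {variable!r}")
    cats = table.loc[m.columns, variable].astype(str)
    present = [c for c in cats.unique() if c != "nan"]
    if len(present) < 3:
        raise ValueError("ordered-pattern detection needs >= 3 categories")

    if assignments is None:
        cluster_map = {1: list(m.index)}
    else:
        cluster_map = {
            int(c): list(assignments.index[assignments == c])
            for c in sorted(assignments.unique())
        }

    results = []
    for cid, members in cluster_map.items():
        profile = m.loc[members].mean(axis=0)  # per-sample cluster mean
        groups, excluded = {}, []
        for cat in present:
            vals = profile[cats.index[cats == cat]].dropna().to_numpy()
            if len(vals) < 2:
                excluded.append(cat)
            else:
                groups[cat] = vals
        names = list(groups)
        means = pd.Series({c: g.mean() for c, g in groups.items()})
        sds = pd.Series({c: g.std(ddof=1) for c, g in groups.items()})
        if len(names) >= 2 and any(g.std() > 0 for g in groups.values()):
            anova_p = float(stats.f_oneway(*groups.values()).pvalue)
        else:
            anova_p = 1.0
        n_pairs = len(names) * (len(names) - 1) // 2
        pw = pd.DataFrame(np.nan, index=names, columns=names)
        for a, b in itertools.combinations(names, 2):
            if groups[a].std() == 0 and groups[b].std() == 0 \
                    and groups[a].mean() == groups[b].mean():
                p_raw = 1.0
            else:
                p_raw = float(stats.ttest_ind(groups[a], groups[b]).pvalue)
            adj = min(1.0, p_raw * n_pairs)
            pw.loc[a, b] = pw.loc[b, a] = adj
        np.fill_diagonal(pw.values, 1.0)

        observed = list(means.sort_values().index)
        strict = all(
            means[observed[i]] < means[observed[i + 1]]
            for i in range(len(observed) - 1)
        )
        matched = None
        if candidate_orders is not None:
            for cand in candidate_orders:
                cand_present = [c for c in cand if c in means.index]
                if cand_present == observed and strict:
                    matched = tuple(cand)
                    break
            monotone = matched is not None and anova_p < 0.05
        else:
            monotone = strict and anova_p < 0.05
            matched = tuple(observed) if strict else None
        results.append(PatternResult(
            cluster_id=cid, order=observed, category_means=means,
            category_sds=sds, anova_p=anova_p, pairwise_p=pw,
            monotone=monotone, matched_candidate=matched,
            excluded_categories=excluded,
        ))
    return results
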