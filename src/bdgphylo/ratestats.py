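"""Statistics on family-specific rates.

Covers the association between evolutionary rate and functional category
(range-of-medians permutation test), significance-tested hierarchical
clustering (SHC) of scaled rate profiles under a Monte-Carlo Gaussian null,
normalized mutual information between clusterings, silhouette coherence, and
cluster x function hypergeometric enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact
from sklearn.metrics import normalized_mutual_info_score, silhouette_score
from statsmodels.stats.multitest import multipletests

from .io import FunctionAnnotation

__all__ = [
    "category_medians",
    "permutation_test_range",
    "shc_cluster",
    "ClusteringResult",
    "compare_clusterings_nmi",
    "mean_silhouette",
    "cluster_function_enrichment",
    "standardize_profiles",
]

METRICS = {
    "euclidean": "euclidean",
    "pearson": "correlation",  # 1 - Pearson correlation
    "manhattan": "cityblock",
    "maximum": "chebyshev",
}
LINKAGES = ("average", "median", "complete", "centroid", "single")


def _metric_key(metric: str) -> str:
    key = metric.lower()
    if key not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}, got {metric!r}")
    return METRICS[key]


# ---------------------------------------------------------------------------
# rate / function association
# ---------------------------------------------------------------------------


def category_medians(
    rates: pd.Series, ann: FunctionAnnotation, min_size: int = 9
) -> pd.DataFrame:
    """Median rate per detailed functional category.

    Only informative annotations are used; categories with fewer than
    *min_size* families are reported but flagged ineligible for the
    permutation test.
    """
    info = ann.informative
    common = rates.index.intersection(info.index)
    if len(common) == 0:
        raise ValueError("no informative annotated families among the rates")
    df = pd.DataFrame(
        {"rate": rates.loc[common], "detailed": info.loc[common, "detailed"]}
    )
    out = df.groupby("detailed")["rate"].agg(median="median", size="size")
    out["eligible"] = out["size"] >= min_size
    return out.sort_values("median")


def permutation_test_range(
    rates: pd.Series,
    ann: FunctionAnnotation,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 9,
) -> dict:
    """Permutation test of rate/function association.

    Statistic: difference between the largest and smallest per-category
    median over eligible categories (>= *min_size* families). The null
    permutes the family-to-category assignment, preserving category sizes.
    Reported p is the raw exceedance fraction r/n; the add-one variant
    (r+1)/(n+1) is included alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    info = ann.informative
    common = rates.index.intersection(info.index)
    cats = info.loc[common, "detailed"]
    sizes = cats.value_counts()
    eligible = sizes.index[sizes >= min_size]
    if len(eligible) < 2:
        raise ValueError("need >= 2 eligible categories for the range statistic")
    mask = cats.isin(eligible)
    values = rates.loc[common][mask].to_numpy(dtype=float)
    codes = pd.Categorical(cats[mask]).codes
    n_cat = codes.max() + 1

    def range_stat(vals: np.ndarray) -> float:
        med = np.array([np.median(vals[codes == c]) for c in range(n_cat)])
        return float(med.max() - med.min())

    observed = range_stat(values)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        if range_stat(perm) >= observed:
            exceed += 1
    return {
        "observed": observed,
        "p_value": exceed / n_perm,
        "p_value_add_one": (exceed + 1) / (n_perm + 1),
        "n_perm": n_perm,
        "n_families": int(mask.sum()),
        "n_categories": int(n_cat),
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# significance-tested hierarchical clustering
# ---------------------------------------------------------------------------


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each coordinate to zero mean, unit variance."""
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return pd.DataFrame(
        (arr - arr.mean(axis=0)) / sd, index=profiles.index, columns=profiles.columns
    )


@dataclass
class ClusteringResult:
    """Outcome of significance-tested hierarchical clustering."""

    labels: pd.Series  # cluster id per family (duplicates restored)
    metric: str
    linkage: str
    alpha: float
    split_pvalues: list[float] = field(default_factory=list)
    overall_p: float = 1.0
    n_tests: int = 0
    significant: bool = False
    mean_silhouette: float = float("nan")
    restored_duplicates: list = field(default_factory=list)
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def _pair_index(n: int, members: np.ndarray) -> np.ndarray:
    """Condensed-distance indices of all pairs within *members*."""
    members = np.sort(members)
    ii, jj = np.triu_indices(len(members), k=1)
    a, b = members[ii], members[jj]
    return (n * a - a * (a + 1) // 2 + b - a - 1).astype(int)


def _bipartition_stat(dists: np.ndarray, n: int, left: np.ndarray, right: np.ndarray) -> float:
    """Within-over-union pairwise-distance ratio of a bipartition (smaller
    means better separated)."""
    union = np.concatenate([left, right])
    denom = dists[_pair_index(n, union)].sum()
    if denom <= 0:
        return 1.0
    num = 0.0
    if len(left) > 1:
        num += dists[_pair_index(n, left)].sum()
    if len(right) > 1:
        num += dists[_pair_index(n, right)].sum()
    return float(num / denom)


def _top_bipartition(X: np.ndarray, metric_key: str, method: str):
    """Leaves of the two subtrees under the root merge, plus the condensed
    distances used."""
    d = pdist(X, metric=metric_key)
    d = np.nan_to_num(d, nan=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = _scipy_linkage(d, method=method)
    n = X.shape[0]
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    for k, (a, b, _, _) in enumerate(Z):
        members[n + k] = np.concatenate([members[int(a)], members[int(b)]])
    top = Z[-1]
    return members[int(top[0])], members[int(top[1])], d, Z, members


def shc_cluster(
    profiles: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "centroid",
    alpha: float = 0.05,
    n_mc: int = 200,
    seed: int | None = None,
    min_split_size: int = 3,
) -> ClusteringResult:
    """Agglomerative clustering with a Monte-Carlo significance cut.

    Duplicate profiles are removed before clustering and restored to their
    twin's cluster afterwards. Starting from the dendrogram root, each
    candidate bipartition is tested: the statistic compares within-cluster
    pairwise distances with pairwise distances in the union, and the null
    distribution is obtained by sampling same-sized Gaussian datasets
    (mean/covariance fit to the union, diagonal-regularized if singular),
    re-clustering each with the same metric and linkage, and recomputing the
    statistic on the sample's own top bipartition. A split is kept when its
    p-value clears a Bonferroni correction over all tests performed; the
    reported p is the largest kept-split p-value.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    mkey = _metric_key(metric)
    if profiles.shape[0] < min_split_size:
        raise ValueError("need at least 3 profiles to cluster")
    arr = profiles.to_numpy(dtype=float)

    # de-duplicate identical rows, remembering the twin of each removed row
    uniq, first_idx, inverse = np.unique(arr, axis=0, return_index=True, return_inverse=True)
    restored = [
        profiles.index[i]
        for i in range(len(arr))
        if i not in set(first_idx.tolist())
    ]
    order = np.sort(first_idx)
    X = arr[order]
    uniq_index = profiles.index[order]
    rng = np.random.default_rng(seed)

    n = X.shape[0]
    if n < min_split_size:
        raise ValueError(
            f"only {n} distinct profile(s) after de-duplication; "
            "clustering needs at least 3"
        )
    left0, right0, d, Z, members = _top_bipartition(X, mkey, linkage)

    tests: dict[int, float] = {}  # dendrogram node id -> p-value
    n_tests = 0

    def test_node(node_id: int) -> float:
        nonlocal n_tests
        mem = members[node_id]
        sub = X[mem]
        kids_left = members[int(Z[node_id - n][0])]
        kids_right = members[int(Z[node_id - n][1])]
        obs = _bipartition_stat(d, n, kids_left, kids_right)
        mean = sub.mean(axis=0)
        cov = np.atleast_2d(np.cov(sub, rowvar=False))
        evals = np.linalg.eigvalsh(cov)
        if evals.min() <= 1e-10 * max(evals.max(), 1e-300):
            cov = cov + 1e-8 * max(np.trace(cov) / cov.shape[0], 1e-12) * np.eye(cov.shape[0])
            warnings.warn("singular covariance regularized for SHC null")
        better = 0
        for _ in range(n_mc):
            samp = rng.multivariate_normal(mean, cov, size=len(mem), method="eigh")
            sl, sr, sd_, _, _ = _top_bipartition(samp, mkey, linkage)
            stat = _bipartition_stat(sd_, len(mem), sl, sr)
            if stat <= obs:
                better += 1
        n_tests += 1
        p = (better + 1) / (n_mc + 1)
        tests[node_id] = p
        return p

    # top-down provisional descent at level alpha
    root_id = n + len(Z) - 1
    stack = [root_id]
    while stack:
        node_id = stack.pop()
        if len(members[node_id]) < min_split_size:
            continue
        p = test_node(node_id)
        if p < alpha:
            stack.append(int(Z[node_id - n][0]))
            stack.append(int(Z[node_id - n][1]))

    # final Bonferroni over all tests performed
    threshold = alpha / max(n_tests, 1)

    final_labels = np.zeros(n, dtype=int)
    kept_ps: list[float] = []
    next_label = [0]

    def assign(node_id: int) -> None:
        if (
            node_id >= n
            and node_id in tests
            and tests[node_id] < threshold
        ):
            kept_ps.append(tests[node_id])
            assign(int(Z[node_id - n][0]))
            assign(int(Z[node_id - n][1]))
        else:
            final_labels[members[node_id]] = next_label[0]
            next_label[0] += 1

    assign(root_id)

    labels_uniq = pd.Series(final_labels, index=uniq_index, name="cluster")
    # restore duplicates: each original row inherits its unique twin's label
    row_of_unique = {tuple(X[i]): final_labels[i] for i in range(n)}
    labels_all = pd.Series(
        [row_of_unique[tuple(arr[i])] for i in range(len(arr))],
        index=profiles.index,
        name="cluster",
    )
    significant = labels_all.nunique() > 1
    sil = float("nan")
    if significant:
        sil = mean_silhouette(profiles, labels_all, metric)
    return ClusteringResult(
        labels=labels_all,
        metric=metric,
        linkage=linkage,
        alpha=alpha,
        split_pvalues=kept_ps,
        overall_p=max(kept_ps) if kept_ps else (tests.get(root_id, 1.0)),
        n_tests=n_tests,
        significant=significant,
        mean_silhouette=sil,
        restored_duplicates=restored,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# clustering comparison
# ---------------------------------------------------------------------------


def compare_clusterings_nmi(a, b, normalizer: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions of the same set.

    The raw mutual information is divided by the chosen combination of the
    two clustering entropies (arithmetic mean by default; "min", "max" and
    "geometric" available). Two trivial single-cluster partitions are
    defined as identical (NMI 1) with a warning.
    """
    a = pd.Series(a)
    b = pd.Series(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same families")
    if isinstance(b.index, type(a.index)) and not a.index.equals(b.index):
        b = b.reindex(a.index)
        if b.isna().any():
            raise ValueError("partitions must cover the same families")
    if a.nunique() == 1 and b.nunique() == 1:
        warnings.warn("both partitions are trivial (single cluster); NMI defined as 1")
        return 1.0
    return float(
        normalized_mutual_info_score(a.to_numpy(), b.to_numpy(), average_method=normalizer)
    )


def mean_silhouette(profiles: pd.DataFrame, labels, metric: str = "euclidean") -> float:
    """Mean silhouette width of a labeled clustering (singletons score 0)."""
    labels = pd.Series(labels)
    if labels.nunique() < 2:
        raise ValueError("silhouette requires at least two clusters")
    X = profiles.to_numpy(dtype=float)
    return float(silhouette_score(X, labels.to_numpy(), metric=_metric_key(metric)))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def cluster_function_enrichment(
    labels: pd.Series,
    general_functions: pd.Series,
    merge: dict[str, list] | None = None,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Cluster x general-function enrichment (two-sided hypergeometric).

    *labels* maps family -> cluster; *general_functions* maps family ->
    general category (only families in both enter). *merge* pools clusters,
    e.g. ``{"IV-VI": [4, 5, 6]}``. Each (cluster, function) cell gets a
    two-sided hypergeometric (Fisher exact) p-value; significance flags are
    corrected across all cells (Benjamini-Hochberg by default, "bonferroni"
    available) at level *alpha*.
    """
    common = labels.index.intersection(general_functions.index)
    lab = labels.loc[common].copy()
    fun = general_functions.loc[common]
    if merge:
        mapping = {}
        for pooled, members in merge.items():
            for m in members:
                mapping[m] = pooled
        lab = lab.map(lambda c: mapping.get(c, c))
    table = pd.crosstab(lab, fun)
    if (table.sum(axis=1) == 0).any():
        table = table.loc[table.sum(axis=1) > 0]
        warnings.warn("dropped empty cluster(s) after annotation filtering")
    N = int(table.to_numpy().sum())
    rows = []
    for cluster in table.index:
        n_c = int(table.loc[cluster].sum())
        for func in table.columns:
            K = int(table[func].sum())
            k = int(table.loc[cluster, func])
            _, p = fisher_exact(
                [[k, n_c - k], [K - k, N - n_c - (K - k)]], alternative="two-sided"
            )
            expected = n_c * K / N
            rows.append(
                {
                    "cluster": cluster,
                    "function": func,
                    "count": k,
                    "cluster_size": n_c,
                    "function_total": K,
                    "expected": expected,
                    "direction": "over" if k > expected else ("under" if k < expected else "none"),
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    rej, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method=correction)
    out["p_adjusted"] = p_adj
    out["significant"] = rej
    out.attrs["counts"] = table
    return out
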