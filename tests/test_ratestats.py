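import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from bdgphylo.io import FunctionAnnotation
from bdgphylo.ratestats import (
    category_medians,
    cluster_function_enrichment,
    compare_clusterings_nmi,
    mean_silhouette,
    permutation_test_range,
    shc_cluster,
    standardize_profiles,
)


def _ann(mapping):
    fams = list(mapping)
    return FunctionAnnotation(
        pd.DataFrame(
            {"general": ["g"] * len(fams), "detailed": [mapping[f] for f in fams]},
            index=fams,
        )
    )


class TestCategoryMedians:
    def test_small_median(self):
        ann = _ann({"a": "c1", "b": "c1", "c": "c1"})
        rates = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        out = category_medians(rates, ann, min_size=1)
        assert out.loc["c1", "median"] == 2.0

    def test_minimum_size_flag(self):
        mapping = {f"x{i}": "small" for i in range(8)}
        mapping.update({f"y{i}": "big" for i in range(9)})
        ann = _ann(mapping)
        rates = pd.Series(np.arange(17.0), index=list(mapping))
        out = category_medians(rates, ann, min_size=9)
        assert not out.loc["small", "eligible"]
        assert out.loc["big", "eligible"]

    def test_matches_group_by(self):
        rng = np.random.default_rng(0)
        fams = [f"f{i}" for i in range(120)]
        cats = rng.choice(["a", "b", "c"], size=120)
        ann = _ann(dict(zip(fams, cats)))
        rates = pd.Series(rng.lognormal(size=120), index=fams)
        out = category_medians(rates, ann, min_size=1)
        for c in "abc":
            assert out.loc[c, "median"] == np.median(rates[cats == c])

    def test_uninformative_excluded(self):
        ann = _ann({"a": "general", "b": "unknown function", "c": "real"})
        rates = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        out = category_medians(rates, ann, min_size=1)
        assert list(out.index) == ["real"]


class TestPermutationTest:
    def test_identical_rates_give_p_one(self):
        mapping = {f"f{i}": ("a" if i < 10 else "b") for i in range(20)}
        ann = _ann(mapping)
        rates = pd.Series(1.0, index=list(mapping))
        out = permutation_test_range(rates, ann, n_perm=50, seed=0, min_size=2)
        assert out["observed"] == 0.0
        assert out["p_value"] == 1.0

    def test_exhaustive_enumeration_oracle(self):
        """Two categories of two families with rates (1,1 | 9,9): the exact
        permutation p equals the Monte-Carlo estimate within binomial error."""
        mapping = {"a": "lo", "b": "lo", "c": "hi", "d": "hi"}
        ann = _ann(mapping)
        rates = pd.Series([1.0, 1.0, 9.0, 9.0], index=list("abcd"))
        out = permutation_test_range(rates, ann, n_perm=4000, seed=1, min_size=2)
        assert out["observed"] == 8.0
        # exact: of the 4!/(2!2!) = 6 splits, 2 reach the extreme statistic
        exact = 0
        vals = rates.to_numpy()
        for combo in itertools.combinations(range(4), 2):
            lo = [vals[i] for i in combo]
            hi = [vals[i] for i in range(4) if i not in combo]
            stat = abs(np.median(hi) - np.median(lo))
            if stat >= 8.0:
                exact += 1
        p_exact = exact / 6
        assert abs(out["p_value"] - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 4000)

    def test_needs_two_categories(self):
        ann = _ann({"a": "only", "b": "only"})
        with pytest.raises(ValueError):
            permutation_test_range(pd.Series([1.0, 2.0], index=["a", "b"]), ann, min_size=2)

    def test_add_one_variant_reported(self):
        mapping = {f"f{i}": ("a" if i < 5 else "b") for i in range(10)}
        rates = pd.Series(np.r_[np.ones(5), 9 * np.ones(5)], index=list(mapping))
        out = permutation_test_range(rates, _ann(mapping), n_perm=100, seed=0, min_size=2)
        assert out["p_value_add_one"] == pytest.approx(
            (out["p_value"] * 100 + 1) / 101
        )


class TestSHC:
    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(60, 3))
        b = rng.normal(10, 1, size=(60, 3))  # 10 pooled SDs away
        X = pd.DataFrame(np.vstack([a, b]), index=[f"f{i}" for i in range(120)])
        res = shc_cluster(standardize_profiles(X), seed=0)
        assert res.significant
        assert res.n_clusters == 2
        labels = res.labels.to_numpy()
        agreement = max(
            (labels[:60] == labels[0]).mean() * (labels[60:] == labels[-1]).mean(),
            0.0,
        )
        assert (labels[:60] == labels[0]).all()
        assert (labels[60:] == labels[-1]).all()
        assert labels[0] != labels[-1]
        assert res.overall_p < 0.05 / res.n_tests + 1e-12
        assert res.mean_silhouette > 0.5

    def test_duplicate_rows_restored_to_same_cluster(self):
        rng = np.random.default_rng(1)
        base = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(8, 1, (30, 3))])
        X = np.vstack([base, base[:5]])  # 5 exact duplicates
        df = pd.DataFrame(X, index=[f"f{i}" for i in range(65)])
        res = shc_cluster(df, seed=0)
        assert len(res.restored_duplicates) == 5
        for i in range(5):
            assert res.labels.iloc[60 + i] == res.labels.iloc[i]

    def test_too_few_profiles_rejected(self):
        df = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            shc_cluster(df, seed=0)

    def test_unknown_metric_or_linkage_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            shc_cluster(df, metric="hamming", seed=0)
        with pytest.raises(ValueError):
            shc_cluster(df, linkage="ward", seed=0)


class TestNMI:
    def test_identical_partitions(self):
        a = pd.Series([0, 0, 1, 1])
        assert compare_clusterings_nmi(a, a) == pytest.approx(1.0)

    def test_crossed_partitions_share_nothing(self):
        a = pd.Series([0, 0, 1, 1])
        b = pd.Series([0, 1, 0, 1])
        assert compare_clusterings_nmi(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_label_invariance(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.integers(0, 4, 200))
        b = pd.Series(rng.integers(0, 3, 200))
        assert compare_clusterings_nmi(a, b) == pytest.approx(compare_clusterings_nmi(b, a))
        assert compare_clusterings_nmi(a, b) == pytest.approx(
            compare_clusterings_nmi(a.map({0: 9, 1: 8, 2: 7, 3: 6}), b)
        )

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.integers(0, 5, 1000))
        b = pd.Series(rng.integers(0, 5, 1000))
        assert compare_clusterings_nmi(a, b) < 0.05

    def test_trivial_partitions_warn_and_return_one(self):
        a = pd.Series([0, 0, 0])
        with pytest.warns(UserWarning):
            assert compare_clusterings_nmi(a, a) == 1.0


class TestSilhouette:
    def test_separated_clusters_near_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            np.vstack([rng.normal(0, 0.05, (30, 2)), rng.normal(5, 0.05, (30, 2))])
        )
        labels = pd.Series([0] * 30 + [1] * 30)
        assert mean_silhouette(X, labels) > 0.95

    def test_arbitrary_split_of_one_cloud_near_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 3)))
        labels = pd.Series(rng.integers(0, 2, 200))
        assert abs(mean_silhouette(X, labels)) < 0.1

    def test_hand_computed_example(self):
        # two pairs on a line: (0, 1) vs (10, 11)
        X = pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]})
        labels = pd.Series([0, 0, 1, 1])
        # for point 0: a=1, b=(10+11)/2=10.5 -> s=(10.5-1)/10.5
        expect = np.mean(
            [(10.5 - 1) / 10.5, (9.5 - 1) / 9.5, (9.5 - 1) / 9.5, (10.5 - 1) / 10.5]
        )
        assert mean_silhouette(X, labels) == pytest.approx(expect)

    def test_single_cluster_is_error(self):
        X = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            mean_silhouette(X, pd.Series([0, 0, 0, 0]))


class TestEnrichment:
    def test_whole_dataset_cluster_never_significant(self):
        fams = [f"f{i}" for i in range(50)]
        labels = pd.Series(0, index=fams)
        funcs = pd.Series(["a"] * 25 + ["b"] * 25, index=fams)
        out = cluster_function_enrichment(labels, funcs)
        assert (out["p_value"] > 0.999).all()

    def test_overrepresented_cell_flagged(self):
        # 157 of 772 in the focal cluster vs 171 of 1072 overall
        fams = [f"f{i}" for i in range(1072)]
        labels = pd.Series([1] * 772 + [2] * 300, index=fams)
        func = np.array(["other"] * 1072, dtype=object)
        func[:157] = "info"  # 157 in cluster 1
        func[772 : 772 + 14] = "info"  # 171 total
        out = cluster_function_enrichment(labels, pd.Series(func, index=fams))
        row = out[(out.cluster == 1) & (out.function == "info")].iloc[0]
        assert row.direction == "over"
        assert row.significant

    def test_matches_exact_tail_sum(self):
        # 8 of 10 in the cluster vs 10 of 100 background: two-sided
        # hypergeometric p from explicit tail enumeration
        fams = [f"f{i}" for i in range(110)]
        labels = pd.Series([1] * 10 + [2] * 100, index=fams)
        func = np.array(["n"] * 110, dtype=object)
        func[:8] = "y"
        func[10:20] = "y"
        out = cluster_function_enrichment(labels, pd.Series(func, index=fams))
        row = out[(out.cluster == 1) & (out.function == "y")].iloc[0]
        rv = hypergeom(110, 18, 10)
        p8 = rv.pmf(8)
        exact = sum(rv.pmf(k) for k in range(0, 11) if rv.pmf(k) <= p8 * (1 + 1e-9))
        assert row.p_value == pytest.approx(exact, rel=1e-6)

    def test_marginals_conserved(self):
        rng = np.random.default_rng(2)
        fams = [f"f{i}" for i in range(200)]
        labels = pd.Series(rng.integers(0, 3, 200), index=fams)
        funcs = pd.Series(rng.choice(["a", "b", "c", "d"], 200), index=fams)
        out = cluster_function_enrichment(labels, funcs)
        table = out.attrs["counts"]
        assert table.to_numpy().sum() == 200
        for c in table.index:
            assert table.loc[c].sum() == (labels == c).sum()

    def test_merge_pools_clusters(self):
        fams = [f"f{i}" for i in range(30)]
        labels = pd.Series([4] * 10 + [5] * 10 + [6] * 10, index=fams)
        funcs = pd.Series(["a"] * 15 + ["b"] * 15, index=fams)
        out = cluster_function_enrichment(labels, funcs, merge={"IV-VI": [4, 5, 6]})
        assert set(out.cluster) == {"IV-VI"}
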