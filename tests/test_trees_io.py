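import numpy as np
import pandas as pd
import pytest

from bdgphylo.io import (
    KEPT,
    REMOVED_LARGEST,
    REMOVED_OUTGROUP_ONLY,
    FunctionAnnotation,
    ProfileError,
    ProfileMatrix,
    apply_study_filters,
    profile_summaries,
    read_profile_matrix,
)
from bdgphylo.trees import SpeciesTree, TreeError, read_species_tree


class TestSpeciesTree:
    def test_parse_small_newick(self):
        t = SpeciesTree.from_newick("((A:1,B:1):1,C:2);")
        assert t.n_leaves == 3
        assert t.n_nodes == 5
        assert len(t.branch_nodes) == 4
        assert sorted(t.leaf_labels) == ["A", "B", "C"]
        # branch lengths seed the durations
        assert t.durations[t.label_index("C")] == 2.0

    def test_polytomy_rejected_unless_allowed(self):
        with pytest.raises(TreeError, match="multifurcating"):
            SpeciesTree.from_newick("(A,B,C);")
        t = SpeciesTree.from_newick("(A,B,C);", allow_polytomy=True)
        assert t.n_leaves == 3

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            SpeciesTree.from_newick("((A,A),B);")

    def test_missing_lengths_default_to_one(self):
        t = SpeciesTree.from_newick("((A,B),C);")
        assert np.all(t.durations[t.branch_nodes] == 1.0)

    def test_study_scale_topology(self, taxa24_path):
        t = read_species_tree(str(taxa24_path), outgroups={"NEUCR", "DICDI", "ARATH"})
        assert t.n_leaves == 24
        assert t.n_nodes - t.n_leaves == 23  # internal nodes of a binary tree
        assert "HUMAN" in t.leaf_labels
        human = t.label_index("HUMAN")
        sauria = t.label_index("Sauria")
        assert t.parent[human] == t.parent[sauria]  # amniote sister pair

    def test_mrca_and_subtree(self):
        t = SpeciesTree.from_newick("((A,B)ab,(C,D)cd)r;")
        ab = t.mrca([t.label_index("A"), t.label_index("B")])
        assert t.labels[ab] == "ab"
        r = t.mrca([t.label_index("A"), t.label_index("C")])
        assert t.labels[r] == "r"
        leaves = {t.labels[v] for v in t.subtree_leaves(ab)}
        assert leaves == {"A", "B"}

    def test_newick_round_trip(self):
        t = SpeciesTree.from_newick("((A:1,B:1)x:1,C:2)r;")
        t2 = SpeciesTree.from_newick(t.to_newick())
        assert sorted(t2.leaf_labels) == sorted(t.leaf_labels)
        assert np.allclose(sorted(t2.durations[t2.branch_nodes]), sorted(t.durations[t.branch_nodes]))


class TestProfileMatrix:
    def test_read_toy_tsv(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("family\tA\tB\tC\nf1\t0\t1\t2\nf2\t3\t0\t0\n")
        pm = read_profile_matrix(p)
        assert pm.counts.to_numpy().tolist() == [[0, 1, 2], [3, 0, 0]]
        assert (pm.status == KEPT).all()

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("family\tA\tB\nf1\t0\t-1\n")
        with pytest.raises(ProfileError, match="negative"):
            read_profile_matrix(p)

    def test_non_integer_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("family\tA\tB\nf1\t0.5\t1\n")
        with pytest.raises(ProfileError, match="non-integer"):
            read_profile_matrix(p)

    def test_species_mismatch_names_offender(self, toy_tree):
        pm = ProfileMatrix(pd.DataFrame([[1, 2]], index=["f"], columns=["A", "Z"]))
        with pytest.raises(ProfileError, match="Z"):
            pm.validate_against_tree(toy_tree)

    def test_tsv_round_trip(self, tmp_path, toy_profiles):
        p = tmp_path / "out.tsv"
        toy_profiles.to_tsv(p)
        back = read_profile_matrix(p)
        pd.testing.assert_frame_equal(back.counts, toy_profiles.counts)


class TestStudyFilters:
    def _pm(self):
        counts = pd.DataFrame(
            {
                "A": [3400, 1, 0, 0, 2],
                "B": [10, 1, 0, 0, 0],
                "OUT": [5, 1, 4, 0, 1],
            },
            index=["huge", "core", "og_only", "empty", "mixed"],
        )
        return ProfileMatrix(counts)

    def test_largest_and_outgroup_rules(self):
        pm = apply_study_filters(self._pm(), size_threshold=3300, outgroups={"OUT"})
        assert pm.status["huge"] == REMOVED_LARGEST
        assert pm.status["og_only"] == REMOVED_OUTGROUP_ONLY
        assert pm.status["empty"] == REMOVED_OUTGROUP_ONLY  # vacuously absent ingroup
        assert pm.status["core"] == KEPT
        assert pm.status["mixed"] == KEPT

    def test_idempotent(self):
        once = apply_study_filters(self._pm(), size_threshold=3300, outgroups={"OUT"})
        twice = apply_study_filters(once, size_threshold=3300, outgroups={"OUT"})
        pd.testing.assert_series_equal(once.status, twice.status)

    def test_partition_of_families(self):
        pm = apply_study_filters(self._pm(), size_threshold=3300, outgroups={"OUT"})
        kept = int((pm.status == KEPT).sum())
        removed = int((pm.status != KEPT).sum())
        assert kept + removed == len(pm.families)

    def test_percentile_alternative(self):
        counts = pd.DataFrame(
            {"A": np.arange(1, 41), "B": np.zeros(40, dtype=int)},
            index=[f"f{i}" for i in range(40)],
        )
        pm = apply_study_filters(
            ProfileMatrix(counts), size_threshold=None, size_percentile=2.5
        )
        assert int((pm.status == REMOVED_LARGEST).sum()) == 1
        assert pm.status["f39"] == REMOVED_LARGEST

    def test_all_removed_is_error(self):
        pm = ProfileMatrix(pd.DataFrame({"A": [5]}, index=["f"]))
        with pytest.raises(ProfileError, match="every family"):
            apply_study_filters(pm, size_threshold=1)


class TestProfileSummaries:
    def test_small_enumeration(self):
        pm = ProfileMatrix(
            pd.DataFrame([[1, 1], [0, 2], [3, 0]], index=list("xyz"), columns=["A", "B"])
        )
        out = profile_summaries(pm, {"all": ["A", "B"]})
        assert out.loc["all", "core_families"] == 1
        assert out.loc["all", "species_specific_families"] == 2

    def test_single_species_clade(self):
        pm = ProfileMatrix(
            pd.DataFrame([[1, 0], [0, 2]], index=["x", "y"], columns=["A", "B"])
        )
        out = profile_summaries(pm, {"justA": ["A"]})
        assert out.loc["justA", "core_families"] == 1

    def test_core_count_matches_row_scan(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(0.8, size=(1000, 6)),
            index=[f"f{i}" for i in range(1000)],
            columns=list("ABCDEF"),
        )
        pm = ProfileMatrix(counts)
        out = profile_summaries(pm, {"all": list("ABCDEF")})
        brute = sum(1 for _, row in counts.iterrows() if (row > 0).all())
        assert out.loc["all", "core_families"] == brute

    def test_empty_clade_rejected(self, toy_profiles):
        with pytest.raises(ProfileError, match="empty"):
            profile_summaries(toy_profiles, {"none": []})


class TestFunctionAnnotation:
    def test_informative_flagging(self):
        tab = pd.DataFrame(
            {
                "general": ["Information", "General", "Metabolism"],
                "detailed": ["transcription", "general", "transferases"],
            },
            index=["f1", "f2", "f3"],
        )
        ann = FunctionAnnotation(tab)
        assert ann.table.loc["f1", "informative"]
        assert not ann.table.loc["f2", "informative"]
        assert list(ann.informative.index) == ["f1", "f3"]

    def test_duplicate_family_rejected(self):
        tab = pd.DataFrame(
            {"general": ["a", "b"], "detailed": ["x", "y"]}, index=["f1", "f1"]
        )
        with pytest.raises(ProfileError, match="more than once"):
            FunctionAnnotation(tab)
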