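"""Profile matrices, function annotations, study filters and summaries.

A phylogenetic profile matrix holds non-negative integer copy counts, one row
per family and one column per species (tree leaf). Filtering never deletes
rows: each family carries a status flag so that every downstream table can be
traced back to the unfiltered input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import SpeciesTree

__all__ = [
    "ProfileMatrix",
    "FunctionAnnotation",
    "read_profile_matrix",
    "read_annotation",
    "apply_study_filters",
    "profile_summaries",
]

KEPT = "kept"
REMOVED_LARGEST = "removed_largest"
REMOVED_OUTGROUP_ONLY = "removed_outgroup_only"
REMOVED_INFERENCE_FAILURE = "removed_inference_failure"

UNINFORMATIVE_CATEGORIES = {"general", "unknown function"}


class ProfileError(ValueError):
    pass


@dataclass
class ProfileMatrix:
    """Families x species count table with per-family filter status."""

    counts: pd.DataFrame
    status: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            arr = self.counts.to_numpy()
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ProfileError("counts must be integers")
            self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            bad = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ProfileError(
                f"negative count at family {self.counts.index[bad[0]]!r}, "
                f"species {self.counts.columns[bad[1]]!r}"
            )
        self.counts.index.name = "family"
        if self.status is None:
            self.status = pd.Series(KEPT, index=self.counts.index, name="status")
        else:
            self.status = self.status.reindex(self.counts.index)

    @property
    def families(self) -> pd.Index:
        return self.counts.index

    @property
    def species(self) -> pd.Index:
        return self.counts.columns

    @property
    def kept(self) -> pd.DataFrame:
        return self.counts.loc[self.status == KEPT]

    def validate_against_tree(self, tree: SpeciesTree) -> None:
        leaves = set(tree.leaf_labels)
        cols = set(self.species)
        if leaves != cols:
            only_tree = sorted(leaves - cols)
            only_matrix = sorted(cols - leaves)
            raise ProfileError(
                "species mismatch between tree and profile matrix: "
                f"only in tree {only_tree}; only in matrix {only_matrix}"
            )

    def aligned_counts(self, tree: SpeciesTree, kept_only: bool = True) -> pd.DataFrame:
        """Counts with columns reordered to the tree's leaf order."""
        self.validate_against_tree(tree)
        df = self.kept if kept_only else self.counts
        return df[tree.leaf_labels]

    def mark(self, families, status: str) -> None:
        self.status.loc[list(families)] = status

    def to_tsv(self, path: str) -> None:
        out = self.counts.copy()
        out.index.name = "family"
        out.to_csv(path, sep="\t")

    def copy(self) -> "ProfileMatrix":
        return ProfileMatrix(self.counts.copy(), self.status.copy())


def read_profile_matrix(path) -> ProfileMatrix:
    """Read a tab-delimited count table (first column family IDs, header row
    of species labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna())))
        raise ProfileError(
            f"missing value at family {df.index[row]!r}, species {df.columns[col]!r}"
        )
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ProfileError("non-numeric cells in profile matrix")
    if np.any(arr != np.floor(arr)):
        row, col = np.argwhere(arr != np.floor(arr))[0]
        raise ProfileError(
            f"non-integer count at family {df.index[row]!r}, species {df.columns[col]!r}"
        )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ProfileError(f"duplicate family ID: {dup!r}")
    return ProfileMatrix(df.astype(int))


@dataclass
class FunctionAnnotation:
    """Family -> (general, detailed) function map.

    Categories named "general" or "unknown function" convey no information
    and are flagged non-informative (the informative subset drives all
    rate/function statistics).
    """

    table: pd.DataFrame  # index: family; columns: general, detailed

    def __post_init__(self) -> None:
        missing = {"general", "detailed"} - set(self.table.columns)
        if missing:
            raise ProfileError(f"annotation table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ProfileError(f"family annotated more than once: {dup!r}")
        self.table = self.table.assign(
            informative=~self.table["detailed"].isin(UNINFORMATIVE_CATEGORIES)
        )

    @property
    def informative(self) -> pd.DataFrame:
        return self.table.loc[self.table["informative"]]

    def to_tsv(self, path: str) -> None:
        out = self.table[["general", "detailed"]].copy()
        out.index.name = "family"
        out.to_csv(path, sep="\t")


def read_annotation(path) -> FunctionAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return FunctionAnnotation(df)


def apply_study_filters(
    pm: ProfileMatrix,
    size_threshold: int | None = 3300,
    outgroups: set[str] = frozenset(),
    size_percentile: float | None = None,
) -> ProfileMatrix:
    """Flag oversized families and families confined to the outgroups.

    Families whose total copy number exceeds *size_threshold* are flagged
    ``removed_largest`` (largest families inflate the apparent duplication
    rate). Alternatively *size_percentile* removes the top p% by total count.
    Families with zero counts at every non-outgroup leaf are flagged
    ``removed_outgroup_only``. Counts are never modified; filtering is
    idempotent.
    """
    pm = pm.copy()
    totals = pm.counts.sum(axis=1)
    if size_percentile is not None:
        if not 0 < size_percentile < 100:
            raise ProfileError("size_percentile must be in (0, 100)")
        cut = np.percentile(totals.to_numpy(), 100 - size_percentile)
        large = totals.index[totals > cut]
    elif size_threshold is not None:
        if size_threshold <= 0:
            raise ProfileError("size_threshold must be positive")
        large = totals.index[totals > size_threshold]
    else:
        large = pd.Index([])
    pm.mark(large, REMOVED_LARGEST)

    unknown = set(outgroups) - set(pm.species)
    if unknown:
        raise ProfileError(f"outgroups not among species columns: {sorted(unknown)}")
    ingroup = [s for s in pm.species if s not in set(outgroups)]
    ingroup_present = (pm.counts[ingroup] > 0).any(axis=1)
    outgroup_only = pm.counts.index[~ingroup_present & ~pm.counts.index.isin(large)]
    pm.mark(outgroup_only, REMOVED_OUTGROUP_ONLY)

    if (pm.status == KEPT).sum() == 0:
        raise ProfileError("filters removed every family")
    return pm


def profile_summaries(pm: ProfileMatrix, clades: dict[str, list[str]]) -> pd.DataFrame:
    """Descriptive per-clade summary of the kept families.

    For each named leaf set: number of core families (present in every
    member), number of species-specific families (present in exactly one
    member of the clade), and mean fractions present / multicopy across the
    clade's species.
    """
    kept = pm.kept
    rows = []
    for name, members in clades.items():
        if not members:
            raise ProfileError(f"clade {name!r} is empty")
        missing = set(members) - set(pm.species)
        if missing:
            raise ProfileError(f"clade {name!r} has unknown species: {sorted(missing)}")
        sub = kept[list(members)]
        present = sub > 0
        rows.append(
            {
                "clade": name,
                "n_species": len(members),
                "core_families": int(present.all(axis=1).sum()),
                "species_specific_families": int((present.sum(axis=1) == 1).sum()),
                "mean_fraction_present": float(present.mean(axis=0).mean()),
                "mean_fraction_multicopy": float((sub > 1).mean(axis=0).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("clade")
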