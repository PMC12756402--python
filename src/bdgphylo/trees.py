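"""Rooted species trees with per-branch birth-death-gain parameters.

The tree is the fixed scaffold of the analysis: topology is taken as given,
while the branch parameters (duration ``t_b``, birth rate ``lambda_b``, gain
rate ``kappa_b``; the loss rate is 1 by convention, so ``t_b`` carries the
loss scale) are estimated from the data. Newick branch lengths, when present,
only seed the durations.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "read_species_tree"]


class TreeError(ValueError):
    pass


@dataclass
class SpeciesTree:
    """Rooted tree stored as flat arrays for fast post-/pre-order sweeps.

    Nodes are indexed 0..n-1; ``parent[root] == -1``. Every non-root node
    identifies the branch above it, so per-branch quantities are stored as
    per-node arrays (entry for the root is unused).
    """

    labels: list[str]
    parent: np.ndarray
    children: list[list[int]]
    durations: np.ndarray  # t_b for the branch above each node
    birth_rates: np.ndarray | None = None  # lambda_b
    gain_rates: np.ndarray | None = None  # kappa_b
    outgroups: frozenset[str] = frozenset()

    root: int = field(init=False)
    postorder: np.ndarray = field(init=False)
    leaf_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.durations = np.asarray(self.durations, dtype=float)
        if not np.all(np.isfinite(self.durations[self.branch_nodes])):
            raise TreeError("branch durations must be finite")
        if np.any(self.durations[self.branch_nodes] < 0):
            raise TreeError("branch durations must be non-negative")
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()  # children before parents
        self.postorder = np.asarray(order, dtype=int)
        self.leaf_indices = np.asarray(
            [v for v in range(self.n_nodes) if not self.children[v]], dtype=int
        )
        leaf_labels = self.leaf_labels
        if len(set(leaf_labels)) != len(leaf_labels):
            raise TreeError("duplicate leaf labels")
        unknown = set(self.outgroups) - set(leaf_labels)
        if unknown:
            raise TreeError(f"outgroup labels not in tree: {sorted(unknown)}")

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    @property
    def branch_nodes(self) -> np.ndarray:
        """Indices of nodes that have a branch above them (all but the root)."""
        return np.asarray([v for v in range(len(self.labels)) if self.parent[v] >= 0])

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[int(i)] for i in self.leaf_indices]

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def label_index(self, label: str) -> int:
        return self.labels.index(label)

    def subtree_leaves(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(u)
            stack.extend(self.children[u])
        return out

    def mrca(self, nodes: list[int]) -> int:
        if not nodes:
            raise TreeError("mrca of empty node set")
        paths = []
        for v in nodes:
            path = []
            while v >= 0:
                path.append(v)
                v = int(self.parent[v])
            paths.append(path[::-1])
        anc = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            step = {p[depth] for p in paths}
            if len(step) == 1:
                anc = step.pop()
            else:
                break
        return anc

    # -- parameters -------------------------------------------------------
    def with_parameters(
        self,
        durations: np.ndarray | None = None,
        birth_rates: np.ndarray | None = None,
        gain_rates: np.ndarray | None = None,
    ) -> "SpeciesTree":
        """Copy with branch parameters replaced (arrays indexed by node)."""
        tree = SpeciesTree(
            labels=list(self.labels),
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            durations=self.durations.copy() if durations is None else np.asarray(durations, float),
            birth_rates=None if birth_rates is None else np.asarray(birth_rates, float),
            gain_rates=None if gain_rates is None else np.asarray(gain_rates, float),
            outgroups=self.outgroups,
        )
        if tree.birth_rates is None and self.birth_rates is not None:
            tree.birth_rates = self.birth_rates.copy()
        if tree.gain_rates is None and self.gain_rates is not None:
            tree.gain_rates = self.gain_rates.copy()
        return tree

    def branch_table(self):
        """Per-branch parameter table (branch named by its child node)."""
        import pandas as pd

        rows = []
        for v in self.branch_nodes:
            rows.append(
                {
                    "branch": self.labels[int(v)],
                    "parent": self.labels[int(self.parent[v])],
                    "duration": float(self.durations[v]),
                    "birth_rate": float(self.birth_rates[v]) if self.birth_rates is not None else np.nan,
                    "gain_rate": float(self.gain_rates[v]) if self.gain_rates is not None else np.nan,
                    "loss_rate": 1.0,
                }
            )
        return pd.DataFrame(rows).set_index("branch")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        source: str,
        allow_polytomy: bool = False,
        outgroups: set[str] | frozenset[str] = frozenset(),
    ) -> "SpeciesTree":
        """Parse a rooted Newick string or file path.

        Branch lengths, if present, seed ``durations``; otherwise every
        branch starts at 1.0. Multifurcations raise unless *allow_polytomy*.
        """
        if "(" in source or ";" in source:
            handle = _io.StringIO(source)
        else:
            handle = open(source)
        with handle:
            try:
                dt = dendropy.Tree.get(
                    file=handle, schema="newick", suppress_internal_node_taxa=False
                )
            except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
                raise TreeError(f"duplicate leaf label in Newick input: {exc}") from exc
        nodes = list(dt.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        labels: list[str] = []
        seen: set[str] = set()
        n_internal = 0
        for n in nodes:
            name = None
            if n.taxon is not None and n.taxon.label:
                name = str(n.taxon.label)
            elif n.label:
                name = str(n.label)
            if n.is_leaf():
                if name is None:
                    raise TreeError("unlabeled leaf in Newick input")
                if name in seen:
                    raise TreeError(f"duplicate leaf label: {name!r}")
            else:
                if not allow_polytomy and len(n.child_nodes()) > 2:
                    where = name or f"internal node #{index[id(n)]}"
                    raise TreeError(
                        f"multifurcating node {where} "
                        "(pass allow_polytomy=True to accept)"
                    )
                if name is None or name in seen:
                    name = f"N{n_internal}"
                    while name in seen:
                        n_internal += 1
                        name = f"N{n_internal}"
                n_internal += 1
            seen.add(name)
            labels.append(name)
        parent = np.full(len(nodes), -1, dtype=int)
        children: list[list[int]] = [[] for _ in nodes]
        durations = np.ones(len(nodes))
        for n in nodes:
            i = index[id(n)]
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
                if n.edge.length is not None:
                    durations[i] = float(n.edge.length)
        return cls(
            labels=labels,
            parent=parent,
            children=children,
            durations=durations,
            outgroups=frozenset(outgroups),
        )

    def to_newick(self, with_lengths: bool = True) -> str:
        def rec(v: int) -> str:
            if self.is_leaf(v):
                s = self.labels[v]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")" + self.labels[v]
            if with_lengths and self.parent[v] >= 0:
                s += f":{self.durations[v]:.10g}"
            return s

        return rec(self.root) + ";"


def read_species_tree(
    path: str, allow_polytomy: bool = False, outgroups: set[str] = frozenset()
) -> SpeciesTree:
    """Read a rooted Newick tree file; see :meth:`SpeciesTree.from_newick`."""
    return SpeciesTree.from_newick(path, allow_polytomy=allow_polytomy, outgroups=outgroups)
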