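"""Dollo parsimony reconstruction on presence/absence profiles.

Under the Dollo criterion a family is gained exactly once and may be lost
any number of times. For a rooted tree the optimal reconstruction is
closed-form: the gain sits on the branch above the most recent common
ancestor of the present leaves, the family is present exactly on the
spanning subtree connecting those leaves, and one loss is charged to every
branch leaving the spanning subtree into a present-free clade. This gives
the unique minimal-loss single-gain scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import SpeciesTree

__all__ = ["DolloReconstruction", "dollo_reconstruct_family", "dollo_branch_totals"]


@dataclass
class DolloReconstruction:
    """Single-family Dollo scenario: origin node, loss branches, and the
    implied presence set (node indices)."""

    gain_node: int | None  # node below the gain branch; None for all-absent
    loss_branches: list[int]  # branches named by their child node
    present_nodes: set[int]

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


def dollo_reconstruct_family(presence, tree: SpeciesTree) -> DolloReconstruction:
    """Minimal-loss single-gain reconstruction of one presence profile.

    *presence* is a boolean array in the tree's leaf order (or a dict by
    leaf label). All-absent profiles yield the trivial empty scenario.
    """
    if isinstance(presence, dict):
        presence = [bool(presence[s]) for s in tree.leaf_labels]
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != (tree.n_leaves,):
        raise ValueError("presence vector length does not match leaves")
    present_leaves = [int(tree.leaf_indices[k]) for k in np.flatnonzero(presence)]
    if not present_leaves:
        return DolloReconstruction(None, [], set())
    origin = tree.mrca(present_leaves)
    # spanning subtree: union of paths origin -> present leaves
    span: set[int] = set()
    for leaf in present_leaves:
        v = leaf
        while v != origin and v not in span:
            span.add(v)
            v = int(tree.parent[v])
        span.add(origin)
    losses = []
    for v in sorted(span):
        for c in tree.children[v]:
            if c not in span:
                losses.append(c)
    return DolloReconstruction(origin, sorted(losses), span)


def dollo_branch_totals(
    presence_matrix,
    tree: SpeciesTree,
    count_root_origin: bool = False,
) -> pd.DataFrame:
    """Per-branch gain and loss totals over many families.

    *presence_matrix* is a DataFrame (families x species, truthy = present)
    or boolean array in leaf order. A family's gain is charged to the branch
    above its origin node; origins at the tree root have no branch above
    them and are counted only when *count_root_origin* (then charged to a
    pseudo-branch named after the root). Both conventions are visible:
    the returned frame's ``attrs['root_origins']`` holds the number of
    families whose origin is the root.
    """
    if isinstance(presence_matrix, pd.DataFrame):
        mat = presence_matrix[tree.leaf_labels].to_numpy().astype(bool)
    else:
        mat = np.asarray(presence_matrix, dtype=bool)
    labels = [tree.labels[int(v)] for v in tree.branch_nodes]
    gains = {lab: 0 for lab in labels}
    losses = {lab: 0 for lab in labels}
    root_origins = 0
    root_label = tree.labels[tree.root]
    if count_root_origin:
        gains.setdefault(root_label, 0)
        losses.setdefault(root_label, 0)
    for row in mat:
        rec = dollo_reconstruct_family(row, tree)
        if rec.gain_node is None:
            continue
        if rec.gain_node == tree.root:
            root_origins += 1
            if count_root_origin:
                gains[root_label] += 1
        else:
            gains[tree.labels[rec.gain_node]] += 1
        for b in rec.loss_branches:
            losses[tree.labels[b]] += 1
    out = pd.DataFrame(
        {"gains": pd.Series(gains), "losses": pd.Series(losses)}
    )
    out["net"] = out["gains"] - out["losses"]
    out.index.name = "branch"
    out.attrs["root_origins"] = root_origins
    out.attrs["count_root_origin"] = count_root_origin
    return out
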