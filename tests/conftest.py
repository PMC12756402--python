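import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from bdgphylo.io import ProfileMatrix
from bdgphylo.trees import SpeciesTree

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def taxa24_path() -> Path:
    return DATA / "holozoan_24taxa.nwk"


@pytest.fixture()
def toy_tree() -> SpeciesTree:
    """3-leaf tree with fixed branch rates for enumeration oracles."""
    t = SpeciesTree.from_newick("((A:0.4,B:0.7)N:0.3,C:0.6)R;")
    n = t.n_nodes
    return t.with_parameters(birth_rates=np.full(n, 0.3), gain_rates=np.full(n, 0.25))


@pytest.fixture()
def toy_profiles() -> ProfileMatrix:
    counts = pd.DataFrame(
        [[2, 0, 1], [0, 0, 3], [1, 1, 1], [0, 1, 0]],
        index=["f1", "f2", "f3", "f4"],
        columns=["A", "B", "C"],
    )
    return ProfileMatrix(counts)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def truncated_generator(birth: float, gain: float, loss: float, n_max: int) -> np.ndarray:
    """Generator of the birth-death-gain chain truncated at n_max (up-rate
    from the cap suppressed so rows sum to zero)."""
    K = n_max + 1
    Q = np.zeros((K, K))
    for n in range(K):
        up = gain + birth * n
        down = loss * n
        if n < n_max:
            Q[n, n + 1] = up
        if n > 0:
            Q[n, n - 1] = down
        Q[n, n] = -(up if n < n_max else 0.0) - down
    return Q


def expm_transition(birth, gain, loss, t, n_max) -> np.ndarray:
    from scipy.linalg import expm

    return expm(truncated_generator(birth, gain, loss, n_max) * t)


def enumerate_joint(tree: SpeciesTree, mats: dict, prior: np.ndarray, leaf_counts: dict):
    """Brute-force joint distribution over internal node states given fixed
    leaf counts; returns (per-node marginal dict, per-branch joint dict,
    total likelihood)."""
    K = len(prior) - 1
    n = tree.n_nodes
    internals = [v for v in range(n) if not tree.is_leaf(v)]
    marg = {v: np.zeros(K + 1) for v in range(n)}
    joint = {int(v): np.zeros((K + 1, K + 1)) for v in tree.branch_nodes}
    for assign in itertools.product(range(K + 1), repeat=len(internals)):
        states = dict(zip(internals, assign))
        for v in tree.leaf_indices:
            v = int(v)
            states[v] = leaf_counts[tree.labels[v]]
        p = prior[states[tree.root]]
        for v in tree.branch_nodes:
            v = int(v)
            p *= mats[v][states[int(tree.parent[v])], states[v]]
        for v in range(n):
            marg[v][states[v]] += p
        for v in tree.branch_nodes:
            v = int(v)
            joint[v][states[int(tree.parent[v])], states[v]] += p
    total = marg[tree.root].sum()
    return marg, joint, total


def dollo_brute_force(presence: np.ndarray, tree: SpeciesTree):
    """Minimal losses over all Dollo-valid assignments (single gain) by
    exhaustive enumeration of internal presence states."""
    n = tree.n_nodes
    internals = [v for v in range(n) if not tree.is_leaf(v)]
    leaf_state = {}
    for k, v in enumerate(tree.leaf_indices):
        leaf_state[int(v)] = bool(presence[k])
    if not any(leaf_state.values()):
        return 0, None
    best = None
    best_origin = None
    for assign in itertools.product([0, 1], repeat=len(internals)):
        states = dict(zip(internals, assign))
        states.update(leaf_state)
        gains = int(states[tree.root])  # present at root counts as the gain
        losses = 0
        for v in tree.branch_nodes:
            v = int(v)
            u = int(tree.parent[v])
            if not states[u] and states[v]:
                gains += 1
            if states[u] and not states[v]:
                losses += 1
        if gains != 1:
            continue
        if best is None or losses < best:
            best = losses
            if states[tree.root]:
                best_origin = tree.root
            else:
                best_origin = next(
                    int(v)
                    for v in tree.branch_nodes
                    if states[int(v)] and not states[int(tree.parent[int(v)])]
                )
    return best, best_origin


def random_binary_tree(labels: list[str], rng: np.random.Generator, with_rates=False):
    parts = list(labels)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a}:{rng.uniform(0.2, 0.8):.3f},{b}:{rng.uniform(0.2, 0.8):.3f})")
    tree = SpeciesTree.from_newick(parts[0] + ";")
    if with_rates:
        n = tree.n_nodes
        tree = tree.with_parameters(
            birth_rates=np.full(n, 0.3), gain_rates=np.full(n, 0.2)
        )
    return tree
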