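"""Lineage-level summaries of inferred family events.

Turns per-family event posteriors into expected per-branch change accounts,
classifies each lineage into an evolutionary mode (expansion, remodeling,
specialization, streamlining), calls high-confidence per-family events, and
censuses parallel (repeated independent) gains and losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "branch_change_summary",
    "classify_mode",
    "classify_modes",
    "ModeLabel",
    "call_high_confidence_events",
    "parallel_event_census",
]

MODES = ("Expansion", "Streamlining", "Specialization", "Remodeling", "Unclassified")


def branch_change_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Expected per-branch event counts and net changes.

    *events* is a per-family, per-branch table with columns
    ``p_origination/p_extinction/p_expansion/p_contraction`` (as produced by
    :meth:`BDGResults.branch_events`). Returns per-branch expected gains G,
    losses X, expansions E, contractions K, net family change G - X, and
    net multicopy change E - K.
    """
    need = {"branch", "p_origination", "p_extinction", "p_expansion", "p_contraction"}
    missing = need - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    g = events.groupby("branch")[
        ["p_origination", "p_extinction", "p_expansion", "p_contraction"]
    ].sum()
    out = g.rename(
        columns={
            "p_origination": "gains",
            "p_extinction": "losses",
            "p_expansion": "expansions",
            "p_contraction": "contractions",
        }
    )
    out["net_families"] = out["gains"] - out["losses"]
    out["net_multicopy"] = out["expansions"] - out["contractions"]
    return out


@dataclass(frozen=True)
class ModeLabel:
    """Evolutionary-mode call for one lineage, with its rule terms."""

    label: str
    terms: dict

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def classify_mode(
    gains: float, losses: float, expansions: float, contractions: float
) -> ModeLabel:
    """Classify one lineage by the four expected-event totals.

    Rules (G gains, X losses, E expansions, K contractions):

    - Expansion: G >= 2X and E >= 2K
    - Streamlining: X >= 2G and E <= 1.2K
    - Specialization: X >= 2G and E >= 2K
    - Remodeling: |G - X| < 0.6 (G + X) and E > K

    Evaluated in the precedence order Expansion -> Streamlining ->
    Specialization -> Remodeling; lineages matching none are Unclassified.
    """
    G, X, E, K = (float(v) for v in (gains, losses, expansions, contractions))
    if min(G, X, E, K) < 0:
        raise ValueError("event totals must be non-negative")
    terms = {
        "G": G,
        "X": X,
        "E": E,
        "K": K,
        "expansion_rule": G >= 2 * X and E >= 2 * K,
        "streamlining_rule": X >= 2 * G and E <= 1.2 * K,
        "specialization_rule": X >= 2 * G and E >= 2 * K,
        "remodeling_rule": abs(G - X) < 0.6 * (G + X) and E > K,
    }
    if G + X == 0:
        terms["note"] = "no family events on this branch"
        return ModeLabel("Unclassified", terms)
    for label, key in (
        ("Expansion", "expansion_rule"),
        ("Streamlining", "streamlining_rule"),
        ("Specialization", "specialization_rule"),
        ("Remodeling", "remodeling_rule"),
    ):
        if terms[key]:
            return ModeLabel(label, terms)
    return ModeLabel("Unclassified", terms)


def classify_modes(summary: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`classify_mode` to every row of a branch change summary."""
    rows = {}
    for branch, r in summary.iterrows():
        m = classify_mode(r["gains"], r["losses"], r["expansions"], r["contractions"])
        rows[branch] = {"mode": m.label, **m.terms}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "branch"
    return out


def call_high_confidence_events(
    events: pd.DataFrame, threshold: float = 0.6
) -> pd.DataFrame:
    """High-confidence per-family gain/loss calls.

    The score is Pr(gain) - Pr(loss) on a family-branch; a gain is called
    when the score strictly exceeds *threshold* and a loss when it is
    strictly below -*threshold* (at most one call per family-branch).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    score = events["p_origination"] - events["p_extinction"]
    out = events[["family", "branch"]].copy()
    out["score"] = score
    out["type"] = np.where(score > threshold, "gain", np.where(score < -threshold, "loss", ""))
    out = out.loc[out["type"] != ""].reset_index(drop=True)
    return out


def parallel_event_census(calls: pd.DataFrame) -> dict:
    """Census of families with repeated independent gains or losses.

    A family with >= 2 high-confidence gain calls counts as a parallel-gain
    family, and all of its gain calls count as parallel gains (losses
    analogously). Returns the four headline counts plus per-family tables.
    """
    out = {}
    for etype, plural in (("gain", "gains"), ("loss", "losses")):
        sub = calls.loc[calls["type"] == etype]
        per_family = sub.groupby("family").size()
        multi = per_family[per_family >= 2]
        out[f"families_with_parallel_{plural}"] = int(len(multi))
        out[f"parallel_{etype}_events"] = int(multi.sum())
        out[f"per_family_{plural}"] = multi.sort_values(ascending=False)
    return out
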