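"""Ancestral-state and branch-event posteriors against exhaustive enumeration."""

import numpy as np
import pandas as pd
import pytest

from bdgphylo.io import ProfileMatrix
from bdgphylo.model import BDGResults, BirthDeathGainModel, FitResult
from bdgphylo.process import (
    LikelihoodEngine,
    RateVariationModel,
    TruncationPolicy,
    branch_transition_matrix,
    root_prior_vector,
)
from bdgphylo.trees import SpeciesTree

from conftest import enumerate_joint


def _fixed_results(pm, tree, phi, rvm=None, n_max=1):
    """BDGResults at prescribed parameters (no fitting)."""
    model = BirthDeathGainModel(
        pm,
        tree,
        rate_variation=rvm,
        condition_on_observed=False,
        truncation=TruncationPolicy(n_max=n_max, tail_tol=1.0),
    )
    eng = LikelihoodEngine(model.tree.with_parameters(
        birth_rates=tree.birth_rates, gain_rates=tree.gain_rates
    ), model.truncation)
    ll, _, _, unc = eng.mixture_loglik(model.counts, phi, rvm, False)
    fit = FitResult(
        phi=phi,
        tree=tree,
        rate_variation=rvm,
        loglik=float(ll.sum()),
        loglik_unconditioned=float(unc.sum()),
        family_status=pd.Series("ok", index=pm.families),
        n_max_used=model.truncation.n_max,
    )
    return model, BDGResults(model, fit)


class TestAncestralStates:
    def test_leaf_nodes_are_observed_indicators(self, toy_tree, toy_profiles):
        _, res = _fixed_results(toy_profiles, toy_tree, 0.7)
        anc = res.ancestral_states()
        counts = toy_profiles.counts
        for fam in counts.index:
            for leaf in counts.columns:
                row = anc[(anc.family == fam) & (anc.node == leaf)].iloc[0]
                c = counts.loc[fam, leaf]
                expect = [c == 0, c == 1, c > 1]
                assert np.allclose(
                    row[["p_absent", "p_single", "p_multi"]].astype(float), expect
                )

    def test_probabilities_sum_to_one(self, toy_tree, toy_profiles):
        _, res = _fixed_results(toy_profiles, toy_tree, 0.7)
        anc = res.ancestral_states()
        sums = anc[["p_absent", "p_single", "p_multi"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-8)

    def test_matches_exhaustive_enumeration(self, toy_tree, toy_profiles):
        model, res = _fixed_results(toy_profiles, toy_tree, 0.7)
        K = model.truncation.n_max
        anc = res.ancestral_states()
        mats = {
            int(v): branch_transition_matrix(
                0.3, 0.25, 1.0, toy_tree.durations[int(v)], K
            )
            for v in toy_tree.branch_nodes
        }
        prior = root_prior_vector(0.7, K)
        for fam in toy_profiles.families:
            leaf_counts = toy_profiles.counts.loc[fam].to_dict()
            marg, _, total = enumerate_joint(toy_tree, mats, prior, leaf_counts)
            for v in range(toy_tree.n_nodes):
                m = marg[v] / total
                expect = [m[0], m[1], m[2:].sum()]
                got = anc[
                    (anc.family == fam) & (anc.node == toy_tree.labels[v])
                ][["p_absent", "p_single", "p_multi"]].to_numpy()[0]
                assert np.allclose(got, expect, atol=1e-8)


class TestBranchEvents:
    def test_matches_exhaustive_enumeration(self, toy_tree, toy_profiles):
        model, res = _fixed_results(toy_profiles, toy_tree, 0.7)
        K = model.truncation.n_max
        ev = res.branch_events()
        mats = {
            int(v): branch_transition_matrix(
                0.3, 0.25, 1.0, toy_tree.durations[int(v)], K
            )
            for v in toy_tree.branch_nodes
        }
        prior = root_prior_vector(0.7, K)
        for fam in toy_profiles.families:
            leaf_counts = toy_profiles.counts.loc[fam].to_dict()
            _, joint, total = enumerate_joint(toy_tree, mats, prior, leaf_counts)
            for v in toy_tree.branch_nodes:
                v = int(v)
                J = joint[v] / total
                row = ev[(ev.family == fam) & (ev.branch == toy_tree.labels[v])].iloc[0]
                assert np.allclose(
                    [row.p_origination, row.p_extinction, row.p_expansion, row.p_contraction],
                    [J[0, 1:].sum(), J[1:, 0].sum(), J[1, 2:].sum(), J[2:, 1].sum()],
                    atol=1e-8,
                )

    def test_event_classes_partition(self, toy_tree, toy_profiles):
        _, res = _fixed_results(toy_profiles, toy_tree, 0.7)
        ev = res.branch_events()
        s = ev[["p_origination", "p_extinction", "p_expansion", "p_contraction", "p_none"]].sum(axis=1)
        assert np.allclose(s, 1.0, atol=1e-8)

    def test_flow_conservation(self, toy_tree, toy_profiles):
        """Expected presence at a child equals expected presence at its
        parent plus Pr(origination) minus Pr(extinction)."""
        _, res = _fixed_results(toy_profiles, toy_tree, 0.7)
        anc = res.ancestral_states().set_index(["family", "node"])
        ev = res.branch_events()
        for _, row in ev.iterrows():
            child = anc.loc[(row.family, row.branch)]
            parent_label = toy_tree.labels[
                int(toy_tree.parent[toy_tree.label_index(row.branch)])
            ]
            parent = anc.loc[(row.family, parent_label)]
            lhs = 1.0 - child.p_absent
            rhs = 1.0 - parent.p_absent + row.p_origination - row.p_extinction
            assert abs(lhs - rhs) < 1e-6

    def test_origination_vanishes_without_gain(self):
        tree = SpeciesTree.from_newick("(A:0.6,B:0.6)r;")
        tree = tree.with_parameters(
            birth_rates=np.full(3, 0.3), gain_rates=np.full(3, 1e-9)
        )
        pm = ProfileMatrix(
            pd.DataFrame([[0, 0]], index=["f"], columns=["A", "B"])
        )
        _, res = _fixed_results(pm, tree, 0.5)
        ev = res.branch_events()
        assert (ev.p_origination < 1e-6).all()

    def test_mixture_posteriors_are_weighted_averages(self, toy_tree, toy_profiles):
        """With two rate categories, event posteriors are the category
        posteriors' weighted mix of per-category posteriors."""
        rvm = RateVariationModel(n_categories=2, shapes={"sigma": 0.8}, enabled=("sigma",))
        model, res = _fixed_results(toy_profiles, toy_tree, 0.7, rvm=rvm)
        ev = res.branch_events()
        from bdgphylo.process import FamilyRateFactors

        mids = rvm.midpoints("sigma")
        eng = LikelihoodEngine(res.tree, model.truncation)
        _, post, _, _ = eng.mixture_loglik(model.counts, 0.7, rvm, False)
        per_cat = []
        for m in mids:
            model_c = BirthDeathGainModel(
                toy_profiles, toy_tree, rate_variation=None,
                condition_on_observed=False, truncation=model.truncation,
            )
            # per-category engine: scale all rates by the category midpoint
            scaled = toy_tree.with_parameters(
                durations=toy_tree.durations * m,
                birth_rates=toy_tree.birth_rates,
                gain_rates=toy_tree.gain_rates,
            )
            fit_c = FitResult(
                phi=0.7, tree=scaled, rate_variation=None,
                loglik=0.0, loglik_unconditioned=0.0,
                family_status=pd.Series("ok", index=toy_profiles.families),
            )
            per_cat.append(BDGResults(model_c, fit_c).branch_events())
        fam0 = toy_profiles.families[0]
        b = toy_tree.labels[int(toy_tree.branch_nodes[0])]
        mixed = res.branch_events()
        got = mixed[(mixed.family == fam0) & (mixed.branch == b)].p_origination.iloc[0]
        parts = [
            pc[(pc.family == fam0) & (pc.branch == b)].p_origination.iloc[0]
            for pc in per_cat
        ]
        expect = post[0, 0] * parts[0] + post[0, 1] * parts[1]
        assert abs(got - expect) < 1e-8

    def test_expected_counts_bounded_by_family_number(self, toy_tree, toy_profiles):
        _, res = _fixed_results(toy_profiles, toy_tree, 0.7)
        ev = res.expected_event_counts()
        assert (ev.to_numpy() <= len(toy_profiles.families) + 1e-9).all()
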