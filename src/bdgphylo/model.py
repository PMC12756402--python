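"""Statsmodels-style model and results objects for the birth-death-gain fit.

``BirthDeathGainModel`` binds a profile matrix to a species tree;
``fit()`` performs staged maximum-likelihood estimation (homogeneous ->
branch-specific -> branch + family rate variation, each warm-starting the
next, iterating until the log-likelihood gain per round drops below a
tolerance) and returns a ``BDGResults`` carrying the estimates, the
per-family rate-category posteriors, ancestral-state posteriors and branch
event posteriors, with TSV/JSON export and a text ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ProfileMatrix
from .process import (
    PARAMETERS,
    FamilyRateFactors,
    LikelihoodEngine,
    ProcessError,
    RateVariationModel,
    TruncationError,
    TruncationPolicy,
)
from .trees import SpeciesTree

__all__ = ["BirthDeathGainModel", "BDGResults", "FitResult"]

# loss rate is 1 by scaling, so other rates/durations live near unity;
# bounds are generous but keep the truncated state space tractable
_LOG_BOUNDS = (np.log(1e-3), np.log(30.0))
_SHAPE_BOUNDS = (np.log(0.05), np.log(50.0))

STAGES = ("homogeneous", "branch", "family")

CLASS_SLICES = ("absent", "single", "multi")


@dataclass
class FitResult:
    """Fitted parameters plus the convergence record of each stage."""

    phi: float
    tree: SpeciesTree  # carries fitted durations / birth / gain rates
    rate_variation: RateVariationModel | None
    loglik: float
    loglik_unconditioned: float
    stage_traces: dict = field(default_factory=dict)  # stage -> [loglik per round]
    converged: bool = True
    family_status: pd.Series | None = None  # ok | failed per family
    n_max_used: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "phi": self.phi,
            "loglik": self.loglik,
            "loglik_unconditioned": self.loglik_unconditioned,
            "converged": self.converged,
            "n_max_used": self.n_max_used,
            "stage_traces": self.stage_traces,
            "branches": {
                self.tree.labels[int(v)]: {
                    "duration": float(self.tree.durations[v]),
                    "birth_rate": float(self.tree.birth_rates[v]),
                    "gain_rate": float(self.tree.gain_rates[v]),
                }
                for v in self.tree.branch_nodes
            },
            "rate_variation": None
            if self.rate_variation is None
            else {
                "n_categories": self.rate_variation.n_categories,
                "enabled": list(self.rate_variation.enabled),
                "shapes": {k: float(v) for k, v in self.rate_variation.shapes.items()},
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class BirthDeathGainModel:
    """Birth-death-gain model for family copy-number profiles on a tree.

    Parameters
    ----------
    profiles : ProfileMatrix or DataFrame
        Non-negative integer counts, families x species. Only families with
        status ``kept`` enter the likelihood when a ProfileMatrix is given.
    tree : SpeciesTree
        Rooted topology. Newick lengths (if any) seed the durations.
    rate_variation : RateVariationModel or None
        Family-rate heterogeneity used by the final stage; default C=2
        categories on all four factors.
    condition_on_observed : bool
        Divide each family likelihood by Pr(profile not all-zero).
    """

    def __init__(
        self,
        profiles,
        tree: SpeciesTree,
        rate_variation: RateVariationModel | None = None,
        condition_on_observed: bool = True,
        truncation: TruncationPolicy = TruncationPolicy(),
    ):
        if isinstance(profiles, pd.DataFrame):
            profiles = ProfileMatrix(profiles)
        profiles.validate_against_tree(tree)
        self.profiles = profiles
        self.tree = tree
        self.counts = profiles.aligned_counts(tree).to_numpy()
        self.family_ids = profiles.kept.index
        if self.counts.shape[0] == 0:
            raise ProcessError("no kept families to fit")
        if rate_variation is None:
            rate_variation = RateVariationModel(n_categories=2)
        self.rate_variation = rate_variation
        self.condition_on_observed = condition_on_observed
        n_max = max(truncation.n_max, int(self.counts.max()) + 5)
        self.truncation = replace(truncation, n_max=n_max)
        self._base_durations = tree.durations.copy()
        self._n_max_hint = n_max  # sticky truncation size across engine rebuilds

    @classmethod
    def from_files(cls, tree_path: str, profile_path: str, **kwargs) -> "BirthDeathGainModel":
        from .io import read_profile_matrix
        from .trees import read_species_tree

        return cls(read_profile_matrix(profile_path), read_species_tree(tree_path), **kwargs)

    # -- likelihood -------------------------------------------------------
    def _engine(self, durations, birth, gain) -> LikelihoodEngine:
        tree = self.tree.with_parameters(durations=durations, birth_rates=birth, gain_rates=gain)
        eng = LikelihoodEngine(tree, self.truncation)
        eng._n_max_hint = self._n_max_hint
        return eng

    def loglike(
        self,
        phi: float,
        durations: np.ndarray,
        birth_rates: np.ndarray,
        gain_rates: np.ndarray,
        rvm: RateVariationModel | None,
    ) -> float:
        eng = self._engine(durations, birth_rates, gain_rates)
        ll, _, _, _ = eng.mixture_loglik(self.counts, phi, rvm, self.condition_on_observed)
        self._n_max_hint = eng._n_max_hint
        # periodically forget the truncation hint so an oversized excursion
        # during optimization does not pin later evaluations at a large cap
        self._evals = getattr(self, "_evals", 0) + 1
        if self._evals % 64 == 0:
            self._n_max_hint = self.truncation.n_max
        return float(np.sum(ll))

    # -- parameter packing ------------------------------------------------
    def _unpack(self, x: np.ndarray, stage: str, state: dict):
        n = self.tree.n_nodes
        bn = self.tree.branch_nodes
        durations = state["durations"].copy()
        birth = state["birth"].copy()
        gain = state["gain"].copy()
        if stage == "homogeneous":
            phi, lam, kap, tau = np.exp(x)
            durations[bn] = tau * self._base_durations[bn]
            birth[:] = lam
            gain[:] = kap
            rvm = None
        else:
            nb = len(bn)
            phi = np.exp(x[0])
            durations[bn] = np.exp(x[1 : 1 + nb])
            birth[bn] = np.exp(x[1 + nb : 1 + 2 * nb])
            gain[bn] = np.exp(x[1 + 2 * nb : 1 + 3 * nb])
            if stage == "family":
                shapes = np.exp(x[1 + 3 * nb :])
                rvm = RateVariationModel(
                    n_categories=self.rate_variation.n_categories,
                    shapes={
                        p: float(s)
                        for p, s in zip(self.rate_variation.enabled, shapes)
                    },
                    enabled=self.rate_variation.enabled,
                )
            else:
                rvm = None
        return float(phi), durations, birth, gain, rvm

    def _pack(self, stage: str, state: dict) -> tuple[np.ndarray, list]:
        bn = self.tree.branch_nodes
        lo, hi = _LOG_BOUNDS
        if stage == "homogeneous":
            x = np.log(
                [
                    state["phi"],
                    float(np.mean(state["birth"][bn])),
                    float(np.mean(state["gain"][bn])),
                    state.get("tau", 1.0),
                ]
            )
            bounds = [(lo, hi)] * 4
        else:
            parts = [
                [np.log(state["phi"])],
                np.log(state["durations"][bn]),
                np.log(state["birth"][bn]),
                np.log(state["gain"][bn]),
            ]
            bounds = [(lo, hi)] * (1 + 3 * len(bn))
            if stage == "family":
                shapes = [
                    state["shapes"].get(p, 1.0) for p in self.rate_variation.enabled
                ]
                parts.append(np.log(shapes))
                bounds += [_SHAPE_BOUNDS] * len(shapes)
            x = np.concatenate([np.asarray(p, dtype=float) for p in parts])
        return x, bounds

    def _blocks(self, stage: str, n_params: int) -> list[np.ndarray]:
        """Coordinate-descent blocks: one global block (root prior, and
        gamma shapes in the family stage), then (t_b, lambda_b, kappa_b)
        per branch."""
        if stage == "homogeneous":
            return [np.arange(n_params)]
        nb = len(self.tree.branch_nodes)
        glob = [0] + list(range(1 + 3 * nb, n_params))
        blocks = [np.asarray(glob)]
        for i in range(nb):
            blocks.append(np.asarray([1 + i, 1 + nb + i, 1 + 2 * nb + i]))
        return blocks

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        stages: tuple = STAGES,
        tol: float = 0.01,
        max_rounds: int = 12,
        maxiter_per_round: int = 10,
        start: dict | None = None,
        restarts: int = 1,
        seed: int | None = None,
        verbose: bool = False,
    ) -> "BDGResults":
        """Staged maximum-likelihood fit.

        Each stage runs rounds of bounded quasi-Newton (L-BFGS-B on
        log-parameters) until the log-likelihood improves by less than
        *tol* between consecutive rounds, then hands its estimates to the
        next stage as a warm start.
        """
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        rng = np.random.default_rng(seed)
        best = None
        for restart in range(max(1, restarts)):
            state = self._initial_state(start)
            if restart > 0:
                jitter = rng.lognormal(0.0, 0.3, size=3)
                state["phi"] *= jitter[0]
                state["birth"] = state["birth"] * jitter[1]
                state["gain"] = state["gain"] * jitter[2]
            result = self._fit_once(state, stages, tol, max_rounds, maxiter_per_round, verbose)
            if best is None or result.loglik > best.loglik:
                best = result
        return BDGResults(self, best)

    def _initial_state(self, start: dict | None) -> dict:
        n = self.tree.n_nodes
        mean_count = max(float(self.counts.mean()), 0.05)
        state = {
            "phi": max(mean_count, 0.1),
            "durations": self._base_durations.copy(),
            "birth": np.full(n, 0.3),
            "gain": np.full(n, 0.3),
            "tau": 1.0,
            "shapes": {p: 1.0 for p in self.rate_variation.enabled},
        }
        if start:
            state.update(start)
        return state

    def _fit_once(self, state, stages, tol, max_rounds, maxiter_per_round, verbose) -> FitResult:
        traces: dict[str, list[float]] = {}
        converged = True
        final_rvm = None
        for stage in stages:
            x, bounds = self._pack(stage, state)
            bounds = np.asarray(bounds)

            def negll(xv, stage=stage, state=state):
                phi, dur, bir, gai, rvm = self._unpack(xv, stage, state)
                try:
                    val = self.loglike(phi, dur, bir, gai, rvm)
                except TruncationError as exc:
                    # graded penalty: slopes back toward the feasible region
                    return 1e8 * (1.0 + exc.excess)
                except (ProcessError, FloatingPointError):
                    return 1e12
                if not np.isfinite(val):
                    return 1e12
                return -val

            trace = [-negll(x)]
            if not np.isfinite(trace[0]) or trace[0] <= -1e11:
                raise ProcessError(
                    f"non-finite likelihood at the start of stage {stage!r}"
                )
            blocks = self._blocks(stage, len(x))
            fcur = -trace[0]
            for _ in range(max_rounds):
                # one round = a coordinate-descent sweep over parameter blocks;
                # the global block (root prior + gamma shapes) gets a deeper
                # inner optimization since branch blocks arrive warm-started
                for bi, idx in enumerate(blocks):
                    def block_negll(sub, idx=idx, x=x):
                        xv = x.copy()
                        xv[idx] = sub
                        return negll(xv)

                    miter = 3 * maxiter_per_round if bi == 0 else maxiter_per_round
                    res = optimize.minimize(
                        block_negll,
                        x[idx],
                        method="L-BFGS-B",
                        bounds=bounds[idx],
                        options={"maxiter": miter, "ftol": 1e-8, "maxls": 10},
                    )
                    if res.fun <= fcur:
                        x[idx] = res.x
                        fcur = res.fun
                trace.append(-fcur)
                if trace[-1] - trace[-2] < tol:
                    break
            else:
                converged = False
            traces[stage] = trace
            phi, dur, bir, gai, rvm = self._unpack(x, stage, state)
            state = dict(state)
            state["phi"] = phi
            state["durations"] = dur
            state["birth"] = bir
            state["gain"] = gai
            if rvm is not None:
                state["shapes"] = dict(rvm.shapes)
            final_rvm = rvm
            if verbose:
                print(f"stage {stage}: loglik {trace[-1]:.3f} after {len(trace) - 1} rounds")

        fitted_tree = self.tree.with_parameters(
            durations=state["durations"],
            birth_rates=state["birth"],
            gain_rates=state["gain"],
        )
        eng = LikelihoodEngine(fitted_tree, self.truncation)
        ll, _, _, uncond = eng.mixture_loglik(
            self.counts, state["phi"], final_rvm, self.condition_on_observed
        )
        status = pd.Series(
            np.where(np.isfinite(ll), "ok", "failed"), index=self.family_ids, name="status"
        )
        return FitResult(
            phi=state["phi"],
            tree=fitted_tree,
            rate_variation=final_rvm,
            loglik=float(ll[np.isfinite(ll)].sum()),
            loglik_unconditioned=float(uncond[np.isfinite(uncond)].sum()),
            stage_traces=traces,
            converged=converged,
            family_status=status,
            n_max_used=self.truncation.n_max,
        )


class BDGResults:
    """Results of a :class:`BirthDeathGainModel` fit.

    Exposes the fitted parameters plus lazily computed posterior tables:
    per-family rate-category posteriors, ancestral-state posteriors
    collapsed to {absent, single, multi}, and branch event posteriors
    (origination / extinction / expansion / contraction).
    """

    def __init__(self, model: BirthDeathGainModel, fit: FitResult):
        self.model = model
        self.fit_result = fit
        self._pass2 = None

    # ------------------------------------------------------------------
    @property
    def llf(self) -> float:
        return self.fit_result.loglik

    @property
    def phi(self) -> float:
        return self.fit_result.phi

    @property
    def tree(self) -> SpeciesTree:
        return self.fit_result.tree

    @property
    def family_status(self) -> pd.Series:
        return self.fit_result.family_status

    @property
    def ok_families(self) -> pd.Index:
        return self.family_status.index[self.family_status == "ok"]

    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            "Birth-Death-Gain model fit",
            "==========================",
            f"families: {len(self.model.family_ids)} "
            f"(failed: {int((fr.family_status == 'failed').sum())})",
            f"leaves: {self.model.tree.n_leaves}   branches: {len(self.model.tree.branch_nodes)}",
            f"log-likelihood (conditioned): {fr.loglik:.3f}",
            f"log-likelihood (unconditioned): {fr.loglik_unconditioned:.3f}",
            f"root Poisson mean phi: {fr.phi:.4f}",
            f"truncation n_max: {fr.n_max_used}",
            f"converged: {fr.converged}",
        ]
        if fr.rate_variation is not None:
            rv = fr.rate_variation
            lines.append(f"family rate variation: C={rv.n_categories} on {', '.join(rv.enabled)}")
            for p in rv.enabled:
                mids = rv.midpoints(p)
                lines.append(
                    f"  {p}: shape={rv.shapes[p]:.3f} midpoints="
                    + "/".join(f"{m:.3f}" for m in mids)
                )
        for stage, tr in fr.stage_traces.items():
            lines.append(f"stage {stage}: loglik {tr[0]:.2f} -> {tr[-1]:.2f} in {len(tr) - 1} rounds")
        lines.append(self.tree.branch_table().to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    # -- pass 2 ---------------------------------------------------------
    def _run_pass2(self):
        if self._pass2 is not None:
            return self._pass2
        model, fr = self.model, self.fit_result
        eng = LikelihoodEngine(fr.tree, model.truncation)
        counts = model.counts
        F = counts.shape[0]
        rvm = fr.rate_variation
        _, post_w, index_maps, _ = eng.mixture_loglik(
            counts, fr.phi, rvm, model.condition_on_observed
        )
        if rvm is None:
            combos = [FamilyRateFactors()]
        else:
            combos, _, _ = rvm.combinations()

        tree = fr.tree
        n_nodes = tree.n_nodes
        node_class = np.zeros((F, n_nodes, 3))
        branch_joint = np.zeros((F, n_nodes, 3, 3))  # indexed by child node
        ok = np.ones(F, dtype=bool)
        for k, fac in enumerate(combos):
            ll, aux = eng.loglik_given_category(counts, fr.phi, fac, return_messages=True)
            ok &= np.isfinite(ll)
            mats, prior, n_max = aux["mats"], aux["prior"], aux["n_max"]
            L, msg = aux["L"], aux["msg"]
            slc = [np.array([0]), np.array([1]), np.arange(2, n_max + 1)]
            w = post_w[:, k][:, None]
            # outside pass
            O: dict[int, np.ndarray] = {int(tree.root): np.broadcast_to(prior, (F, n_max + 1)).copy()}
            for u in tree.preorder:
                u = int(u)
                Ou = O[u]
                kids = tree.children[u]
                for v in kids:
                    Q = Ou.copy()
                    for wch in kids:
                        if wch != v:
                            Q = Q * msg[wch]
                    # joint class table on branch (u, v); normalized per
                    # family before mixing so per-combo scalings cancel
                    Jc = np.empty((F, 3, 3))
                    Mv = [L[v][:, slc_y] @ mats[v][:, slc_y].T for slc_y in slc]
                    for xi_, slc_x in enumerate(slc):
                        Qx = Q[:, slc_x]
                        for yi, My in enumerate(Mv):
                            Jc[:, xi_, yi] = np.einsum("fa,fa->f", Qx, My[:, slc_x])
                    jt = Jc.sum(axis=(1, 2), keepdims=True)
                    Jc = Jc / np.where(jt > 0, jt, 1.0)
                    branch_joint[:, v] += w[:, 0][:, None, None] * Jc
                    O[v] = Q @ mats[v]
                    s = O[v].max(axis=1)
                    s = np.where(s > 0, s, 1.0)
                    O[v] = O[v] / s[:, None]
                post = O[u] * L[u]
                tot = post.sum(axis=1, keepdims=True)
                tot = np.where(tot > 0, tot, 1.0)
                post = post / tot
                for ci, slc_c in enumerate(slc):
                    node_class[:, u, ci] += w[:, 0] * post[:, slc_c].sum(axis=1)
        # normalize joint tables (scales cancel per family-branch)
        sums = branch_joint.sum(axis=(2, 3), keepdims=True)
        sums = np.where(sums > 0, sums, 1.0)
        branch_joint = branch_joint / sums
        tots = node_class.sum(axis=2, keepdims=True)
        tots = np.where(tots > 0, tots, 1.0)
        node_class = node_class / tots
        self._pass2 = {
            "node_class": node_class,
            "branch_joint": branch_joint,
            "post_w": post_w,
            "index_maps": index_maps,
            "ok": ok,
        }
        return self._pass2

    def family_rate_posteriors(self) -> pd.DataFrame:
        """Per-family slow/fast posteriors, expected factors and scaled rates.

        Expected factor of parameter pi: sum_c p_f(pi_c) * pi_c over its
        categories; scaled rates are sigma*birth, sigma*gain, sigma*loss.
        """
        p2 = self._run_pass2()
        fr = self.fit_result
        rvm = fr.rate_variation
        post_w, index_maps = p2["post_w"], p2["index_maps"]
        F = post_w.shape[0]
        out = pd.DataFrame(index=self.model.family_ids)
        expected = {}
        for p in PARAMETERS:
            if rvm is None or p not in rvm.enabled:
                expected[p] = np.ones(F)
                continue
            mids = rvm.midpoints(p)
            marg = np.zeros((F, len(mids)))
            for k, im in enumerate(index_maps):
                marg[:, im[p]] += post_w[:, k]
            for c in range(len(mids)):
                out[f"p_{p}_cat{c}"] = marg[:, c]
            expected[p] = marg @ mids
        for p in PARAMETERS:
            out[p] = expected[p]
        out["scaled_birth"] = expected["sigma"] * expected["birth"]
        out["scaled_gain"] = expected["sigma"] * expected["gain"]
        out["scaled_loss"] = expected["sigma"] * expected["loss"]
        out["status"] = self.family_status
        return out

    def ancestral_states(self) -> pd.DataFrame:
        """Per-family, per-node posterior of {absent, single, multi}."""
        p2 = self._run_pass2()
        nc = p2["node_class"]
        tree = self.tree
        recs = []
        fam_ok = self.family_status.to_numpy() == "ok"
        for fi, fam in enumerate(self.model.family_ids):
            if not fam_ok[fi]:
                continue
            for v in range(tree.n_nodes):
                recs.append(
                    (fam, tree.labels[v], nc[fi, v, 0], nc[fi, v, 1], nc[fi, v, 2])
                )
        return pd.DataFrame(
            recs, columns=["family", "node", "p_absent", "p_single", "p_multi"]
        )

    def branch_events(self) -> pd.DataFrame:
        """Per-family, per-branch posterior event probabilities."""
        p2 = self._run_pass2()
        J = p2["branch_joint"]
        tree = self.tree
        fam_ok = self.family_status.to_numpy() == "ok"
        recs = []
        for fi, fam in enumerate(self.model.family_ids):
            if not fam_ok[fi]:
                continue
            for v in tree.branch_nodes:
                v = int(v)
                j = J[fi, v]
                recs.append(
                    (
                        fam,
                        tree.labels[v],
                        j[0, 1] + j[0, 2],  # origination: 0 -> >=1
                        j[1, 0] + j[2, 0],  # extinction: >=1 -> 0
                        j[1, 2],  # expansion: 1 -> >1
                        j[2, 1],  # contraction: >1 -> 1
                        j[0, 0] + j[1, 1] + j[2, 2],  # class unchanged
                    )
                )
        return pd.DataFrame(
            recs,
            columns=[
                "family",
                "branch",
                "p_origination",
                "p_extinction",
                "p_expansion",
                "p_contraction",
                "p_none",
            ],
        )

    def expected_ancestral_counts(self) -> pd.DataFrame:
        """Expected numbers of absent/single/multi families per node."""
        anc = self.ancestral_states()
        return (
            anc.groupby("node")[["p_absent", "p_single", "p_multi"]]
            .sum()
            .rename(
                columns={
                    "p_absent": "expected_absent",
                    "p_single": "expected_single",
                    "p_multi": "expected_multi",
                }
            )
        )

    def expected_event_counts(self) -> pd.DataFrame:
        """Expected numbers of each family event per branch (sums of the
        per-family probabilities)."""
        ev = self.branch_events()
        out = ev.groupby("branch")[
            ["p_origination", "p_extinction", "p_expansion", "p_contraction"]
        ].sum()
        return out.rename(
            columns={
                "p_origination": "expected_gains",
                "p_extinction": "expected_losses",
                "p_expansion": "expected_expansions",
                "p_contraction": "expected_contractions",
            }
        )
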