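"""Birth-death-gain process semantics and likelihood machinery.

The copy number ``n`` of a family evolves along each branch as a linear
birth-death process with immigration: up-rate ``kappa + lambda*n`` (de novo
gain plus duplication) and down-rate ``mu*n`` (loss of one copy). Transition
probabilities over a branch of duration ``t`` factorize exactly: each of the
``i`` parental copies independently leaves a geometric-with-atom number of
descendants, and the immigration stream contributes an independent
negative-binomial count. Rows of the transition matrix are therefore a
binomial mixture over the number of surviving parental lineages convolved
with negative-binomial offspring/immigrant distributions — no matrix
exponentials are needed, which keeps the generator-exponentiation route
available as an independent numerical oracle.

Family-level rate heterogeneity is a discretized-gamma mixture: each of the
four family factors (overall scale sigma, birth, gain, loss) takes one of C
equal-probability category values (the mean of the corresponding gamma
quantile slice of a unit-mean gamma), and the family likelihood is the
mixture over the cross-product of enabled categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import special, stats

from .trees import SpeciesTree

__all__ = [
    "FamilyRateFactors",
    "RateVariationModel",
    "TruncationPolicy",
    "branch_transition_matrix",
    "root_prior_vector",
    "discretized_gamma_midpoints",
    "profile_loglik_given_category",
    "family_loglik",
    "dataset_loglik",
    "LikelihoodEngine",
]

PARAMETERS = ("sigma", "birth", "gain", "loss")


class ProcessError(ValueError):
    pass


class TruncationError(RuntimeError):
    def __init__(self, msg: str, excess: float = 1.0):
        super().__init__(msg)
        self.excess = excess  # how far past the cap, in log units


@dataclass(frozen=True)
class FamilyRateFactors:
    """Dimensionless multipliers modulating branch rates for one family.

    Effective rates on branch b: birth ``sigma*birth*lambda_b``, gain
    ``sigma*gain*kappa_b``, loss ``sigma*loss*1``.
    """

    sigma: float = 1.0
    birth: float = 1.0
    gain: float = 1.0
    loss: float = 1.0

    def __post_init__(self):
        for name in PARAMETERS:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ProcessError(f"family factor {name} must be finite and > 0")


@dataclass(frozen=True)
class TruncationPolicy:
    """Finite-state computation of the unbounded process.

    ``n_max`` caps the modeled copy number; any row of a transition matrix
    leaking more than ``tail_tol`` probability past the cap triggers doubling
    of ``n_max`` (up to ``max_doublings``), after which the matrix rows are
    renormalized.
    """

    n_max: int = 32
    tail_tol: float = 1e-6
    max_doublings: int = 3


def _lineage_params(birth: float, loss: float, t: float) -> tuple[float, float]:
    """Extinction probability p0 and geometric parameter xi for the
    descendants of a single copy after time t."""
    if t == 0.0:
        return 0.0, 0.0
    x = (birth - loss) * t
    if abs(x) < 1e-10:  # birth ~ loss: continuous limit
        bt = 0.5 * (birth + loss) * t
        p = bt / (1.0 + bt)
        return p, p
    # stable in both directions of x via expm1
    num = -np.expm1(-x)  # 1 - e^{-x}
    den = birth - loss * np.exp(-x)
    p0 = loss * num / den
    xi = birth * num / den
    return float(p0), float(xi)


_LGAM_INT: dict[int, np.ndarray] = {}  # gammaln(0..K) lookup per size


def _lgam_int(K: int) -> np.ndarray:
    tab = _LGAM_INT.get(K)
    if tab is None:
        tab = special.gammaln(np.arange(K + 1, dtype=float))
        _LGAM_INT[K] = tab
    return tab


def branch_transition_matrix(
    birth: float,
    gain: float,
    loss: float,
    t: float,
    n_max: int,
    renormalize: bool = True,
) -> np.ndarray:
    """Transition matrix ``P[i, j] = Pr(child count j | parent count i)``
    on states 0..n_max, from the analytic birth-death-immigration
    factorization.

    Rows are truncated at ``n_max``; with ``renormalize`` they are rescaled
    to sum to one (callers audit the pre-normalization tail mass through
    :class:`TruncationPolicy`).
    """
    for name, v in (("birth", birth), ("gain", gain), ("loss", loss), ("t", t)):
        if not np.isfinite(v) or v < 0:
            raise ProcessError(f"{name} must be finite and non-negative")
    if n_max < 1:
        raise ProcessError("n_max must be >= 1")
    K = n_max + 1
    if t == 0.0:
        return np.eye(K)
    if birth > 0.0 and (birth * t < 1e-14 or gain / birth > 1e12):
        birth = 0.0  # duplication negligible; avoids overflow in gain/birth

    p0, xi = _lineage_params(birth, loss, t)
    i = np.arange(K)
    j = np.arange(K)
    lg1 = _lgam_int(K + 1)[1 : K + 1]  # log n! = gammaln(n+1) for n = 0..K-1
    tri = j[None, :] <= i[:, None]
    # B[i, s]: probability that s of i parental lineages survive
    q = 1.0 - p0
    if q <= 0.0:
        B = np.zeros((K, K))
        B[:, 0] = 1.0
    elif q >= 1.0:
        B = np.eye(K)
    else:
        d = i[:, None] - j[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            logB = (
                lg1[:, None]
                - lg1[None, :]
                - np.where(tri, lg1[np.where(tri, d, 0)], 0.0)
                + j[None, :] * np.log(q)
                + d * np.log(p0)
            )
        B = np.where(tri, np.exp(logB), 0.0)
    # G[s, j]: distribution of total descendants given s survivors, i.e.
    # s + NB(s, xi) offspring convolved with the immigration component.
    s = np.arange(K)
    k = j[None, :] - s[:, None]  # extra counts beyond the s survivors
    up = k >= 0
    kc = np.where(up, k, 0)
    if birth > 0.0 and xi > 0.0:
        r = s[:, None] + gain / birth  # NB(s + gain/birth, 1 - xi)
        with np.errstate(divide="ignore", invalid="ignore"):
            logG = (
                special.gammaln(kc + r)
                - special.gammaln(r)
                - lg1[np.where(up, kc, 0)]
                + r * np.log1p(-xi)
                + kc * np.log(xi)
            )
        G = np.where(up & (r > 0), np.exp(logG), 0.0)
        G[0, 0] = 1.0 if gain == 0.0 else (1.0 - xi) ** (gain / birth)
    elif birth > 0.0:  # t tiny enough that xi underflowed: effectively frozen
        G = np.zeros((K, K))
        G[s, s] = 1.0
    else:
        # no duplication: survivors persist as single copies; immigration is
        # Poisson with the integrated gain intensity
        m = gain * (-np.expm1(-loss * t) / loss if loss > 0.0 else t)
        if m > 0.0:
            with np.errstate(divide="ignore", invalid="ignore"):
                logG = kc * np.log(m) - m - lg1[kc]
            G = np.where(up, np.exp(logG), 0.0)
        else:
            G = np.zeros((K, K))
            G[s, s] = 1.0
    P = B @ G
    if renormalize:
        rowsum = P.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(rowsum > 0, P / rowsum, P)
    return P


def transition_tail_mass(P: np.ndarray) -> float:
    """Largest per-row truncation deficit of an *unnormalized* matrix."""
    return float(np.max(1.0 - P.sum(axis=1)))


def root_prior_vector(phi: float, n_max: int) -> np.ndarray:
    """Poisson(phi) root-size prior truncated to 0..n_max (renormalized)."""
    if not np.isfinite(phi) or phi < 0:
        raise ProcessError("phi must be finite and non-negative")
    p = stats.poisson.pmf(np.arange(n_max + 1), phi)
    return p / p.sum()


def discretized_gamma_midpoints(shape: float, n_categories: int) -> np.ndarray:
    """Category values of a discretized unit-mean gamma: the mean of each of
    ``n_categories`` equal-probability quantile slices. The arithmetic mean
    of the returned values is exactly 1, which anchors the family-factor
    scale against the branch rates."""
    if shape <= 0 or not np.isfinite(shape):
        raise ProcessError("gamma shape must be finite and positive")
    if n_categories < 1:
        raise ProcessError("need at least one category")
    C = n_categories
    edges = stats.gamma.ppf(np.linspace(0, 1, C + 1), shape, scale=1.0 / shape)
    # E[X; a<X<b] for Gamma(shape, rate=shape) = I(shape+1, shape*b) - I(shape+1, shape*a)
    cum = special.gammainc(shape + 1.0, shape * edges[1:-1])
    cum = np.concatenate([[0.0], cum, [1.0]])
    mids = C * np.diff(cum)
    return np.maximum(mids, 1e-12)


@dataclass
class RateVariationModel:
    """Discretized-gamma family-rate heterogeneity for the four factors.

    Each enabled parameter gets ``n_categories`` equal-weight category
    values derived from a unit-mean gamma with its own shape; disabled
    parameters are pinned at 1. Category assignments of distinct parameters
    are a priori independent.
    """

    n_categories: int = 2
    shapes: dict = field(default_factory=dict)  # parameter -> gamma shape
    enabled: tuple = PARAMETERS

    def __post_init__(self):
        bad = set(self.enabled) - set(PARAMETERS)
        if bad:
            raise ProcessError(f"unknown parameters: {sorted(bad)}")
        for p in self.enabled:
            self.shapes.setdefault(p, 1.0)

    def midpoints(self, parameter: str) -> np.ndarray:
        if parameter not in self.enabled:
            return np.array([1.0])
        return discretized_gamma_midpoints(self.shapes[parameter], self.n_categories)

    def combinations(self) -> tuple[list[FamilyRateFactors], np.ndarray, list[dict]]:
        """Cross-product of per-parameter categories.

        Returns (factor objects, prior weights, per-combo category index map).
        """
        per_param = {}
        for p in PARAMETERS:
            per_param[p] = self.midpoints(p)
        combos, weights, indices = [], [], []
        axes = [range(len(per_param[p])) for p in PARAMETERS]
        for idx in product(*axes):
            vals = {p: float(per_param[p][k]) for p, k in zip(PARAMETERS, idx)}
            combos.append(FamilyRateFactors(**vals))
            w = 1.0
            for p, k in zip(PARAMETERS, idx):
                w *= 1.0 / len(per_param[p])
            weights.append(w)
            indices.append({p: k for p, k in zip(PARAMETERS, idx)})
        return combos, np.asarray(weights), indices


# ---------------------------------------------------------------------------
# pruning likelihood engine
# ---------------------------------------------------------------------------


class LikelihoodEngine:
    """Vectorized post-order (pruning) likelihood over many families at once.

    Holds the tree and truncation policy; transition matrices are rebuilt on
    demand for a given set of branch parameters and family factors, with the
    truncation tail audited and ``n_max`` doubled when it leaks.
    """

    def __init__(self, tree: SpeciesTree, trunc: TruncationPolicy = TruncationPolicy()):
        if tree.birth_rates is None or tree.gain_rates is None:
            raise ProcessError("tree branch rates are unset; fit or assign them first")
        self.tree = tree
        self.trunc = trunc
        self._leaf_pos = {int(v): k for k, v in enumerate(tree.leaf_indices)}
        self._n_max_hint = trunc.n_max  # sticky: successful size from last audit

    # -- transition matrices ---------------------------------------------
    def matrices(self, factors: FamilyRateFactors, n_max: int) -> dict[int, np.ndarray]:
        t = self.tree
        mats = {}
        for v in t.branch_nodes:
            v = int(v)
            mats[v] = branch_transition_matrix(
                factors.sigma * factors.birth * t.birth_rates[v],
                factors.sigma * factors.gain * t.gain_rates[v],
                factors.sigma * factors.loss * 1.0,
                t.durations[v],
                n_max,
                renormalize=False,
            )
        return mats

    def sized_matrices(
        self, factors: FamilyRateFactors, audit_rows: int | None = None
    ) -> tuple[dict[int, np.ndarray], int]:
        """Matrices at the smallest n_max (>= policy n_max) whose truncation
        tail is below tolerance; rows renormalized.

        The tail audit covers parent states 0..*audit_rows* (default: half
        of n_max): states near the cap always leak, but they carry
        negligible posterior mass once the cap is comfortably above the
        observed counts — which is exactly what the audit enforces.
        """
        cap = self.trunc.n_max * 2**self.trunc.max_doublings
        t = self.tree
        base = max(audit_rows or self.trunc.n_max // 2, 1)
        for v in t.branch_nodes:
            v = int(v)
            birth = factors.sigma * factors.birth * t.birth_rates[v]
            gain = factors.sigma * factors.gain * t.gain_rates[v]
            loss = factors.sigma * factors.loss
            g = (birth - loss) * t.durations[v]
            growth = np.exp(min(g, 50.0))
            immig = gain * (growth - 1.0) / (birth - loss) if abs(g) > 1e-9 else gain * t.durations[v]
            mean_end = base * growth + immig
            # crude upper quantile; avoids building hopeless state spaces
            need = mean_end + 10.0 * np.sqrt(mean_end + 1.0)
            if need > cap:
                raise TruncationError(
                    f"rates on branch {t.labels[v]!r} push the process far past "
                    f"the truncation cap ({cap}); parameters are implausible",
                    excess=float(np.log(need / cap)),
                )
        n_max = max(self.trunc.n_max, self._n_max_hint)

        def audit(mats, n_max):
            upto = min(n_max // 2 if audit_rows is None else audit_rows, n_max - 1) + 1
            return max(transition_tail_mass(P[:upto]) for P in mats.values())

        for _ in range(self.trunc.max_doublings + 1):
            mats = self.matrices(factors, n_max)
            tail = audit(mats, n_max)
            if tail < self.trunc.tail_tol:
                with np.errstate(invalid="ignore", divide="ignore"):
                    for v, P in mats.items():
                        rs = P.sum(axis=1, keepdims=True)
                        mats[v] = np.where(rs > 0, P / np.where(rs > 0, rs, 1.0), 0.0)
                self._n_max_hint = n_max
                return mats, n_max
            n_max *= 2
        raise TruncationError(
            f"truncation tail {tail:.3g} still above {self.trunc.tail_tol:.3g} "
            f"at n_max={n_max // 2}; rates are likely too large",
            excess=float(np.log(max(tail / self.trunc.tail_tol, 2.0))),
        )

    # -- pruning ----------------------------------------------------------
    def _leaf_onehot(self, counts: np.ndarray, n_max: int) -> np.ndarray:
        F, L = counts.shape
        if counts.max(initial=0) > n_max:
            raise ProcessError(
                f"observed count {int(counts.max())} exceeds n_max={n_max}; "
                "raise the truncation cap"
            )
        onehot = np.zeros((L, F, n_max + 1))
        for k in range(L):
            onehot[k, np.arange(F), counts[:, k]] = 1.0
        return onehot

    def loglik_given_category(
        self,
        counts: np.ndarray,
        phi: float,
        factors: FamilyRateFactors,
        return_messages: bool = False,
    ):
        """Log-likelihood of each profile (rows of *counts*, columns in the
        tree's leaf order) for fixed family factors.

        With ``return_messages`` also returns the per-node conditional
        vectors and upward messages needed for posterior passes.
        """
        counts = np.atleast_2d(np.asarray(counts, dtype=int))
        if counts.max(initial=0) > self.trunc.n_max * 2**self.trunc.max_doublings:
            raise ProcessError(
                f"observed count {int(counts.max())} exceeds n_max even after "
                "refinement; raise the truncation cap"
            )
        mats, n_max = self.sized_matrices(
            factors, audit_rows=max(int(counts.max(initial=0)), 1)
        )
        if stats.poisson.sf(n_max, phi) > self.trunc.tail_tol:
            raise TruncationError(
                f"root prior mean {phi:.3g} leaves > {self.trunc.tail_tol:.1g} "
                f"mass beyond n_max={n_max}"
            )
        prior = root_prior_vector(phi, n_max)
        t = self.tree
        F = counts.shape[0]
        L: dict[int, np.ndarray] = {}
        msg: dict[int, np.ndarray] = {}
        logscale = np.zeros(F)
        for v in t.postorder:
            v = int(v)
            if t.is_leaf(v):
                # leaf conditional is an indicator, so the upward message is
                # just a gathered column of the transition matrix
                obs = counts[:, self._leaf_pos[v]]
                if t.parent[v] >= 0:
                    msg[v] = mats[v].T[obs]
                if return_messages:
                    onehot = np.zeros((F, n_max + 1))
                    onehot[np.arange(F), obs] = 1.0
                    L[v] = onehot
                continue
            kids = t.children[v]
            Lv = msg[kids[0]]
            for c in kids[1:]:
                Lv = Lv * msg[c]
            s = Lv.max(axis=1)
            bad = s <= 0.0
            if bad.any():
                s = np.where(bad, 1.0, s)
                logscale = logscale + np.where(bad, -np.inf, np.log(s))
            else:
                logscale = logscale + np.log(s)
            Lv = Lv / s[:, None]
            if return_messages or t.parent[v] < 0:
                L[v] = Lv
            if t.parent[v] >= 0:
                msg[v] = Lv @ mats[v].T
        lik = L[t.root] @ prior
        with np.errstate(divide="ignore"):
            ll = np.log(lik) + logscale
        if return_messages:
            return ll, {"L": L, "msg": msg, "mats": mats, "prior": prior, "n_max": n_max}
        return ll

    def mixture_loglik(
        self,
        counts: np.ndarray,
        phi: float,
        rvm: RateVariationModel | None,
        condition_on_observed: bool = True,
    ):
        """Mixture log-likelihood over rate-category combinations.

        Returns ``(loglik, posterior_weights, combo_index_maps,
        unconditioned_loglik)``; conditioning divides by the probability that
        a family is present in at least one leaf (all-zero profiles cannot
        enter the data).
        """
        counts = np.atleast_2d(np.asarray(counts, dtype=int))
        if rvm is None:
            combos = [FamilyRateFactors()]
            weights = np.array([1.0])
            index_maps = [{p: 0 for p in PARAMETERS}]
        else:
            combos, weights, index_maps = rvm.combinations()
        F = counts.shape[0]
        ll_c = np.empty((F, len(combos)))
        ll0_c = np.empty(len(combos))
        # evaluate the all-zero profile in the same pruning pass (one extra row)
        padded = np.vstack([counts, np.zeros((1, counts.shape[1]), dtype=int)])
        for k, fac in enumerate(combos):
            both = self.loglik_given_category(padded, phi, fac)
            ll_c[:, k] = both[:F]
            ll0_c[k] = both[F]
        logw = np.log(weights)
        tot = special.logsumexp(ll_c + logw[None, :], axis=1)
        post = np.exp(ll_c + logw[None, :] - tot[:, None])
        uncond = tot.copy()
        if condition_on_observed:
            p_zero = float(np.exp(special.logsumexp(ll0_c + logw)))
            p_zero = min(p_zero, 1.0 - 1e-300)
            tot = tot - np.log1p(-p_zero)
        if not np.all(np.isfinite(tot)):
            bad = int(np.flatnonzero(~np.isfinite(tot))[0])
            raise ProcessError(
                f"non-finite mixture likelihood for profile row {bad}; "
                "check rates/truncation (log-space accumulation is already used)"
            )
        return tot, post, index_maps, uncond


# ---------------------------------------------------------------------------
# functional wrappers (the operation-level API)
# ---------------------------------------------------------------------------


def profile_loglik_given_category(
    profile,
    tree: SpeciesTree,
    phi: float,
    factors: FamilyRateFactors = FamilyRateFactors(),
    trunc: TruncationPolicy = TruncationPolicy(),
) -> float:
    """Log-likelihood of a single profile (dict or array in leaf order)."""
    counts = _as_counts(profile, tree)
    eng = LikelihoodEngine(tree, trunc)
    return float(eng.loglik_given_category(counts, phi, factors)[0])


def family_loglik(
    profile,
    tree: SpeciesTree,
    phi: float,
    rvm: RateVariationModel | None,
    trunc: TruncationPolicy = TruncationPolicy(),
    condition_on_observed: bool = True,
):
    """Mixture log-likelihood and normalized posterior category weights for
    a single family."""
    counts = _as_counts(profile, tree)
    eng = LikelihoodEngine(tree, trunc)
    ll, post, index_maps, uncond = eng.mixture_loglik(
        counts, phi, rvm, condition_on_observed
    )
    return float(ll[0]), post[0], index_maps, float(uncond[0])


def dataset_loglik(
    counts: np.ndarray,
    tree: SpeciesTree,
    phi: float,
    rvm: RateVariationModel | None,
    trunc: TruncationPolicy = TruncationPolicy(),
    condition_on_observed: bool = True,
) -> float:
    """Sum of per-family mixture log-likelihoods (families independent;
    fixed left-to-right summation order for reproducibility)."""
    eng = LikelihoodEngine(tree, trunc)
    ll, _, _, _ = eng.mixture_loglik(np.asarray(counts), phi, rvm, condition_on_observed)
    return float(np.sum(ll))


def _as_counts(profile, tree: SpeciesTree) -> np.ndarray:
    if isinstance(profile, dict):
        missing = set(tree.leaf_labels) - set(profile)
        if missing:
            raise ProcessError(f"profile missing leaves: {sorted(missing)}")
        return np.asarray([[profile[s] for s in tree.leaf_labels]], dtype=int)
    arr = np.atleast_2d(np.asarray(profile, dtype=int))
    if arr.shape[1] != tree.n_leaves:
        raise ProcessError("profile length does not match number of leaves")
    return arr
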