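# Methods

## The model

`bdgphylo` models the copy number of a gene/protein-domain family as a
continuous-time Markov chain on the non-negative integers, evolving
independently in each family along each branch of a rooted species tree.
With copy number $n$, the instantaneous up-rate is $\kappa + \lambda n$
(de novo **gain** plus per-copy **duplication**) and the down-rate is
$\mu n$ (per-copy **loss**). The family size at the root follows a
Poisson($\phi$) prior. Because an undated tree carries no absolute time
scale, rates and durations are normalized so that the branch loss rate is
1: the branch duration $t_b$ carries the loss scale, and the branch birth
and gain rates $\lambda_b, \kappa_b$ are expressed relative to it.

Rates factorize into branch and family components. For family $f$ on
branch $b$ the effective rates are

$$\lambda = \sigma_f\,\lambda_f\,\lambda_b,\qquad
  \kappa = \sigma_f\,\kappa_f\,\kappa_b,\qquad
  \mu = \sigma_f\,\mu_f\cdot 1,$$

where $\sigma_f$ is an overall family scaling factor and
$\lambda_f,\kappa_f,\mu_f$ are per-process family factors. Each family
factor follows a discretized gamma distribution with $C$ equal-probability
categories (default $C=2$: a slow and a fast category); the category value
is the mean of the corresponding quantile slice of a **unit-mean** gamma,
so the arithmetic mean of the category values is exactly 1. This anchors
the family-factor scale against the branch rates — one identifiability
constraint, built into the construction rather than imposed post hoc.
Category assignments of different parameters are a priori independent, so
with all four factors enabled a family's likelihood is a 16-component
mixture with equal prior weights.

## Transition probabilities

Transition probabilities over a branch are computed from the analytic
factorization of the linear birth–death–immigration process rather than by
matrix exponentiation: each of the $i$ parental copies independently
leaves zero descendants with probability $p_0$ or a geometric($\xi$)
number otherwise, and immigration contributes an independent negative
binomial ($r=\kappa/\lambda$) count with the same $\xi$. A row of the
transition matrix is therefore a binomial mixture over the number of
surviving parental lineages times shifted negative-binomial totals; the
$\lambda=\mu$ case is taken by the continuous limit
$p_0=\xi=\lambda t/(1+\lambda t)$, and $\lambda=0$ reduces to binomial
survival with Poisson immigration. All probability-mass computations run
in log space via `gammaln`. The truncated-generator matrix exponential is
used only in the test suite, as an independent oracle; the two routes
agree to well below $10^{-8}$ per entry.

The unbounded chain is truncated at `n_max` states. The truncation policy
audits the leaked tail mass of the rows up to the largest observed count
and doubles `n_max` (up to `max_doublings`, default 3) when it exceeds
`tail_tol` (default $10^{-6}$); surviving rows are renormalized, which
makes the finite-state model an exact probability model in its own right
(the likelihood sums to one over the truncated profile space — a property
the tests exploit). Parameter proposals whose predicted state occupancy
lies far beyond the reachable cap are rejected with a graded penalty
before any matrix is built, which keeps optimizer excursions cheap.

## Likelihood and fitting

Profile likelihoods use Felsenstein pruning, vectorized across families;
leaf messages are gathered columns of the branch transition matrix.
Per-node scaling guards against underflow; mixtures accumulate with a
max-shifted log-sum-exp and fixed summation order for reproducibility.
By default the likelihood conditions on observability — division by
$1-\Pr(\text{all-zero profile})$ — since families absent from every
species cannot enter the input; both conditioned and unconditioned
log-likelihoods are reported.

`BirthDeathGainModel.fit()` estimates parameters in three warm-started
stages of increasing complexity: (1) homogeneous — $\phi$, one global
birth and gain rate, and a global time-scale multiplier; (2)
branch-specific — $\phi$ plus $(t_b,\lambda_b,\kappa_b)$ for every branch;
(3) branch + family variation — adding the gamma shapes of the enabled
family factors (warm-started at 1.0). Each stage runs coordinate-descent
sweeps: a bounded quasi-Newton (L-BFGS-B) step on log-parameters for one
block at a time — a global block, then one $(t_b,\lambda_b,\kappa_b)$
block per branch. A stage stops when a full sweep improves the
log-likelihood by less than `tol` (default 0.01) or when `max_rounds`
sweeps have run. Random restarts (`restarts`, default 1) jitter the
initial state lognormally. Families whose likelihood is non-finite are
flagged `failed`, reported, and excluded from posterior summaries.

## Posterior quantities

After fitting, a single inside–outside pass per rate-category combination
yields, mixed over the per-family category posteriors:

- **family rate posteriors** — $p_f(\pi^S), p_f(\pi^F)$ per parameter,
  expected factors $\pi_f=\sum_c p_f(\pi^c)\pi^c$, and the scaled rates
  $\sigma_f\lambda_f, \sigma_f\kappa_f, \sigma_f\mu_f$ used downstream;
- **ancestral states** — per-family, per-node posteriors collapsed to
  {absent, single copy, multi copy}; summing over families gives the
  expected ancestral repertoire composition;
- **branch events** — exact joint parent–child class posteriors per
  branch, collapsed to origination ($0\to\ge1$), extinction ($\ge1\to0$),
  expansion ($1\to>1$), contraction ($>1\to1$) and "no class change".
  Joint (not product-of-marginals) posteriors are used, so the flow
  identity E[presence at child] = E[presence at parent] + Pr(orig) −
  Pr(ext) holds exactly.

## Downstream analyses

**Modes.** Each lineage's expected totals $G$ (gains), $X$ (losses), $E$
(expansions), $K$ (contractions) are classified: Expansion ($G\ge2X$ and
$E\ge2K$), Streamlining ($X\ge2G$ and $E\le1.2K$), Specialization
($X\ge2G$ and $E\ge2K$), Remodeling ($|G-X|<0.6(G+X)$ and $E>K$). The
four rules are neither exhaustive nor mutually exclusive, so a precedence
order is applied — Expansion → Streamlining → Specialization → Remodeling
— chosen so that the two loss-dominated modes (which share the $X\ge2G$
clause) are separated by their expansion behaviour before the broader
turnover rule is consulted; unmatched lineages are Unclassified, and all
rule terms are returned for audit.

**High-confidence events and parallelism.** A family sustains a
high-confidence gain on a branch when Pr(origination) − Pr(extinction)
strictly exceeds 0.6 (loss: below −0.6). Families with two or more
high-confidence gains (losses) constitute the parallel-gain (-loss)
census.

**Dollo parsimony.** For presence/absence profiles the single-gain,
minimal-loss reconstruction is closed-form: origin at the MRCA of the
present leaves, presence on the spanning subtree, one loss per branch
leaving it. Families whose origin is the tree root have no branch above
them; by default such origins are excluded from per-branch gain totals
(the convention that makes whole-tree gain totals comparable to
likelihood-based branch events), with the root-origin count reported
separately and a flag to include them.

**Rate/function association.** Per-category medians of $\sigma_f$ are
computed over informative annotations only; categories with at least 9
families are eligible. The test statistic is the range of eligible
category medians; the null permutes the family-to-category assignment
preserving category sizes. The raw exceedance fraction $r/n$ is reported
(with the $(r+1)/(n+1)$ variant alongside, which is never zero).

**Significance-tested clustering (SHC).** Profiles of the three scaled
rates are centered and scaled; duplicate rows are removed and restored to
their twin's cluster afterwards. Agglomerative clustering (four metrics ×
five linkages; Pearson is 1 − correlation) is cut top-down: each candidate
bipartition is scored by the ratio of within-cluster to union pairwise
distance sums, and its null distribution is estimated by drawing
same-sized Gaussian datasets from the mean/covariance of the union
(diagonal-regularized when singular), re-clustering each with the same
metric and linkage, and recomputing the score of the replicate's own top
bipartition; $p=(\#\{\text{null} \le \text{obs}\}+1)/(n_{\mathrm{mc}}+1)$.
Family-wise error is controlled by Bonferroni over all merge tests
performed during the descent (a deliberate, conservative simplification
of published SHC corrections): a split is retained only if
$p<\alpha/m$ with $m$ the total number of tests run. The largest retained
$p$ is reported, along with the mean silhouette (singletons score 0).
NMI between clusterings normalizes mutual information by the arithmetic
mean of the two entropies (flag for min/max/geometric); two trivial
single-cluster partitions have NMI 1 by convention, with a warning.

**Enrichment.** Cluster × general-function cells are tested with the
two-sided hypergeometric (Fisher exact) test, flagged over/under, and
corrected with Benjamini–Hochberg across all cells (Bonferroni via flag).
Small clusters may be pooled before testing.

## The synthetic-data generator

`simulate_dataset` draws each family's category assignments, a Poisson
root count, and then evolves every branch by exact jump-chain (Gillespie)
simulation of the birth–death–gain process — never by sampling from the
transition matrices — so the simulator and the likelihood code are
mutually independent implementations of the same process and cross-check
each other (empirical transition frequencies vs analytic rows; recovery
experiments vs truth tables). Truth tables record per-family factors and
categories, all internal node states, and event indicators computed with
the same class-pair definitions the inference uses.

Default conditions emulate the statistical structure of a holozoan-scale
domain-content dataset: a 24-leaf rooted tree (21 ingroup species + 3
outgroups), ~1400 families, branch durations uniform on [0.3, 1.2] —
taxon samples for this kind of analysis are deliberately chosen to avoid
very short or very long backbone branches — branch
birth/gain rates lognormal around 0.5/0.3 with loss 1, Poisson(1.5) root,
C=2 gamma variation, and a 45-detailed / 7-general synthetic functional
annotation with optional planted rate association (categories filled from
opposite tails of the $\sigma_f$ distribution). All-zero profiles are
rejection-sampled away, mirroring observability conditioning.

What the generator does **not** emulate: annotation noise and missing
domain calls, correlated evolution between families, lineage-specific
model violations (e.g. bursts), and the size scale of the few very large
real families (`apply_study_filters` removes families above a total-count
threshold — default 3300 instances — before fitting for exactly this
reason). Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, as the
package's own choice of reproducible experiment sizes. Recovery is
assessed stage-appropriately, on data simulated from the model class the
stage fits: branch parameters (pooled median relative error of
$t_b,\lambda_b,\kappa_b$) on 500 families from the branch-variable model
without family variation, fitted through stage 2; slow/fast category
assignment (concordance at ≥4-fold midpoint separation) on 500 families
with two-category $\sigma$ variation, fitted through stage 3. The
end-to-end acceptance run uses 300 families on a 12-leaf tree with
$\sigma$-only C=2 variation; calibration uses 100 seeded permutation runs
(300 permutations each) and 20 seeded SHC runs ($n_{\mathrm{mc}}=200$) on
200-point Gaussian data. Estimates at these
sizes are consistent (errors shrink as families are added) but retain
visible Monte-Carlo spread; thresholds in the tests reflect that.

Other numerical choices: optimizer bounds $[10^{-3}, 30]$ on rates and
durations (log scale) and $[0.05, 50]$ on gamma shapes; `n_max` starts at
max(observed count + 5, 32); ties in the mode rules resolve by the stated
precedence; degenerate inputs (no events on a branch, single-cluster
partitions, singular covariances, all-absent families) take documented
special paths rather than erroring where a convention exists.

## Known limitations

- Branch gain rates ($\kappa_b$) are the weakest-identified parameters at
  a few hundred families; their per-branch errors dominate the recovery
  median.
- With family-rate variation enabled, the family-factor distribution and
  the global branch scale lie on a nearly flat likelihood ridge: fits can
  exceed the truth's log-likelihood while every branch duration is
  rescaled by a common factor with compensating rate shifts. Relative
  branch-to-branch comparisons and per-family posteriors are stable
  across the ridge; absolute branch parameters under the full model are
  not, at a few hundred families. The unit-mean anchoring limits but does
  not eliminate this.
- The SHC merge test is a faithful-in-spirit reimplementation of
  significance-tested hierarchical clustering, not an exact replica of any
  published variant's statistic or correction; its Bonferroni control is
  conservative.
- Very large observed counts force large truncated state spaces; the
  truncation cap fails loudly (families flagged `failed`) rather than
  silently degrading, and such families are reported and excluded from
  downstream summaries.
- Stage-3 fits with all four family factors enabled (16 mixture
  components) are supported but slow at study scale on one core; the
  acceptance run enables $\sigma$ variation only.
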