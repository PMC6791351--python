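# Methods

## The generative model

Every dataset the package analyses is simulated by the package itself; there
is no empirical input (user trees and traits are accepted through the same
interfaces, but the study design is fully generative).

**Trees.** Pure-birth (Yule) trees conditioned on a tip count *n*: lineages
split at exponential waiting times with total rate *k*·λ (λ = 1, the
splitting lineage chosen uniformly), and after the *n*-th speciation one
further Exp(*n*λ) epoch is drawn before the present. Cutting exactly at the
*n*-th speciation would leave the youngest cherry with zero-length pendant
edges — two identical rows in every trait covariance and therefore a
singular likelihood — so the extra epoch is part of the generator's
definition here. Any height artifact of the stopping rule is irrelevant
because every tree is rescaled to unit height; only topology and relative
node times survive. Tip ids are assigned in sorted-label order and internal
ids in deterministic postorder, so all matrices are reproducible across
runs.

**Regimes.** A binary character *R* evolves under the equal-rates Mk model
with rate *q* = 0.5 per unit height: the root state is uniform on {0, 1}
(the stationary distribution; the data source leaves this unstated) and a
child differs from its parent with probability (1 − e^(−2qt))/2 over a
branch of length *t*. An edge carries the state of its rootward node,
constant along the edge; within-edge transitions are not simulated. The same
convention drives both the trait simulator and the multi-regime fitters, so
the two sides are mutually consistent by construction. Replicates are
accepted only if the minority regime covers 25–45% of the tips *retained*
after pruning; the whole (R, T, S) triple is redrawn on failure (the
retained set depends on T under correlated missingness), with attempts
capped at 1000 and logged.

**Traits.** The trait of interest *T* evolves by preorder recursion using
the exact Gaussian transition along each edge: under BM/BMS the child is
Normal(parent, σ²ᵣ·t); under OU/OUM it is
Normal(θᵣ + (parent − θᵣ)e^(−αt), σ²/(2α)(1 − e^(−2αt))). Defaults are the
study conditions: σ²₀ = 0.5, σ²₁ = 1 (BMS), θ₀ = 10, θ₁ = 11 (OUM),
α = 1.5. The root starts at θ₀ for OU/OUM; for BM/BMS the root value is set
to 10 so trait scales match across models — BM/BMS inference is invariant to
this constant, so the choice is inconsequential. The liability *L* behind
clumped missingness is BM with σ² = 1 from root value 0.

**Missingness.** Random (rMT): independent Bernoulli(p) per tip — chosen
over exact-count sampling because the realized missing fraction should
fluctuate around *p* (at *p* = 0.5, *n* = 600 essentially all draws fall in
≈[0.43, 0.57]). Clumped (cluMT): exactly round(p·n) tips missing, the
lowest-liability quantile (ties, a measure-zero event, break by label
order). Correlated (corMT): exactly round(p·n) tips drawn without
replacement with probability proportional to w = t/ΣT − min T/ΣT, so the
minimum-trait tip (weight 0) is never missing. The sequential renormalized
draw is realized by the exponential-keys equivalence (keys Exp(1)/wᵢ, remove
the k smallest), which has identical distribution and is O(n log n); a test
checks it against direct enumeration of the sequential procedure on a
four-tip case. round() is round-half-to-even throughout. Trees are sized as
round(300/(1 − p)) — 333, 600, 3000 — so that 300 tips always remain and
tree size is never confounded with missingness.

## The D statistic

Phylogenetic signal of the binary status *S* uses the sister-clade
difference sum: nodal values are the unweighted mean of the two child values
(branch lengths play no role), and d is the sum of |parent − child| over all
edges. D = (d_obs − d_b)/(d_r − d_b), where d_r averages 1000 random
permutations of the tip states and d_b averages 1000 Brownian-liability
simulations thresholded *at their own order statistic* so each null
replicate matches the observed number of missing tips exactly — without the
per-replicate prevalence match the D = 0 calibration does not hold at finite
n. The null count of 1000 is the conventional default; the source study does
not report its own.

## Fitting

All four models are Gaussian at the tips, so each fit is GLS with the scale
σ² and the mean coefficients profiled out in closed form; the log-likelihood
is −(n/2)(log 2π + log σ̂² + 1) − ½ log det V₀. What remains is at most one
shape parameter — α for OU/OUM, the rate ratio σ²₁/σ²₀ for BMS — optimized
on a log scale over [10⁻⁶, 10³] by a 5-point grid followed by bounded Brent
(xatol 10⁻⁸) between the flanking grid points. Optima at the search-box
boundary, and numerically zero residual variance (a constant trait), flag
the fit as non-converged; flagged fits are excluded from bias/precision
summaries but counted.

The root is pinned to the root-regime optimum for OU/OUM (matching the
simulator, where the trait starts at θ₀), giving parameter counts k = 2
(BM: σ², root mean), 3 (BMS: two rates + root mean), 3 (OU: σ², θ, α) and
4 (OUM: σ², θ₀, θ₁, α). The alternative — estimating a free root state or
assuming a stationary root — would add a parameter and change the AICc
penalties; it is not what the simulation generates, so it was not adopted.
The OU covariance is the fixed-root kernel
V⁰ᵢⱼ = (1/2α)e^(−α(dᵢ+dⱼ−2tₐ))(1 − e^(−2αtₐ)); the OUM mean distributes
each tip's expectation over (θ₀, θ₁) by integrating the OU mean along the
regime segments of its root-to-tip path (rows sum to 1 by telescoping).
Covariance factorizations use a symmetric positive-definite Cholesky with a
one-shot 10⁻¹⁰ ridge retry on failure (logged via warnings).

Pruning suppresses unary internal nodes (merging edge lengths) but never the
root: if the root becomes unary its stem is kept, so every retained tip
keeps its exact root-to-tip depth and the fitted covariance remains the one
the generating process implies. This differs from tools that re-root at the
MRCA of the retained tips and discard the stem. The regime painting
transfers to the pruned tree by node identity (a merged edge takes the state
of its surviving rootward parent).

Model choice: AICc with ties broken by fewer parameters, then fixed order
BM, BMS, OU, OUM. The BM-vs-OU likelihood-ratio test uses 2ΔlogL against the
plain χ²₁ critical value (3.841 at 0.05) with no boundary-mixture
correction; with a 50:50 mixture the nominal 5% level would halve, and the
uncorrected test is the variant whose rejection rate matches the full-scale
reference behaviour.

## Summaries

Per design cell (generating model × scenario × percentage): the
miss-selection count (AICc-best ≠ generating model) with the best-model
breakdown; the median ΔAICc of the generating model restricted to
miss-selected replicates; normalized bias (mean estimate − true)/true — the
sign convention is "estimate minus truth", so overestimated α is positive;
and normalized precision, median(|estimate − median|)/true. Bias and
precision use only the generating model's own fits.

## Problem sizes and reproducibility

The full design is 4 models × (nMT + 3 scenarios × 3 percentages) = 40
cells × 1000 replicates. The package's own summary runs (acceptance script
and end-to-end tests) use 200 replicates per fitted cell and 50 D-statistic
replicates per percentage — sizes at which binomial/Monte-Carlo error (±3
SE) still brackets the full-scale reference values while a cell completes in
a couple of minutes on one CPU. One check is sized differently on power
grounds: the systematic downward sign of σ̂² under BM/BMS is a ~1/n effect
against sqrt(2/n) replicate noise, unresolvable at 300 tips with hundreds of
replicates, so that test uses 40-tip trees with 2000 cheap replicates, where
the sign sits 2–4 standard errors from zero. Every random quantity flows from a single
master `numpy` SeedSequence; each replicate gets an independent spawned
stream, split again into named substreams (tree, regimes, trait,
missingness, D nulls), so any replicate can be regenerated bit-identically
from the manifest.

## What the generator does and does not emulate

Simulated data are idealized: no measurement error, no fossil/internal
extinction, exactly one regime history known without error, and missingness
generated by the three schemes above. Passing tests therefore show that the
estimators behave correctly *under the generating model*, not that real
datasets — where the generating process is unknown and regimes are
reconstructed — enjoy the same robustness. The corMT scheme is
deliberately non-phylogenetic (status sampled by trait-proportional weights,
not by a correlated liability); a multivariate liability-trait model would
be more realistic but is out of scope.

## Known limitations

* Only strictly bifurcating rooted trees; no NEXUS, networks or
  multifurcations (a warning, not an error, for non-ultrametric user trees).
* Binary regimes only; no within-edge stochastic character maps.
* The 1-D profiled optimizers assume a well-behaved likelihood in the single
  shape parameter; pathological data can park α at the search-box boundary,
  which is flagged rather than repaired.
* D is reported without p-values (the study compares means only).
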