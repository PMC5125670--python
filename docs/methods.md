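# Methods

This note documents the models, estimators, and algorithmic choices behind
`shortscale`, and what its validation does and does not show.

## The measurement model and its estimation

All strategies operate on a one-factor (congeneric) measurement model for
dichotomous items: item i's latent response is y*_i = λ_i·θ + ε_i with
standardized loadings λ_i and θ ~ N(0, 1), observed as x_i = 1 when y*_i
exceeds a threshold.

**Tetrachoric correlations.** Pairwise correlations of the latent responses
are estimated by maximum likelihood under the bivariate-normal liability
model: thresholds come from the margins of each 2×2 table, and r solves
P(Z₁ > τ₁, Z₂ > τ₂; r) = p₁₁. The rectangle probability is computed from
the conditional-probit representation ∫ Φ((r·Φ⁻¹(u) − τ₂)/√(1−r²)) du on
96 fixed Gauss–Legendre nodes, which vectorizes across all item pairs, and
r is found by 52 vectorized bisection steps on [−0.999, 0.999]
(monotonicity of p₁₁ in r makes bisection exact to machine-level
tolerance). Accuracy against scipy's bivariate-normal CDF is ~1e-6 over
the relevant range, far below the sampling error of any estimated
tetrachoric. Boundary rules: a table with both discordant (or both
concordant) cells empty maps to ±0.999; a single empty cell receives a 0.5
continuity correction before estimation; a constant item column is an
error naming the item. The matrix is smoothed to positive semidefiniteness
by eigenvalue clipping at zero followed by diagonal re-normalization.
When a subset of items is evaluated, the corresponding sub-matrix of the
*raw* pairwise estimates is re-smoothed, so subset fits are identical to
fitting the tetrachorics of the subset data directly.

**One-factor fit.** Loadings minimize the unweighted least-squares
discrepancy f(λ) = Σ_{i<j} (r_ij − λ_i λ_j)² via L-BFGS-B with analytic
gradient, bounds λ ∈ [−0.999, 0.999] (Heywood guard), convergence
tolerance 1e-8 on f, and an iteration cap of 500. Start values are the
first principal component scaled by √(eig₁ − 1), which approximates the
loadings for one-factor structures and is exactly zero for a diagonal
matrix (whose global minimum is the null loading vector). This estimator
is deliberately *not* WLSMV: the mean-and-variance-adjusted weight matrix
requires the asymptotic covariance of all thresholds and polychorics, and
its chi-square calibration buys nothing for *ranking* candidate subsets.
Consequently the chi-square statistic T = (n−1)·f_min and the derived CFI
and RMSEA are internally consistent (they satisfy the usual structural
identities and order subsets sensibly) but are **not** comparable in
absolute value to WLSMV statistics from SEM software.

Fit indices: df = m(m−1)/2 − m; the baseline is mutual independence with
df = m(m−1)/2; CFI = 1 − max(T−df, 0)/max(T−df, T_b−df_b, 0) with the
degenerate 0/0 case defined as 1; RMSEA = √(max(T−df, 0)/(df·(n−1))) with
the df = 0 saturated case defined as 0. Reliability is McDonald's ω =
(Σλ)² / [(Σλ)² + Σ(1−λ²)], the factor saturation of the congeneric model.

## The optimization objectives

The ACO objective sums four criteria mapped onto commensurate scales by
logistic transforms centered at conventional cutoffs (CFI .95, RMSEA .05,
ω .90, max|Δr| .03), plus a quadratic sensitivity term peaking at mean
item difficulty .625 — the optimum for four-alternative items with a .25
guessing floor, halfway between the floor and 1. The quadratic is negative
below a mean difficulty of ~.178, out of step with the 0–1 scaling of the
logistic components; it is clamped at 0 by default, with `clamp=False`
available, and every result records which mode produced it. Δr is the
signed difference between Pearson correlations of the short-form and
long-form *unit-weighted sum scores* with each covariate (binary
covariates enter as 0/1, giving point-biserial correlations); the φ_Cor
argument is the maximum absolute difference over the covariate panel.
All transforms use `scipy.special.expit`, which is overflow-safe.

The GA cost is I·k + (1 − R²): R² is the coefficient of determination of
an intercept-included OLS regression of the long-form total score on the
retained items' scores, computed from precomputed centered cross-product
matrices (a k×k solve per candidate, independent of sample size).

## The selection algorithms

**SCOFA** computes the full-pool tetrachoric matrix once, then alternates
fit → drop-the-lowest-loading → refit until k items remain. Ties break to
the lowest item position. A non-convergent intermediate fit aborts with
the partial removal order attached.

**ACO.** Each replication starts from a uniform pheromone trail τ = 1.
Per iteration, `n_ants` subsets of size k are drawn by sequential sampling
without replacement with probability proportional to τ (renormalizing
after each draw — this is the documented probability model), and scored;
a candidate whose CFA fails scores −∞ and is logged, never fatal. The
update is an exponential moving average toward the unit exploration
baseline plus *advantage deposits*:

τ ← (1−ρ)·τ + ρ·(1 + D·Δ),

where each ant adds (score − iteration-worst)/n_ants to its items' Δ and
the best-so-far subset additionally deposits its full advantage (elitist
reinforcement). Two properties motivated this rule over a plain
evaporate-and-deposit trail: (a) *neutrality* — under a flat objective all
advantages are zero, so the trail stays exactly at the uniform baseline
instead of drifting through self-reinforcing sampling noise, and (b)
*self-recovery* — a converged colony with no score spread relaxes back
toward exploration. Defaults: n_ants 30, ρ 0.1, deposit scale D 25
(effective concentration for objective advantages of order 0.1–0.5, the
scale of the four-part objective), 200 iterations, stall limit 30. A run
consists of `n_replications` (default 3) independent replications with
derived seeds master+1, master+2, …; the reported result is the best of
the replications, which is also the protocol under which the method is
usually applied. Within a data set, subset evaluations are memoized, so
revisited subsets cost nothing.

**GA.** Candidates are inclusion masks. Parents are drawn
rank-proportionally (best rank gets the largest weight), offspring arise
by uniform crossover at `crossover_rate` (else a clone) and per-position
mutation at rate 1/L by default, and a strictly better offspring replaces
the worst population member (steady-state; the incumbent best always
survives, making `elitism_count` ≥ 1 automatic). An empty candidate is
repaired to size 1; with `fixed_k` set, offspring are repaired to exactly
k by random add/drop before evaluation. `tune_item_cost` bisects on I over
[1e-6, 1] with a fixed seed per probe; k(I) is non-increasing up to search
noise, and if no probed I yields the target length within the bisection
budget the closest run is returned with a warning flag.

All three strategies are fully deterministic given (data, config, seed):
every stochastic draw goes through one seeded `numpy` generator per run.

## The synthetic-data generator

Responses follow a guessing-floored standardized 2PL model:
P(x_pi = 1) = c + (1−c)·F(a_i·θ_p − τ_i), with θ ~ N(0,1), probit link by
default (a_i = λ_i/√(1−λ_i²); the logistic option uses the 1.702
convention), and c the guessing floor. The intercept τ_i is calibrated by
root-finding (Brent) so the *population* marginal — an 81-node
Gauss–Hermite expectation over θ — equals the requested item difficulty
to 1e-6; the guessing floor breaks the closed form, hence the numerical
route. Targets at or below c are unattainable and raise an error naming
the item. c = 1 is accepted as a documented degenerate floor (every
response correct); this follows the generator's contract even though the
nominal parameter range is [0, 1). Covariates are drawn jointly
multivariate-normal with θ at declared correlations, mutually independent
given θ unless a full covariate correlation matrix is supplied; the
implied joint correlation matrix must be positive definite.

A rank correlation between loadings and easiness can be imposed by
Iman–Conover-style reordering: difficulty targets are re-assigned along
normal scores ρ·z(loading ranks) + √(1−ρ²)·noise. The blend imposes the
correlation on normal scores, so the realized Spearman correlation is
slightly below the nominal ρ.

**The 89-item vocabulary-like pool** (`make_ppvt_like_pool`) emulates a
four-alternative picture-vocabulary instrument: 89 items, guessing .25,
loadings from truncated-normal quantiles on [−.03, .81] with mean ≈ .41,
difficulty targets from truncated-normal quantiles on [.28, .98] with mean
≈ .64 (targets below the .25 floor are infeasible under the generative
model and excluded by construction), and a covariate panel mixing strong
convergent (.5–.65), moderate, and near-zero discriminant trait
correlations. The loading–easiness rank correlation is set to 0.9,
calibrated so that the highest-loading items are nearly all very easy —
the defining confound of the emulated instrument, and the mechanism that
makes greedy loading-maximizing selection produce easy, redundant, less
valid short forms. At n = 3,000, noise in fitted loadings still dilutes
the confound relative to very large samples, so stepwise selection lands
at mean difficulty ≈ .85 rather than the ≈ .92 seen at census-scale n.

What the generator does *not* emulate: item-position and fatigue effects,
missing data, local dependence beyond the single factor, polytomous
items, and ability-dependent guessing. Tests passing on these synthetic
pools therefore validate the machinery and the *directional* methodological
contrast, not any instrument-specific numerical value.

## Validation strategy and problem sizes

The test suite checks, at sizes chosen for a single CPU:

* exact arithmetic (the C(89,25) search-space count against an independent
  multiplicative oracle) and the cutoff behavior of every transform on
  dense grids;
* tetrachoric estimates against a full-likelihood grid+simplex oracle
  built on scipy's bivariate-normal CDF, and the one-factor discrepancy
  against a 21⁴-point grid + simplex search;
* parameter recovery at n = 5,000 with 20 items, run at c = 0 because
  that is the condition under which the generating model and the fitted
  liability model coincide — with c > 0 tetrachoric loadings are
  attenuated by design and exact recovery is not a well-posed target;
* oracle optimality of both metaheuristics on 10-item pools where the
  objectives can be enumerated exhaustively (252 and 210 subsets), over
  50 seeded runs each;
* the headline contrast on the 89-item pool at n = 3,000 over 10 seeded
  replications: the stepwise form must be easier on average and shift
  covariate correlations more than both metaheuristic 15-item forms.

## Known limitations

* Fit statistics are least-squares-calibrated, not WLSMV; compare ranks,
  not values, against SEM software output.
* The tetrachoric clamp at |r| = 0.999 and the PSD smoothing slightly bias
  matrices containing near-boundary tables.
* max|Δr| at k = 15 has a noise-and-attenuation floor of roughly .04–.05
  at n = 3,000; φ_Cor consequently operates mostly in its low tail there.
* Listwise-complete data are assumed throughout (no missing-data support).
* Single-factor models only; no measurement-invariance testing.
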