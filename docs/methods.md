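# Methods

This note documents the models and procedures implemented in trophnet, the
assumptions behind them, the synthetic data they are validated on, and the
numerical and design choices that were genuinely open.

## Interaction inference

An interaction is a *head-to-head proximity event*: two ants whose head
points are at Euclidean distance ≤ `threshold_px` in at least one frame in
which **both** are detected.  The rule is deliberately binary — frame rates
vary from 0.31 to 2.92 images/s across and within trials, so durations and
contact counts are not comparable across trials and are discarded.  Key
conventions:

* **Boundary inclusive.**  A distance exactly equal to the threshold counts.
* **Co-detection required.**  A frame contributes only when both ants are
  detected in it; a missed detection can therefore hide an interaction but
  never invent one.  No interpolation is performed across frame gaps.
* **Head proxy.**  The head is the tag centre displaced `head_offset_px`
  along the tag's front direction.  The default offset is 0: the threshold
  is calibrated empirically from manual head-to-head measurements, so a
  constant tag-to-head displacement is absorbed by the calibration.  The
  offset remains configurable for sensitivity analyses.
* **Threshold calibration.**  Manual distance measurements (target: 50
  sampled frames per trial) are averaged per trial and the *largest*
  per-trial mean becomes the single operating threshold for all trials
  (102 px at 0.04 mm/px for the reference imaging setup).  Taking the
  maximum is conservative in the direction of not missing true encounters.
* **Node policy.**  Networks are built from edge lists; by default the node
  set is the *participants* (ants with ≥ 1 edge), because not every tagged
  ant interacts.  An `all_tagged` policy retains isolates (degree 0,
  betweenness 0 by convention) for sensitivity analyses, and network density
  can alternatively be computed over C(group_size, 2); the observed-network
  convention is the default because the verbal definition of "all possible
  interactions" is ambiguous between the two.

## Network and activity measures

Density is |E| / C(n, 2) on the constructed graph's node set.  Degree counts
distinct partners.  Betweenness is unnormalised shortest-path betweenness,
fractional over multiple geodesics, each unordered pair counted once,
unreachable pairs contributing zero (computed via Brandes' algorithm;
validated against an in-package exhaustive path enumerator).  Total distance
moved is the sum of Euclidean displacements between consecutive detections,
in pixels; with subsampled frames it is necessarily a lower bound on the
continuous path length.

### Walktrap community detection

The cluster count comes from an in-package implementation of the walktrap
algorithm: a t-step random walk (default t = 4) on the *lazy* chain (a
self-loop added to every vertex, as in the reference implementation)
characterises each node by its walk distribution; communities are merged
greedily — only pairs sharing an edge may merge — choosing the merger with
the smallest Ward-style cost

    delta_sigma(C1, C2) = (1/n) |C1||C2| / (|C1|+|C2|) * r2(C1, C2),
    r2 = sum_k (P_t[C1,k] − P_t[C2,k])^2 / d(k),

and the merge dendrogram is cut at the level of maximum modularity
(evaluated on the original graph).  Disconnected components never merge;
isolated vertices are excluded from the walk and each counts as its own
community.  Determinism: merge-cost ties break toward the lexicographically
smallest community pair, and modularity ties cut at the *first* (finest)
maximum.  Exact ties occur on roughly 1 in 500 random community graphs;
there the published algorithm is genuinely underdetermined and independent
implementations resolve them by floating-point accident, so tie-free
planted-partition graphs are the appropriate agreement benchmark (the
package matches igraph's walktrap on 100% of such graphs).

## Mixed models

### Linear mixed model

For a response y with fixed design X and crossed random intercepts
(group, individual, frame-rate stratum),

    y = X beta + sum_k Z_k b_k + e,   b_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I).

The deviance is profiled over the variance ratios gamma_k =
sigma_k^2/sigma_e^2: given gamma, beta and sigma_e^2 are closed-form, so the
optimiser (Nelder–Mead on log gamma, relative convergence 1e-6, ratios
clipped to [1e-10, 1e10]) works in ≤ 3 dimensions.  All algebra runs on the
q×q system Gamma^-1 + Z'Z; when one factor is much larger than the rest
(individuals), it is eliminated exactly by block decomposition with
per-observation-count Gram matrices precomputed, making each deviance
evaluation O(q_small^3) — this keeps 500-replicate recovery studies at
n = 1600 observations under a minute.  The profiled ML and REML criteria
match lme4's definitions exactly, verified against lme4 (coefficients,
variance components, log-likelihoods, AIC) and statsmodels MixedLM in the
test suite.

* **ML vs REML.**  AIC model selection compares ML fits (candidates differ
  in fixed effects, so REML likelihoods are not comparable); the selected
  structure is refit under REML for reported coefficients.  AIC = 2k − 2·logLik
  with k = p + (number of variance components) + 1.
* **Frame rate as a grouping factor.**  The continuous trial-mean rate is
  binned (default width 0.1 images/s) to form random-intercept levels; the
  bin width is configurable since any discretisation of a continuous rate
  into strata is a convention.  For *trial-level* responses the mean frame
  rate instead enters as a fixed covariate.
* **Reference levels.**  Factors are indicator-coded with defaults
  food_type = protein, availability = limited as references, so the
  interaction coefficient is the carbohydrate-specific availability effect —
  the contrast of scientific interest.  References are configurable.
* **Random factors with one level** are dropped with a warning (variance
  fixed at 0); rank-deficient fixed designs raise an error.

### Gamma log-link GLMM (betweenness)

Betweenness is positive and right-skewed; it is modelled as Gamma with
shape nu and mean exp(X beta + Z b).  The marginal likelihood uses the
Laplace approximation: the random-effect mode is found by Newton iteration
with step halving (penalised joint density; convergence at relative
gradient < 1e-9), the outer optimiser works over (log sigma_k^2, log nu)
with beta profiled by penalised IRLS, and beta is then polished by direct
BFGS maximisation of the Laplace objective.  Coefficient covariance is the
beta block of the inverse joint observed information at the mode
(conditional on the variance estimates, as in lme4).  Agreement with
glmmTMB on test data: coefficients and log-likelihood to ~1e-3.

Zeros: a gamma response must be positive, and betweenness is frequently 0.
The default `zero_handling="shift"` adds a constant (default 1) to the
response before fitting; `drop` and `error` are alternatives.  The choice is
recorded in the model report.

### Type II Wald analysis of deviance

For each fixed term T with higher-order relatives R (terms whose variable
set strictly contains T's), the hypothesis matrix maps the full-model
coefficients onto T's coefficients in the reduced design without R's
columns, L = [pinv(X_-R) X]_T; the statistic (Lb)'(L V L')^{-1}(Lb) is
referred to χ² with df = rank(L).  This respects marginality — each term is
tested after all terms of equal or lower order, ignoring its own relatives —
and reproduces car::Anova(type = 2, Wald) to four significant figures in
the cross-check tests.  Null calibration is verified by simulation: 1000
statistics under a true-null term are KS-consistent with χ²(1).

### R², contrasts, degrees of freedom

Variance-partition R²: marginal = var(X beta) / (var(X beta) + Σ sigma_k² +
sigma_eps²); conditional adds Σ sigma_k² to the numerator; the
random-effects share is their difference (reported in percent).  For the
gamma log link the observation-level variance on the latent scale is
trigamma(nu) (the standard choice for log links; a lognormal approximation
is the obvious alternative and differs negligibly at the shapes seen here).

Estimated marginal means average model predictions over the factor grid
with covariates at their sample means.  Pairwise availability contrasts
within each food type use Satterthwaite denominator degrees of freedom —
df = 2 f² / (g' Σ_psi g) with f = c'V(psi)c, gradient g by central finite
differences in the variance components, and Σ_psi the inverse REML
information (finite-difference Hessian) — matching lmerTest/emmeans to ~3%
on test data.  Kenward–Roger was the other candidate; Satterthwaite was
chosen for its simplicity and because the two agree closely at these sample
sizes.  Tukey adjustment uses the studentized range over the compare-factor
family; with two levels it coincides with the unadjusted two-sided t test.
Gamma fits use the asymptotic normal reference (df = ∞), as is conventional
for Laplace GLMM contrasts.

## Synthetic data

### Trajectory level

Each ant follows a discrete-time correlated random walk (wrapped-normal
turning angles, SD 0.6 rad; gamma step lengths, mean 8 px/s, shape 2) on a
1 s grid, confined to a private "home disc" (radius 40 px) inside the
1125 px arena (90 mm at 0.04 mm/px).  Home discs and planted-pair corridors
are placed by rejection sampling with clearance 1.5 × threshold + wander
diameter + pad, which *guarantees* that non-planted pairs never come within
1.5 × threshold of each other — the noiseless-mode separation margin that
makes recovery tests unambiguous.  Each planted pair walks to a meeting
point (head separation 70 px < 102 px), holds for 12 s — longer than the
longest sampling interval 1/0.31 ≈ 3.2 s, so at least one sampled frame
captures every encounter — and returns.  Frames are sampled under a
piecewise-constant rate schedule within [0.31, 2.92] images/s (three
segments by default, plus a closing sample at trial end so full-rate
sampling captures every step of the true path).  The generator audits its
own output by brute force (minimum pairwise head distance over all sampled
frames) and refuses configurations it cannot choreograph.

What this emulates: arena geometry, group sizes, variable frame rates,
head-proximity encounters with known identity.  What it does not: real ant
movement statistics, crowding, occlusion-induced detection loss (available
only as uniform dropout), or ambiguous near-threshold encounters.  Passing
recovery tests therefore demonstrates correctness of the inference chain,
not robustness to tracking noise.

### Measure level

`simulate_measures` generates per-ant responses with linear predictor
beta0 + beta_gs·size + beta_ft·I(carb) + beta_av·I(unlim) +
beta_int·I(carb)·I(unlim), plus Gaussian group, individual and frame-rate
random intercepts; Gaussian residuals for the degree-/distance-like columns
and a gamma draw (log link, same predictor) for the betweenness-like
column.  Defaults are the reference validation conditions: 40 groups of 20
ants, each group tested in **two** treatment cells (groups are retested in
the emulated protocol; a one-trial-per-group design would confound
treatment with the group intercept and make the individual variance
unidentifiable), group sizes uniform on 14–30, beta_gs = 0.5,
beta_int = −2.0 planted in the carbohydrate × unlimited cell (so the
carbohydrate-cell availability contrast equals −2.0), main effects 0,
SDs sigma_group = 1, sigma_individual = 0.5, sigma_e = 1, frame-rate SD 0.

## Validation studies and problem sizes

The studies behind `tests/test_acceptance.py` and `scripts/acceptance.py`
use these sizes, chosen to run in minutes on one CPU:

* interaction recovery: 20 trials × 5 seeds, 600 s per trial, 3–10 planted
  pairs, group sizes spanning 14–30 and base rates spanning 0.31–2.92;
* centrality oracle: 200 random graphs, n ≤ 12, exhaustive enumeration;
* walktrap agreement: 50 planted-partition graphs (2–4 blocks, p_in
  0.6–0.9, p_out 0.02–0.10, n ≤ 30) against python-igraph, plus the
  two-triangles / K6 / bridged-K5 fixtures;
* mixed-model recovery: 500 replicates at the defaults above (REML refit,
  Satterthwaite CIs, EMM contrasts);
* AIC selection consistency: 200 replicates per generating structure;
* Wald null calibration: 1000 refits (50 groups × 4 trials × 5–8 ants).

A note on AIC selection consistency: when the generating structure is the
*smallest* candidate (no interaction), AIC's non-vanishing overfitting
probability bounds the selection rate — the true model must beat each of
three one-extra-parameter candidates (each won with probability
P(χ²₁ < 2) ≈ 0.84) and the three-way candidate, which yields ≈ 0.59
asymptotically regardless of sample size; the observed rate matches this.
When the generating structure contains the planted −2.0 interaction the
rate is ≈ 0.88, limited only by the three-way candidate's overfitting.

## Known limitations

* Interaction classification is geometric only; antennation and actual food
  exchange are indistinguishable, and directionality of transfer is out of
  scope.
* The gamma GLMM uses a single Laplace approximation (no adaptive
  quadrature); with few observations per random level its variance
  components can be biased low, as is typical.
* Satterthwaite machinery relies on finite-difference derivatives of the
  REML criterion; at variance boundaries (estimates near 0) the information
  matrix is near-singular and the degrees of freedom are clipped to
  [1, 1e7].
* The movement simulator is test scaffolding, not a behavioural model; no
  claim about real colonies follows from simulator-based validation alone.
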