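# Methods

`mimodiv` implements a three-stage comparative analysis of dry-season
deciduousness in the legume genus *Mimosa*: does leaf habit (deciduous vs
evergreen) shape diversification, does it shape how environmental niches
evolve, and which environmental axes predict it across species today? All
three stages share one ultrametric, time-calibrated phylogeny (branch
lengths in Myr) and a binary habit coding in which any species retaining
part of its foliage — including semideciduous forms — counts as evergreen.

## Stage 1: time-sliced state-dependent diversification

The diversification model is of the state-dependent speciation/extinction
(SSE) family with composite states: two observed habit states crossed with
two hidden rate classes (A, B). The hidden classes make the
"habit-independent" null a fair competitor: rate variation may exist but be
unlinked to habit. The likelihood integrates the standard D/E ordinary
differential equations tipward to rootward,

    dE_i/dt = mu_i - (lambda_i + mu_i + q_i) E_i + lambda_i E_i^2 + sum_j q_ij E_j
    dD_i/dt = -(lambda_i + mu_i + q_i) D_i + 2 lambda_i E_i D_i + sum_j q_ij D_j

with rates switching at a slice age (7 or 15 Ma; ages run backward from the
present, "early" meaning older than the slice). The model family crosses
four epoch scenarios — speciation habit-dependent or habit-independent in
each epoch — with symmetric vs asymmetric and time-constant vs
time-variable habit transitions, plus two unsliced references (18 models).

Linking scheme (parameter-count matching): "dependent" epochs let lambda
vary by observed habit, "independent" epochs by hidden class only, so
corresponding models have identical free-parameter counts and AIC reduces
to a likelihood comparison. Extinction is shared across states within an
epoch (a flag frees it); hidden-class flips have a single symmetric rate
(per epoch when transitions are time-variable); simultaneous habit+class
changes are forbidden. Root states are weighted by their share of the root
D (a flat option exists) and the likelihood conditions on two surviving
crown lineages by default. The per-state survival factor
`lambda (1 - E)^2` is floored at 1e-12: without the floor a bounded
optimizer can drive the conditioned likelihood to arbitrarily large values
in the near-certain-extinction corner of parameter space, a degenerate
regime rather than a fit.

Integration uses an embedded adaptive Dormand-Prince RK45 (rtol 1e-8,
atol 1e-10) compiled with numba; the epoch boundary is always a
breakpoint, never stepped over. The equations are non-stiff within the
bounded rate range [1e-6, 10] per Myr, and the integrator is verified
against a fine-step explicit Euler oracle and against factorization
identities (state-independent rates make the likelihood the product of a
one-state birth-death density and a Markov trait likelihood). D vectors
are renormalized at every node with the log-compensation accumulated.
Fitting is bounded quasi-Newton (L-BFGS-B) on log rates with a
data-informed first start and Latin-hypercube-spread extra starts; all
starts are recorded.

A direction worth documenting: on a fixed dataset the log-likelihood
*rises* as the sampling fraction drops at moderate fractions. The fraction
enters twice — each sampled tip contributes a factor rho, lowering the
likelihood, while the E equations start at 1-rho, raising D along
branches — and the second effect dominates until rho becomes small.

## Stage 2: multi-regime niche evolution

Each environmental variable (aridity index AI, vapor pressure deficit VPD,
growing-season precipitation GSP, sand and clay content; species values
z-scored) is modeled as a Gaussian process along the tree under habit
regimes, with nine nested models: BM1, BMV, OU1, OUA, OUV, OUM, OUVA,
OUMV, OUMVA — the suffix letters marking which of rate (sigma^2, V),
selection strength (alpha, A) and optimum (theta, M) differ between
regimes. The mean-reverting dynamics per regime are
dX = alpha (theta - X) dt + sigma dW, with BM the alpha = 0 limit and
stationary variance sigma^2 / (2 alpha).

Joint inference of the discrete regime process and the continuous trait is
approximated by the classical two-step procedure: an all-rates-different
Markov fit to habit, a fixed set of stochastic character maps drawn from
it (node states sampled from pruning conditionals, within-branch histories
by endpoint-conditioned rejection, cap 1e5), and a map-averaged Gaussian
likelihood (log-mean-exp across maps). The same maps serve all nine models
and all variables so model contrasts are not confounded by map noise.
Tip moments are exact under piecewise-constant parameters: each edge folds
into a decay factor, a deterministic shift and an added variance, and the
tip covariance is the MRCA variance attenuated along both descending
paths. Model ranking uses AICc (n = number of species) counting continuous
parameters only — the Mk rates are shared by every compared model — with
the root fixed at the root regime's optimum for OU models and an estimated
ancestral mean for BM models. Trait-scale equivariance (x -> cx maps
sigma^2 -> c^2 sigma^2, theta -> c theta, alpha unchanged, AICc
differences unchanged) is enforced by test.

## Stage 3: Bayesian phylogenetic multilevel model

Habit is Bernoulli with logit link:

    logit P(y_i = 1) = beta_0 + x_i' beta + a_i + u_i,
    a ~ MVN(0, sigma_phylo^2 C),   u_i ~ N(0, sigma_species^2),

where C is the phylogenetic correlation matrix (shared root-to-MRCA depth
over tree height). Predictors are mean-centered and divided by two
standard deviations so binary and continuous effects are comparable;
priors are Normal(0, 2) on slopes and Student-t(3, 0, 2.5) on the
intercept and (half-t) on both SDs.

Sampling is a Polya-Gamma augmented Gibbs sampler: conditional on
omega_i ~ PG(1, eta_i) the updates for (beta_0, beta), a and u are exact
multivariate normals; the SDs are slice-sampled on the log scale; the
intercept's t prior enters through its normal/inverse-gamma mixture. The
PG draws use the weighted sum-of-exponentials series truncated at 100
terms with the tail replaced by its expectation (midpoint-rule integral);
the residual bias is far below Monte-Carlo noise at the sample sizes used
and is covered by the simulation-based calibration test. C is factored
once as Cholesky(C + 1e-10 I). Multiple independent chains feed R-hat and
ESS (arviz). The `adapt_delta` control of gradient-based samplers has no
Gibbs analogue; the argument is accepted for interface parity and unused.

Derived quantities, all computed per posterior draw: Bayesian R^2 on the
probability scale, `Var(p) / (Var(p) + mean(p (1 - p)))`, with random
effects zeroed (marginal) or included (conditional); posterior predictive
checks locating observed statistics within replicated datasets; and
prior/likelihood power-scaling by importance reweighting
(w proportional to prior^(alpha-1)), reporting mean drift, a
1-Wasserstein distance between base and reweighted marginals normalized
by the posterior SD (flag threshold 0.05), and the weight ESS. Only
top-level priors (intercept, slopes, SDs) are power-scaled; the
random-effect vectors belong to the hierarchy.

## Occurrence and environment preparation

Occurrences are filtered to native-range polygons (shapely covers
predicate), ranges delineated as convex hulls (degenerate hulls buffered
by one grid cell), species with fewer than five records replaced by 20
random points sampled uniformly without replacement from grid-cell centers
inside their polygon, and all point sets spatially thinned so no retained
pair lies within 1.5 km (haversine, Earth radius 6371.0088 km; greedy
max-conflict removal with seeded tie-breaks, checked idempotent and
compared against an exact maximum-independent-set oracle on small
instances). Species values are point means (median available); VIF
screening uses 1/(1 - R^2) with threshold 5; predictors are 2-SD scaled
with the constants retained for back-transformation. Observed and random
points are never mixed within a species. Gridded environmental layers are
consumed as in-memory arrays with an affine header; no GeoTIFF reader is
bundled.

## Synthetic data: what it emulates, and what it does not

The generators produce data with exactly the dependence structure each
stage assumes: a Gillespie simulation of the composite-state birth-death
process with the epoch switch (event log retained and replayable to the
identical pruned tree), exact-transition OU sampling on regime paintings,
the logistic model with phylogenetically correlated and iid intercepts and
a controllable predictor correlation (default 0.93 between the AI and GSP
analogues), and clustered occurrence points over smooth gradient-plus-noise
layers with a sparse-species subset. Survival conditioning is by retry
(tip count within [0.5, 2] x target), which slightly biases toward
fast-growing histories at high extinction; extinction defaults are low.

Default study conditions: crown age 30 Myr, slice at 7 Myr, habit
transitions at the fitted rates of the empirical system (evergreen ->
deciduous 0.113/Myr early, ~0.001 late; reverse 0.015 -> 0.014), early
speciation varying by hidden class (0.05 vs 0.30/Myr, class flip rate
0.025/Myr), late speciation varying by habit (evergreen 0.30, deciduous
0.10/Myr), extinction 0.02/Myr. These rates were chosen as a realistic
radiation profile in which most branching happens before the slice, so the
early epoch carries real information. Passing tests on these data show the
estimators recover the structure they assume; they do not show robustness
to the things real data add — sampling biases, measurement error in habit
scoring, spatially structured occurrence error, or niche evolution
violating the piecewise-OU form.

A candid limitation surfaced by the recovery study: with parameter counts
matched, the habit-dependent-early and class-dependent-early models are
hard to tell apart at a few hundred tips when early habit transitions are
frequent, because habit then accumulates monotonically through the early
epoch and doubles as a clock that the habit-dependent model can exploit.
The true scenario attains the lowest AIC in roughly half to three quarters
of replicates depending on the realization, while the within-scenario
rate ordering (early evergreen->deciduous rate above the late rate) is
recovered almost always. The unsliced analogue of the contrast, with class
contrast present throughout the tree, is recovered cleanly — the ambiguity
is specific to epoch-confined rate variation.

## Problem sizes and numerical defaults

Recovery studies run at: SSE 20 replicates of ~170-tip trees (6 models, 2
optimizer starts); OUV 20 replicates of 200-tip trees with 8 shared maps;
GLMM coverage 20 replicates of 100 species at reduced MCMC (2 chains x 900
iterations); simulation-based calibration 200 replicates of 40 species.
Full-scale analysis defaults mirror the empirical study: ~226-336 species,
100 stochastic maps, 4 chains x 10000 iterations (2000 warmup, thin 10).
Numerical defaults: ODE rtol 1e-8 / atol 1e-10; rate bounds [1e-6, 10] per
Myr; ultrametricity tolerance 1e-6 x tree height with a terminal-branch
repair for rounding noise; covariance ridge 1e-10 on near-singular
matrices; survival-factor floor 1e-12. Every random operation takes an
explicit seed, and the pipeline derives per-stage seeds from one global
seed via SHA-256 so stages are independently rerunnable.
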