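# Methods

## The model

`bmmlr` analyses trials with K correlated binary outcomes collected from
subjects nested in J clusters (centers, hospitals, sites), with a 0/1
treatment indicator and subject-level covariates, in the presence of
treatment heterogeneity.

The joint distribution of the K binary outcomes (a multivariate Bernoulli)
is parametrized through the Q = 2^K joint response patterns: the pattern
matrix H enumerates them with row 1 = all successes and row Q = all
failures (the reference category), intermediate rows in decreasing binary
order; for K = 2 the categories read ({11}, {10}, {01}, {00}).  The joint
probabilities follow a multinomial logistic regression

    phi_q(x) = exp(psi_q) / (sum_{r<Q} exp(psi_r) + 1),
    psi_q = x' gamma_q,     psi_Q = 0  (identifiability),

and marginal success probabilities are the linear maps
theta_k = sum_q H[q,k] phi_q.

Three analysis models are implemented:

* **BMMLR** (the main model): a mixed-effects multinomial logistic
  regression.  Selected coefficients vary by cluster,
  gamma_qj = gamma_q0 + u_qj with u_qj ~ N(0, Sigma_q) per free category;
  the rest are fixed effects shared across clusters.
* **BMLR**: the single-level restriction (fixed effects only).
* **BMB**: the conjugate multivariate-Bernoulli analysis — per arm, joint
  category counts plus a Dirichlet prior give a closed-form Dirichlet
  posterior for phi.  Clustering and covariates are ignored; conditional
  effects come from subsampling.

## Posterior computation

The multinomial likelihood has no conjugate prior, so the samplers use
Pólya-Gamma data augmentation with a per-category binary-logistic
reduction.  Conditional on the other categories' current linear predictors,
category q's contribution to the likelihood is a binary logit in
eta_i = psi_qi − C_i with offset C_i = log(sum_{r≠q} exp(psi_ri) + 1)
(the reference category contributes the 1).  Drawing omega_i ~ PG(1, eta_i)
makes the conditional likelihood Gaussian in psi_q with precision omega_i
and working response (z_i − 1/2)/omega_i + C_i, where z_i indicates
membership of category q.  Every coefficient block is then conditionally
multivariate normal and each Sigma_q conditionally inverse-Wishart, so a
sweep is direct sampling throughout, cycling per category:
omega → beta_q (fixed) → gamma_qj per cluster → gamma_q0 → Sigma_q.
The update order within a sweep is a convention; it does not affect the
stationary distribution.  Clusters of size 1 are handled by the same
conditional (their random effect shrinks to the population mean).

PG(1, c) variates are sampled exactly with Devroye's alternating-series
rejection sampler (truncated inverse-Gaussian proposal below t = 0.64,
exponential tail above), compiled with numba; the implementation is checked
against the moment identity E[omega] = tanh(c/2)/(2c) and Var[PG(1,0)] =
1/24.  The inverse-Wishart draw uses the Bartlett decomposition.

Priors follow the defaults: independent N(0, 10) on every fixed effect and
random-effect mean per category, inverse-Wishart(2, 0.1 I) on each
Sigma_q, and Dirichlet hyperparameters 0.01 per category for BMB.  An
improper uniform prior on Sigma_q is available; it is refused when
J ≤ 2·dim(Sigma) because the conditional would be improper.
Initialization is neutral (all coefficients 0, Sigma at its prior scale);
burn-in absorbs it.  Chains are stored unthinned; thinning is applied in
the transformation step.  Fixed seeds give bit-identical chains.

A practical caveat found while testing: pinning Sigma_q very close to zero
through the prior (scale ~1e-4 with large df) makes the (gamma_j, gamma_0)
pair nearly rigid and freezes the Gibbs chain — hierarchical non-centering
would be needed for that regime.  Moderate pinning mixes fine.

## Transformation to treatment effects

For each retained draw, every reference subject's phi is evaluated under
their own arm and design row, averaged within cluster-arm cells over the
subjects in the (sub)population, converted to theta, differenced between
arms per cluster (delta_j = theta_Aj − theta_Cj), pooled with
cluster-size weights delta = sum_j n_j delta_j / sum_j n_j, and optionally
collapsed to the weighted composite delta(w) = sum_k w_k delta_k.

Design choices that were genuinely open:

* **Averaging set** — arm-restricted by default (each subject contributes
  under the arm they were observed in); a counterfactual variant (everyone
  under both arms) exists behind an explicit design-row builder and is off
  by default.
* **Empty cells** — clusters whose arm cell is emptied by interval
  filtering are dropped from the pooled estimate and the weights
  renormalize over the remaining clusters.
* **Pooling weights** — n_j counts the subjects contributing to the
  population estimate (both arms combined), not the raw cluster size.
* **Estimand / cluster mode** — `cluster_mode="observed"` evaluates each
  cluster at its own gamma_qj draws: inference about the observed sample of
  clusters.  `cluster_mode="population"` evaluates at the gamma_q0 draws,
  so the pooled effect carries between-cluster uncertainty and refers to
  the cluster population; this is also how a new, unobserved cluster is
  predicted.  The distinction matters: with many subjects per cluster the
  observed-mode posterior concentrates on the realized cluster sample, so a
  test of the population-level null from it is anticonservative (we measure
  Any-rule Type I error around 0.25 at J=10, n_j=100 in observed mode
  versus ~0.05 in population mode).  The simulation harness therefore uses
  population mode; for describing the effect in the observed centers,
  observed mode is the right choice.

Subpopulations are specified as the full reference sample, an interval of
one covariate (empirical averaging over subjects inside it), or a point
value of the covariate profile (plugged directly into the linear
predictor).

## Decision rules

Superiority regions on delta (strict inequalities): Single
(delta_primary > 0), All (min delta_k > 0), Any (max delta_k > 0, reported
per outcome), Compensatory (delta(w) > 0).  Evidence is the fraction of
effect draws in the region; superiority is concluded above p_cut,
inferiority below 1 − p_cut.  Cutoffs calibrate the frequentist Type I
error to alpha: one-sided 1 − alpha (All, Compensatory, Single; the Single
cutoff is by analogy with the univariate case) and 1 − alpha/K (Any);
two-sided tests halve alpha.  The Any rule is evaluated per outcome
against its multiplicity-corrected cutoff, so a two-sided analysis can
report superiority and inferiority simultaneously on different outcomes;
this contradiction is reported, not resolved.

## The synthetic-data generator

`generate_dataset` draws trials from a two-level mixed-effects model with
K = 2 outcomes and one standard-normal covariate w:

    psi_q = (g0_q + u0_jq) + (g1_q + u1_jq) T + b2_q w + b3_q w T,
    (u0_jq, u1_jq) ~ N(0, 0.1 I)  independently per free category,

with the default coefficient matrix (categories in columns q1..q3; the
reference column is zero):

    intercept   0.000  0.433  0.433
    T           0.000  0.000  0.000
    w           1.027  0.601  0.427
    w*T        -2.055 -1.201 -0.854

Each cluster receives n_j subjects in each arm.  These defaults encode a
heterogeneous treatment effect whose pooled average is exactly zero (the
least favorable null for the Any and Compensatory rules) with negatively
correlated outcomes (population correlation −0.157 from the fixed-effects
structure, −0.163 with random effects integrated).  Conditionally on the
covariate the effect is positive below the mean: at the point w = −1 the
true effect is delta = (0.25, 0.15), delta(w) = 0.20 with equal weights;
averaged over the band w in [−1, 0] it is delta = (0.116, 0.069),
delta(w) = 0.092, with within-band outcome correlation −0.20.  The
per-category independence of the random effects matters for the study's
conclusions: sharing one (u0, u1) across categories largely cancels in the
marginal success probabilities and erases the single-level models' Type I
inflation that the study demonstrates.

`true_effects_oracle` computes all of these quantities by brute-force
Monte-Carlo integration over the covariate (truncated normal for
intervals), the random effects and both arms — it never touches the
samplers, so it serves as an independent reference for the transformation
pipeline.

What the generator does **not** emulate about real multicenter trials:
unequal and skewed cluster sizes (real registries have singleton centers),
cluster-level covariates, covariate distributions with skew or bounded
support, missingness, and non-randomized treatment assignment.  Passing
operating-characteristic checks therefore demonstrates correctness of the
machinery under the stated generating model, not robustness to those
features.

## The operating-characteristics study

`run_study` replays generate → fit → transform → decide over replicate
datasets and tabulates superiority proportions with binomial standard
errors, plus coefficient-bias summaries for the multilevel model.  Default
conditions: J in {10, 100} clusters, n_j in {10, 100} subjects per arm per
cluster; decisions with right-sided tests at alpha = 0.05 (Compensatory
weights (0.5, 0.5)); the conditional-effect population is the covariate
value one SD below the mean for the regression models and, for the
subsampling BMB analysis (which cannot condition on a point), the adjacent
band [−1, 0].  Replicate seeds are spawned from one master seed, so runs
are reproducible and parallelizable; sampler failures are recorded and
excluded from denominators, never silently dropped.

Full-scale settings (50,000 retained draws + 10,000 burn-in, 2 chains,
transformation thinning 10, 1000 replicates) are the `McmcSettings`
defaults.  The scaled desk settings used by the tests and the acceptance
script are one chain of 2000 retained + 500 burn-in draws with thinning 5
(~400 effect draws, enough resolution for a 0.975 cutoff) and 24–200
replicates per cell; the bias check uses J=100, n_j=50 with 24 replicates,
where the replicate-to-replicate spread of posterior means (~0.05 per
coefficient) averages down far enough for a 0.01 bias bound to be
informative.

## Diagnostics

Brooks–Gelman multivariate PSRF (with the classic univariate Gelman–Rubin
factors) over ≥2 chains; values near 1 indicate no evidence of
non-convergence and 1.10 is the conventional threshold.  A tiny ridge
(1e-12 of the trace) keeps the eigenvalue solve defined when a parameter
has zero within-chain variance.  Sample autocorrelations per parameter
block (constant chains return NaN as the flagged value).  Thinning keeps
every k-th post-burn-in draw.  Diagnostics never mutate chains.

## Numerical choices

* Softmax is stabilized by subtracting the running maximum; the offset
  C_i uses the same log-sum-exp guard.
* Probability vectors are validated to sum to 1 within 1e-10 (double
  precision headroom).
* Ties at exactly p_cut do not conclude (strict inequality).
* Degenerate Bernoulli margins make the outcome correlation undefined; an
  error is raised rather than returning a sentinel.

## Known limitations

* Two levels only; no cluster-level covariates or cross-level
  interactions.
* The number of joint categories grows as 2^K; K ≤ 10 is enforced and
  K ≥ 4 will be slow and sparse.
* The Gibbs sampler mixes slowly when the random-effect variance is
  (nearly) pinned at zero, and autocorrelations of cluster-specific
  parameters are high in general — long chains and thinning are the
  intended workflow.
* Bayes-factor model comparison and intraclass-correlation estimates for
  binary data are out of scope.
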