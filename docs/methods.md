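# Methods

## Model

A trial is a Wiener process X(t) with drift ν and diffusion scale s,
started at z = z_rel·a between absorbing boundaries 0 and a.  The response
is the boundary reached first; the response time is the first-passage time
plus a non-decision constant T_ER, below which the RT density is exactly
zero.  The defective first-passage densities integrate to the closed-form
choice probabilities, which is what makes two-boundary likelihoods and
distance statistics well defined.  Between-trial variability parameters
(s_ν, s_z, s_t) are fixed at zero throughout: every estimator and the
generator operate on the four-parameter model.

The diffusion scale is a convention, not a parameter: (a, ν) scale linearly
with s while z_rel and T_ER are scale-free.  The package works on the s = 1
scale everywhere; the EZ closed form is evaluated on its traditional
s = 0.1 scale and its (a, ν) output multiplied by 10, which is numerically
identical to computing at s = 1 and preserves the classic formulation.

## Numerical evaluation

Two classical series represent the density: a sum over mirror images
("small-time") and a sine series ("large-time").  Each evaluation picks the
representation needing fewer terms for an absolute truncation tolerance of
1e-10 on the time-normalized density (Navarro–Fuss term-count bounds); the
test suite checks the two representations against each other on their
overlap region to 1e-9 and the density against quadrature-vs-closed-form
identities to 1e-6.  Extreme drifts are handled by assembling the density
in log space so the exponential tilt cannot overflow.

The distribution function uses a closed-form image expansion in Gaussian
CDFs (via log-CDFs, again overflow-safe) for normalized times
t_dec/(a/s)² ≤ 2 and the term-wise integral of the sine series above that;
the switch point is far inside both representations' comfortable regions.

Likelihoods floor the per-trial density at 1e-300 before the log; a trial
with rt ≤ T_ER makes the log-likelihood −∞ (the model says such data are
impossible), which is why the optimizers parameterize T_ER strictly below
the fastest observed response.

## Simulation

Trials are sampled exactly: the boundary indicator from the closed-form
choice probability, the RT by inverting the conditional defective CDF with
vectorized bisection (70 iterations, bracketing by doubling).  An
independent fine-step Euler random-walk simulator exists purely as a test
oracle; it cross-validates choice fractions and RT location on biased
cells.  The generator applies no RT ceiling or truncation.

Dataset screening flags a dataset as problematic when either boundary
receives fewer than 4 % of the trials (including zero crossings).
`problematic_fraction` evaluates the rule on freshly drawn binomial
boundary counts, which is exactly the sampling distribution of the counts,
so no RT sampling is spent on a count-only statistic.

## Estimators

**EZ.**  Closed-form inversion of (MRT, VRT, Pc) under z = a/2.  Pc is the
proportion of upper-boundary responses; MRT and VRT are by default the mean
and unbiased variance of *all* RTs (`scope="all"`), with an upper-boundary
conditional variant available.  Under the EZ model's own z = a/2 assumption
the two coincide in population (the conditional RT distributions at the two
boundaries are identical for a symmetric start); on biased data they
differ, and the all-trial convention is the one whose full-grid behaviour
(count and parameter profile of negative T_ER estimates, drift-recovery
correlation) matches the reference results this package reproduces.  Edge
proportions 0, 0.5, 1 are replaced by 1/(2n), 0.5 + 1/(2n), 1 − 1/(2n).
The inverted T_ER may be negative; that invalid-estimate pathway is
deliberately preserved (returned via an unchecked parameter container) and
tabulated by the study pipeline rather than masked.

**CS.**  Pearson χ² between observed and expected counts in RT-quantile
bins, six per boundary, cut at the 0.1/0.3/0.5/0.7/0.9 linear-interpolation
sample quantiles (outer bins unbounded); expected counts are n times the
model's defective CDF masses.  A boundary with fewer than 5 responses
collapses to a single bin carrying that boundary's full model mass — a
documented stand-in for behaviour the original sources leave open.  The
unminimized statistic at the true parameters averages near B − 1 = 11; the
minimized statistic near C(B−1) − P = 7, the degrees of freedom the fit
statistic is referred to.

**KS.**  The two empirical defective CDFs are joined into one super-curve
by mirroring lower-boundary RTs to the negative axis; the statistic is the
sup distance to the model's super-curve, evaluated on both sides of every
empirical jump (where the sup of a jump function minus a continuous one is
attained).  The curve crosses the origin at the proportion of lower
responses.  The asymptotic critical value is Q_α = sqrt(log(2/α)/2).

**ML.**  Minimizes the deviance −2·log L.  Three searches are provided.
The simplex (Nelder–Mead) fits — used for ML, CS and KS — run in raw
parameter space inside a penalty box, with an explicit initial simplex
whose T_ER vertex reaches most of the way to the fastest response; this
matters because the conventional start T_ER⁰ = 0.001 otherwise strands the
simplex on a flat region (observed failure mode: convergence to a spurious
basin with inflated a and T_ER ≈ 0).  One restart from the first solution
guards against premature collapse.  The gradient-based variants (BFGS,
finite-difference step 1e-4; Newton-type via Newton-CG with
finite-difference gradients) work in a smooth unconstrained transform
(log a, logit z_rel, logit of T_ER as a fraction of the minimum RT, raw ν),
which prevents the T_ER-above-min-RT failure by construction.  Iteration
caps default to 5,000.  Standard errors for ML are observed-information
(finite-difference Hessian at the optimum); the distance and closed-form
methods report none, since no comparable plug-in estimate exists.

**Bayes.**  Random-walk Metropolis-within-Gibbs: one Gaussian proposal per
parameter per sweep against log-likelihood plus log-prior, proposals
outside the uniform prior support rejected.  Scales adapt every 25 sweeps
toward a 20–50 % acceptance rate during 500 discarded adaptation sweeps;
500 draws per chain are then retained from each of 3 chains with fixed
starts (a = 1/2/prior-floor, T_ER = 0.001, ν = 0.5/−0.5/0, z_rel = 0.5 —
the nominal third start a = 0 is infeasible under any positive prior and is
clamped to the prior floor 0.0001).  Point estimates are EAP over the
concatenated chains.  Two prior presets exist because the traditional
drift prior U(0, 1) cannot recover negative drifts: "paper" keeps it, and
"symmetric" (U(−5, 5), the study default) widens it.  The sampler was
cross-checked against an independent ensemble sampler (emcee) on the same
posterior.

Convergence is monitored with the Gelman–Rubin PSRF,
sqrt(((n−1)/n·W + (1+1/m)·B/n)/W); its floor for identical chains is
sqrt((n−1)/n) ≈ 0.999 at n = 500.  The upper limit inflates the
between-chain component by an F quantile (Brooks–Gelman-style
approximation).  The point estimate matches arviz's classic (identity)
R-hat to 2e-3 in tests.

## Recovery study

The study grid crosses a ∈ {0.5, 1, 1.5, 2}, z_rel ∈ {0.2, 0.5, 0.8},
T_ER ∈ {0.1, 0.3, 0.5}, ν ∈ {−1, −0.5, 0, 0.5, 1} and n ∈ {50, 100, 400}:
540 cells, 5 datasets per cell, 3 starting-value replications — 8,100 runs
per method, with starting values a⁰, z⁰, ν⁰ ~ U(0.2, 0.8) and T_ER⁰ fixed
at 0.001.  Per-dataset seeds derive deterministically from one root seed
(SeedSequence spawning), so any slice of the study is reproducible.
Deterministic methods (EZ; Bayes with its fixed chain scheme) are computed
once per dataset and repeated across replications, matching how such
studies account runs.  Screening flags are carried in the records but
datasets are not excluded.

Evaluation: bias = mean(est − truth) and RMSE per grouping (default
parameter × method × true value × n); Pearson correlations of truth with
estimates, of estimates across methods (the EZ starting-point column is
structurally unavailable and stays NaN), and of descriptive sample
statistics with true and estimated parameters; the tabulation of negative
EZ non-decision times by level of each true parameter; and per-parameter
Type-III ANOVA of cell-level RMSE (one RMSE per true value × method × n
cell; true value and trials numeric 1-df covariates, method categorical,
all interactions, intercept reported).  The aggregation level is inferred
from the reference tables' degrees of freedom.

## Problem sizes and what the tests show

The acceptance checks run the EZ analysis at the full 8,100-run scale
(closed form, fast) and the iterative-method checks at reduced scale (one
dataset, one replication per cell for the 540-fit ML run; a denser
12-dataset n = 50 grid for the χ² boundary-bias pattern, whose
heavy-tailed errors in sparse-boundary cells need the extra replicates;
small replicate counts for MCMC checks).  Monte-Carlo tolerances are
derived from binomial/sampling error at those sizes.

The generator emulates the study's synthetic conditions exactly — iid
trials from the four-parameter model on a fixed grid.  It does not emulate
real data's contaminants, outliers, between-trial parameter variability,
or multi-condition structure, so passing recovery tests demonstrate
estimator correctness under the model, not robustness to model violation.

## Known limitations

* The χ²-method bias magnitudes reported for PDE-based engines are larger
  than what this exact-CDF implementation produces; the qualitative
  pattern (upward boundary bias concentrated at small n, large a, sparse
  boundaries) reproduces, the engine-specific magnitude does not.
* The screening-rule simulation reports the exact consequence of the
  stated 4 % rule; see the acceptance output for the values it yields.
* Run times are logged per fit but asserted nowhere; they are
  hardware-dependent.
* Hierarchical (multi-subject) models, WLS/G² objectives, EZ2 and robust-EZ
  variants, and contaminant mixtures are out of scope.
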