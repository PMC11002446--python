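# Methods

This note documents the models, estimators and numerical choices behind
`causalfoodq`, what the synthetic templates do and do not emulate, and
the known limitations.

## Structural causal models and simulation

A structural causal model (SCM) here is a DAG plus, per node, a
mechanism, a Gaussian noise scale and a measurement kind.  Sampling is
ancestral: in topological order, each node's latent value is

    x_k = b0_k + sum_j  b_jk * g_jk(x_j) + eps_k,    eps_k ~ N(0, sd_k^2)

over the node's parents, where g_jk is an optional per-edge transform
(identity; `saturating` = softplus((x − c)/s), a smooth ramp that is ~0
below the change point c and ~linear above it; or quadratic).  The
latent value is then mapped to the declared scale: continuous nodes
keep it, binary nodes threshold it (probit-style latent Gaussian),
ordinal nodes bin it at fixed strictly-increasing cut points.
Crucially, *children read observed parent values* (binary 0/1, ordinal
codes), so the sampled table is exactly Markov with respect to the DAG
— conditional-independence structure survives discretization, which is
what makes the templates usable as structure-learning ground truth.

Latent-Gaussian generation of discrete scales was chosen over logistic
or multinomial mechanisms because it keeps closed-form oracles: for any
all-continuous, all-identity SCM the implied covariance is
(I − B)⁻ᵀ D (I − B)⁻¹, which the tests compare against sample
covariances (relative Frobenius error < 2 % at n = 50 000).

Seeding: one integer seed per sampling call, split per node via
`SeedSequence(seed, spawn_key=(rank,))` with rank = position in sorted
node-name order.  Identical (SCM, n, seed) reproduce tables bit-exactly,
and adding an unrelated node does not perturb existing draws.

### Templates

The three presets mimic the *structure* of typical food-quality studies,
not any real dataset's numbers.  All coefficients are fixed named
constants.

- **wheat** — 45 continuous predictors of a continuous baking-quality
  volume.  Ten actives: nine direct parents of volume (protein
  dominating at +0.71 standardized) plus total high-molecular-mass
  glutenin, an *indirect* cause acting only through protein (+0.42).
  The 35 distractors load on 4 shared latent factors (sampled but not
  exported), which also drive the actives, producing a strongly
  collinear table (mean |r| ≈ 0.29) in which the actives explain ~97 %
  of the volume variance.  Distractor loadings are drawn from the
  template seed.
- **dairy** — 7 mixed-scale variables.  Temperature (°C, mean 47,
  sd 13) and fat are exogenous; pH, colour, binary odour and turbidity
  are temperature's children; binary taste (parents: temperature,
  colour, fat) and a 3-level ordinal grade (parents: temperature,
  turbidity, odour, fat) are colliders.  Weights were set so the
  grade–temperature correlation is ≈ −0.46 and the taste–fat
  correlation ≈ +0.33.  The binary/ordinal latent signal-to-noise is
  kept moderate: near-deterministic thresholds make the probit
  conditional mean strongly nonlinear, and the resulting distortion can
  make BIC prefer spurious extra edges; with moderate noise the
  declared structure is the exact CPDAG recovered by hill climbing in
  ~90 % of n = 5000 draws, with the residual misses being one weak
  extra or flipped edge that genuinely scores higher on that draw.
- **wine** — 10 continuous physicochemical predictors plus a 10-level
  ordinal quality grade (unit-variance latent binned at ±2 sd).  The
  five quality parents (alcohol +0.35, volatile acidity −0.20,
  sulphates +0.18, free SO₂ +0.12, chlorides −0.08) are exogenous and
  mutually non-adjacent; the remaining predictors are their children.
  This makes every predictor's total effect either purely direct or
  exactly zero, so the structural path-sum and the
  all-other-covariates DML convention estimate the same quantity — the
  design under which the structural-vs-DML concordance claim is
  testable.

What the templates do *not* emulate: non-Gaussian measurement error,
heteroskedasticity, missing data, panel/repeated-measure structure, and
real measurement units.  Passing tests therefore demonstrate estimator
correctness under the declared generative assumptions, not performance
on any particular real dataset.

## Feature screening

Elastic net with the 1/(2n) convention, so λ is sample-size-stable;
α ∈ [0, 1] is the L1 fraction (default 0.5, a flag — the mix is a
choice, not an estimate).  λ is selected at the minimum of the K-fold
(default 10) mean CV squared error over a 100-point log grid descending
four decades from λ_max = max_j |X_jᵀ(y − ȳ)|/(n α); no one-standard-
error rule.  The intercept is never penalized.  The coordinate-descent
solver is scikit-learn's (identical objective); the KKT conditions
(|X_jᵀr|/n ≤ λα on the inactive set) and the orthonormal-design
soft-threshold closed form are asserted in the tests.  At λ = 0 the
solver is replaced by exact least squares.  `variance_explained` is the
R² of an unpenalized OLS refit on the selected set.

## Structure learning

Score: BIC = max log-likelihood − (k/2) log n, maximized (sign
conventions differ across texts; this one is fixed throughout).  The
default score family treats every column numerically — binary as 0/1,
ordinal as level codes — and scores each node by Gaussian linear
regression on its parents (k = #parents + 2 for slopes, intercept,
variance), computed from a precomputed centered cross-product matrix so
a local score costs O(p³) in the parent count.  This numeric treatment
matches how quality grades are handled throughout the package.  A
conditional-Gaussian family (`family="cg"`) scores declared discrete
nodes as multinomials over discrete-parent configurations and refuses
continuous parents for discrete nodes; it is admissible only for
datasets whose discrete nodes have discrete parents, which the preset
food structures do not satisfy — hence the numeric default.

Hill climbing applies the best of all legal add/delete/reverse
single-edge moves until no move improves the score; ties break
lexicographically on (move type, parent, child), making the result
deterministic and column-order invariant.  Default 10 random restarts
(edge probability 0.2) plus the empty graph.  Whitelists force edges,
blacklists forbid them; the pipeline's learn stage blacklists all edges
*out of* the response by default (`response_sink`), encoding the field
knowledge that a quality assessment is an effect, never a cause, of the
process variables.

Structure MCMC is Metropolis–Hastings over DAGs: uniform proposal over
legal single-edge moves with the |N(G)|/|N(G′)| Hastings correction,
uniform structure prior, and exp(ΔBIC) as the posterior-ratio
surrogate.  Edge frequencies after burn-in (defaults 20 000 / 2 000)
estimate edge posteriors; on ≤ 3-node problems they match exact
enumeration over all 25 DAGs within ±0.05.

CPDAGs are computed by orienting v-structures and propagating Meek's
rules 1–3 to fixpoint (rule 4 is only needed with background-knowledge
orientations, which the CPDAG of a fully oriented DAG never has).

## Causal effects on a fixed DAG

d-separation uses the standard reachability ("Bayes-ball") procedure,
linear in the edges per query; the exponential path-enumeration
implementation in `causalfoodq.exact` serves as its oracle.  Backdoor
sets enumerate subsets of the treatment's non-descendants and test
d-separation in the graph with the treatment's outgoing edges removed;
the default adjustment set is the smallest minimal one (lexicographic
tie-break).  Subset enumeration is exponential in the candidate pool —
fine at food-table sizes (≤ ~15 non-descendants), cappable via
`max_size`.

Path coefficients regress each node on all its parents (standardized
scale by default); direct effects always condition on the child's full
parent set, consistent with linear-SCM semantics.  Total effects sum
path-coefficient products over all directed paths; their standard error
uses the delta method with per-child OLS variances treated as
independent across child regressions and diagonal within one (a mild
approximation; the dominant single-path terms are exact).

Ordinal outcomes are coerced to numeric level codes for effect
estimation, which is why effects are reported in "grade per unit"
terms; discretizing the outcome attenuates effects relative to the
latent scale, identically for all estimators compared.

`do_curve` realizes E[Y | do(x)] nonparametrically: an ensemble
(default 20 members) of one-hidden-layer (32 units, early stopping)
neural regressors of outcome on (treatment, Z), each fit to a bootstrap
resample, marginalized over the empirical Z distribution (the backdoor
formula).  The band is the central 90 % of the member curves — a
bootstrap-ensemble realization of predictive uncertainty, chosen over
explicit variational Bayes because the contract is only a predictive
distribution per grid point.  ACE(x) is the central-difference
derivative (one-sided at the endpoints); grid points outside the
observed treatment support are flagged as extrapolation.

## Double machine learning

The partially linear residual-ratio estimator
θ = Cov(r_Y, r_T)/Var(r_T) with K = 5 cross-fitting folds by default;
`n_folds=1` reproduces the naive plug-in for comparison, and `repeats`
reports the median over fresh fold splits.  The standard error comes
from the influence function ψ = (r_Y − θ r_T) r_T / E[r_T²].  The
covariate set for a "total ACE of x_k" defaults to all other observed
predictors, and all variables are standardized when reporting relative
factors.

The default nuisance learner is a **linear-detrended forest**: exact
OLS plus a 100-tree random forest (minimum leaf 25) on the OLS
residuals.  Food-table nuisance relationships are dominated by linear
trends with milder nonlinearity on top; a pure forest underfits strong
linear signal, and the resulting nuisance bias is exactly what the
residual-ratio estimator cannot forgive for treatments that are highly
predictable from the covariates.  Profiling the linear part out at the
parametric rate removes that failure mode while the forest still
absorbs nonlinear structure.  A plain 500-tree forest remains available
as `learner="rf"`, and any scikit-learn regressor can be plugged in.

## Predictive forests

Bagging of depth-unlimited decision trees (minimum leaf 5) with `mtry`
candidate variables per split — defaults 500 trees and p/3 (regression)
or √p (classification).  The tree learner is scikit-learn's; the
bootstrap bookkeeping and OOB metrics are owned here: each row is
scored only by trees whose bootstrap excluded it (assertable from the
stored per-tree indices), regression reports OOB R², classification the
OOB misclassification rate and confusion table.  Rows in-bag for every
tree (possible at very small ensembles) are excluded with a warning.

## Pipeline and seeding

One global integer seed; stage seeds derive via
`SeedSequence(seed, spawn_key=(stage_rank,))`, so no stage consumes
another's stream and reruns are bit-identical.  Every table in the
Markdown report is also emitted as CSV — the report is a view, not a
source.

## Problem sizes

The validation suite runs at the sizes where the relevant asymptotics
are visibly engaged but desk-scale: n = 5000 for effect estimation and
structure recovery (20 seeds), n = 1000 for the 45-variable selection
problem, n = 50 000 for the covariance-oracle check, 20 000 MCMC
samples for posterior calibration.

## Known limitations

- Identification is backdoor-only: no front-door or instrumental
  variables, no latent-confounder discovery, no counterfactual
  (unit-level) queries.
- Linear-SCM semantics for path coefficients and total effects; for
  nonlinear responses only `do_curve` is appropriate.
- The delta-method se of the path-sum ignores cross-regression
  covariances.
- Backdoor-set enumeration and the `exact` oracles are exponential and
  meant for small graphs.
- The MCMC posterior uses exp(BIC) as a marginal-likelihood surrogate,
  a unit-information-prior-style approximation, with a uniform prior
  over structures.
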