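# causalfoodq

Causal analysis of food-quality data: from a table of process,
composition and sensory variables to *deconfounded* estimates of what an
intervention would actually do to perceived quality.

## The problem

Food-quality studies relate physicochemical measurements (protein
content, pre-treatment temperature, alcohol, acidity, ...) to consumer
or panel quality assessments.  Ordinary regression on such tables is
predictive but not causal: the variables are heavily confounded, so a
regression coefficient mixes the effect of a variable with the effects
of everything correlated with it.  A process engineer who asks *"what
happens to quality if I raise the fermentation temperature?"* needs the
interventional quantity E[Y | do(x)], not the conditional E[Y | x].

`causalfoodq` implements the full workflow:

1. **Feature screening** — elastic net (LASSO + ridge),
   minimizing (1/2n)‖y − Xβ‖² + λ[α‖β‖₁ + (1−α)/2 ‖β‖₂²],
   with λ chosen by K-fold cross-validation, plus PCA variance summaries.
2. **Structure learning** — score-based Bayesian-network search over
   DAGs G = {V, E}: decomposable BIC (log-likelihood − (k/2) log n),
   greedy hill climbing with restarts, and Metropolis–Hastings structure
   MCMC giving posterior edge probabilities P(i→j | X).
3. **Graphical causal inference** on the learned (or supplied) DAG —
   d-separation by reachability, minimal backdoor adjustment sets,
   standardized path coefficients by per-node OLS, total effects as sums
   over directed paths of path-coefficient products, and the
   backdoor-adjusted ACE = ∂E[Y | do(x)]/∂x.
4. **do(x) intervention curves** — a bootstrap ensemble of small neural
   regressors marginalized over the adjustment covariates (the backdoor
   formula), with a central 90 % band and the pointwise derivative
   ACE(x); captures nonlinear responses such as saturation effects.
5. **Double machine learning** — a structure-free cross-check: the total
   ACE as the cross-fitted residual ratio
   θ = Cov(r_Y, r_T) / Var(r_T), where r_Y and r_T are out-of-fold
   residuals of outcome and treatment after flexible regression on the
   remaining covariates.
6. **Predictive baselines** — bagged decision-tree models of quality
   with out-of-bag (OOB) evaluation.

A first-class synthetic-data module generates datasets from structural
causal models with known DAGs, coefficients and noise — including three
presets emulating typical study designs (a wide collinear *wheat* baking
table, a mixed-scale *dairy* consumer table, a *wine* physicochemistry
table with a 10-level tasting grade) — so every estimator can be
validated against ground truth.

## Worked example

The textbook confounding triangle: Z → T, Z → Y, T → Y with structural
equations T = Z + e and Y = 0.5·T + Z + u.  The true effect of T on Y is
0.5; a naive regression is biased to 0.5 + Cov(T,Z)/Var(T) = 1.0.

```python
from causalfoodq import DAG, make_scm, sample_dataset, ace_adjusted, dml_ace, backdoor_sets
import numpy as np

dag = DAG(["Z", "T", "Y"], [("Z", "T"), ("Z", "Y"), ("T", "Y")])
scm = make_scm(dag, {("Z", "T"): 1.0, ("Z", "Y"): 1.0, ("T", "Y"): 0.5})
data = sample_dataset(scm, 5000, seed=1)

num = data.to_numeric()
print(f"naive OLS slope      : {np.polyfit(num['T'], num['Y'], 1)[0]:.3f}")

sets = backdoor_sets(dag, "T", "Y")
print(f"minimal backdoor set : {sorted(sets[0].conditioning)}")

eff = ace_adjusted(data, dag, "T", "Y", standardize=False)
print(f"adjusted ACE         : {eff.estimate:.3f} +/- {eff.se:.3f}")

res = dml_ace(data, "T", "Y", covariates=["Z"], seed=0, standardize=False)
print(f"DML ACE              : {res.theta:.3f} +/- {res.se:.3f}")
```

prints

```
naive OLS slope      : 1.012
minimal backdoor set : ['Z']
adjusted ACE         : 0.519 +/- 0.014
DML ACE              : 0.517 +/- 0.014
```

The naive slope doubles the true effect; both the backdoor-adjusted OLS
and the structure-free DML estimator recover 0.5 within two standard
errors — and agree with each other, which is the package's built-in
cross-validation of structural against unstructured causal estimates.

## Command line

```bash
causalfoodq simulate --template dairy --n 5000 --seed 7 --out dairy.csv
causalfoodq learn    --data dairy.csv --method hc --seed 1
causalfoodq ace      --data dairy.csv --dag structure.dot \
                     --treatment temperature --outcome grade --dml --curve
causalfoodq run config.yaml      # full pipeline from a YAML config
```

The pipeline (`run`) executes simulate/load → select → learn → effects
→ dml → predict from one configuration with a single global seed, and
writes every table as CSV plus a Markdown report and a JSON summary;
rerunning the same configuration reproduces every number bit-exactly.

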