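# avibrain

Phylogenetic comparative analysis of relative brain size, built as a
tested, reusable pipeline. The package is aimed at comparative
biologists who want to ask which ecological, social, or developmental
variables predict brain size across a clade once body-size allometry and
shared ancestry are accounted for — and to validate every step of that
analysis on synthetic data with known ground truth.

## The model

Species trait values are not independent: close relatives resemble each
other. All regressions here are phylogenetic generalized least squares
(PGLS) fits of

```
y = X β + ε,   ε ~ N(0, σ² V_λ)
```

where `V` is the Brownian-motion covariance implied by an ultrametric
phylogeny (`V[i,j]` = depth of the most recent common ancestor of
species *i* and *j*) and `V_λ` multiplies the off-diagonal entries of
`V` by Pagel's λ ∈ [0, 1]. λ = 1 is pure Brownian motion, λ = 0 treats
species as independent; λ is estimated by maximum likelihood from the
profile likelihood unless held fixed. Estimation is ML (not REML), so
AIC is comparable across models with different fixed effects.

On top of this core the pipeline provides:

* **Allometric residuals.** Brain volume scales with body mass
  (log₁₀–log₁₀ linear), with intercepts and slopes that shift among
  major clades. Three candidate PGLS models (global; group intercepts;
  group intercepts + slopes) are compared by AIC, and *relative brain
  size* is the per-species residual from the winning model. Groups with
  fewer than 10 species are pooled into an `"other"` group.
* **Drop-one ΔAIC importance.** Each predictor (multi-level factors as
  whole blocks) is removed from the full model, refitting with λ held
  at the full model's estimate: `ΔAIC = AIC_reduced − AIC_full`, with
  ΔAIC > 2 flagging an important predictor, plus the likelihood partial
  R² `1 − exp(−(2/n)·(logL_full − logL_reduced))`.
* **Phylogenetic signal.** Pagel's λ from an intercept-only fit, with
  percentile parametric-bootstrap confidence intervals.
* **Posterior-tree ensembling.** Every stage re-run over a posterior
  sample of trees (residuals recomputed per tree), reporting across-tree
  means; a maximum-clade-credibility tree can be extracted for plotting.
* **Clade-level re-analysis.** Groups with > 30 species and variation in
  every focal variable are re-analysed with clade-specific single-line
  allometry and their own drop-one tables.
* **Synthetic data.** Yule trees (depth 1), Brownian log-mass,
  λ-structured residual noise, symmetric-Mk categorical predictors, and
  fully recorded ground truth, so power, calibration, and parameter
  recovery are all testable offline.

## Worked example

```python
import numpy as np
from avibrain import *
from avibrain.allometry import comparison_frame

sc = SyntheticScenario(seed=42, effects={"cooperative": {"cooperative": 0.12}})
tree, table, truth = generate_scenario(sc)
cov = vcv(tree)
lb = np.log10(table.column("brain_volume", taxa=tree.tips))
lm = np.log10(table.column("body_mass", taxa=tree.tips))
groups = table.column("group", taxa=tree.tips)

models = fit_allometry_family(lb, lm, groups, cov)
print(comparison_frame(models)[["form", "k", "aic", "lambda", "delta_aic"]])
best = select_allometry(models)
rel = relative_brain_size(best)
rep = importance_table(table, rel.values, ["dev_mode", "cooperative", "migration"], cov)
print(rep.summary)
est = pagel_lambda(rel.values, cov, n_boot=100, seed=1)
print(f"relative brain size signal: lambda = {est.lambda_hat:.3f} "
      f"(95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")
```

prints

```
                   form  k         aic   lambda  delta_aic
                 global  4 -508.959337 0.958932 224.521092
       group_intercepts  5 -680.219675 0.917149  53.260755
group_intercepts_slopes  6 -733.480430 0.887367   0.000000
       term  delta_aic  partial_r2  significant
   dev_mode   8.245920    0.033576         True
cooperative  53.034670    0.167606         True
  migration  -1.636046    0.007849        False
relative brain size signal: lambda = 0.887 (95% CI 0.813-0.935)
```

The two-group scenario was generated with distinct allometric slopes, so
the group-intercepts+slopes model wins decisively (ΔAIC > 53 to the next
form). The cooperative-breeding offset (+0.12 log₁₀ units, injected by
the scenario) and the developmental-mode coefficient (−0.02 per score
unit) are both flagged as important by the drop-one rule, while the null
migration term is not (its ΔAIC is negative: the model improves when it
is dropped). The residual trait retains strong phylogenetic signal, as
expected with λ_true = 0.8.

A command-line interface covers the same stages:

```sh
avibrain simulate --seed 5 --out data/
avibrain trees mcc --in data/trees.nwk --out data/mcc.nwk
avibrain analyze importance --trees data/tree.nwk --traits data/traits.csv --out out/
avibrain run-full --config run.yml
```

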