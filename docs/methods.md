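# Methods

## Model

All inference is phylogenetic generalized least squares. For response
`y` (n species), design `X` (p columns), and a rooted tree with
branch lengths in arbitrary time units, the error covariance is
`σ² V_λ`, where `V[i,j]` is the depth of the most recent common
ancestor of species i and j and `V_λ` rescales the off-diagonal
(shared-history) entries of `V` by λ ∈ [0, 1]. For ultrametric trees
this equals the classical internal-branch rescaling; for non-ultrametric
input (accepted with a warning) the off-diagonal definition is used as
stated.

Estimation is maximum likelihood throughout, not REML. The paper-style
workflow compares models that differ in fixed effects by AIC, and REML
likelihoods are not comparable across fixed-effect structures; ML makes
every AIC comparison in the pipeline valid. Consequences: `σ²` is the
ML estimate (`r'V⁻¹r / n`), and standard errors carry an `n/(n−p)`
small-sample factor so that `V = I` reproduces classical OLS standard
errors exactly (a closed-form testing anchor).

### λ profile and optimisation

For fixed λ, β and σ² have closed forms, giving a one-dimensional
profile likelihood in λ. Writing `D = diag(V)` and
`W = D^{-1/2} V D^{-1/2}`, one symmetric eigendecomposition of `W`
reduces every profile evaluation to O(np²):
`V_λ = D^{1/2} Q (λw + (1−λ)) Q' D^{1/2}`. The optimum is located by an
11-point grid on [0, 1] followed by bounded Brent refinement around the
best grid point (profile likelihoods in λ can be flat or multimodal near
the boundaries; the grid prevents the one-dimensional optimiser from
committing to the wrong basin). The final estimate is the best of all
evaluated candidates, clipped to [0, 1]. A separate Cholesky-based GLS
route (`gls_solve`) exists for fixed covariances; tests require the two
routes and a dense matrix-inversion oracle to agree to 1e-8. If a
Cholesky factorisation fails, the covariance is jittered once by
`1e-10 · mean(diag)` and the event logged.

### Parameter counting

`PGLSFit.k` = design columns + 1 (σ²) + 1 (λ) when λ is estimated; the λ
term is omitted when λ is supplied fixed. In the drop-one comparison the
reduced model inherits the full model's λ, and by default that λ is
counted in the reduced model's k, so the AIC penalty difference equals
the number of columns dropped and a completely uninformative one-column
term has ΔAIC exactly −2. This choice makes the ΔAIC > 2 rule equivalent
to a likelihood-ratio threshold of `2ΔlogL > 2 + 2·(columns dropped)` —
for one column, a χ²₁ tail of ≈ 0.046 under the null, which the
acceptance suite verifies by simulation. `count_lambda_in_reduced=False`
shifts every ΔAIC down by 2 for users who prefer not to penalise the
held-fixed λ.

## Allometry and relative brain size

Brain volume and body mass are log₁₀-transformed. Three candidate forms
are fitted with ML λ — one global line; per-group intercepts; per-group
intercepts and slopes — and the lowest AIC wins (ties to the fewest
parameters). Taxonomic groups below 10 species are pooled into `"other"`
rather than dropped so every species keeps a residual. Relative brain
size is the raw residual `log₁₀(brain) − fitted`; residuals are
recomputed per posterior tree inside the ensemble rather than fixed once,
since the fitted allometry (and its λ) is tree-dependent. Clade-level
analyses instead refit a clade-specific global-form line with λ
re-optimised on the pruned tree, so a clade's residuals are not
contaminated by between-clade allometric shifts.

## Importance, signal, ensembling, clades

* Multi-level factors are dropped as whole blocks (one ΔAIC per term);
  interaction terms are out of scope by design.
* Partial R² is `1 − exp(−(2/n)·ΔlogL)`; it is strictly increasing in
  the log-likelihood gap and non-negative because the reduced model
  (at the full model's λ) is nested in the full one.
* Per-level Wald p-values are reported from both t (df = n − p, default)
  and z reference distributions; they are descriptive, not the decision
  rule.
* Ensembles over posterior trees average β, SE, ΔAIC, and partial R²
  arithmetically; significance is judged on the mean ΔAIC, with
  per-tree significance fractions emitted for diagnostics. Failing
  trees are skipped with a logged warning and counted.
* Phylogenetic signal is the ML λ of an intercept-only fit. CIs are
  percentile parametric bootstraps (default 100 draws) from the fitted
  (μ̂, σ̂², λ̂); boundary re-estimates are retained. Over tree samples, λ̂
  and CI endpoints are averaged per tree.
* Clades qualify with > 30 species and variation in every focal
  variable (≥ 2 observed levels; SD > 0 for continuous scores). Inside
  a clade, a term without variation is dropped with a warning instead of
  disqualifying the clade, and levels carried by fewer than 3 species
  are flagged `low_support`.

## Trait handling

Fine ecological classifications (10 diets, 9 foraging niches) collapse
to six broader categories each through a configurable `CategoryMap`;
the default assignments place aquatic plants under plants/seeds and
carrion under vertebrates, which is a judgement call users can override
via YAML. Reference levels for dummy coding: non-cooperative, solitary,
no territoriality, aquatic-animal diet, aerial-sallying foraging,
sedentary migration. Ordered categories (social bond, territoriality,
migration) are treated as unordered factors so per-level estimates are
reported against those references. The developmental-mode score enters
unstandardised (coefficients are per score unit). Rows with any missing
focal variable are dropped and counted; labels are matched to tree tips
as exact strings after trimming whitespace and replacing spaces with
underscores.

## Synthetic data: what it emulates, and what it does not

Trees are pure-birth (Yule) with depth normalised to 1, so rates are
comparable across tip counts. Log₁₀ body mass is Brownian (default rate
0.5 around a mean of 2.0, i.e. ≈ 100 g with ~0.7 SD in log units); the
developmental-mode score is Brownian with unit rate; categorical
predictors evolve under symmetric Mk processes (off-diagonal rate
`rate/k`, i.e. change events Poisson with rate `rate·(k−1)/k` along a
branch; default rate 0.5 for phylogenetically conserved categories).
Log₁₀ brain volume is assembled additively: group-specific intercepts
and slopes on log mass (defaults −0.6/−0.2 and 0.55/0.75 over two
150-species groups), additive per-level offsets, a dev-mode coefficient
of −0.02 per unit, and λ-structured residual noise (default λ = 0.8,
SD 0.1 in log₁₀ units). Groups are contiguous blocks of the tip
traversal order, approximating clades.

Power/calibration settings used by the test and acceptance runs are
fixed design choices: the two-group allometry benchmark uses λ = 0.9
with slopes 0.55/0.75; the effect-recovery benchmark uses one group of
300 species, λ = 0.5, residual SD 0.05, a single binary effect of 0.15
(3× the noise SD) with Mk rate 2.0 so both states are well represented,
and null terms alongside; the full-pipeline power run in the acceptance
script uses 500 species with a −0.02 dev-mode coefficient over residual
SD 0.02. Replicate counts are 100 for recovery/selection rates, 500 for
the null ΔAIC calibration, and 20 random instances for oracle
equivalence.

What passing these benchmarks does **not** show: real avian data involve
measurement error in endocast volumes and body masses, sex-specific
masses, taxonomic mismatches between trait and tree sources,
non-Mk-like correlated evolution of predictors, collinearity between
ecology and development, and far larger trees (≈ 1900 tips, 100
posterior samples). The generator makes none of those features; results
here validate the estimator and decision rules under their own
assumptions, not the biological conclusions one would draw from real
data.

## Numerical and degenerate-input policy

* Eigenvalues of the depth-normalised covariance are clipped at 0;
  λ = 1 with a singular covariance raises a singularity error rather
  than returning a spurious fit.
* MCC ties break to the lowest tree index; allometry AIC ties to the
  fewest parameters; λ optimiser candidates include all grid points, so
  the reported optimum never falls below the best grid evaluation.
* Pruning conserves root-to-tip depths and pairwise MRCA depths exactly,
  keeping any removed root-side path as a root edge length; degree-2
  nodes are suppressed with branch lengths summed.
* Zero-length terminal branches are allowed; constant traits, empty
  tables, unknown category levels, non-positive masses/volumes,
  duplicated terms, unobserved reference levels, and rank-deficient
  designs raise informative errors.

## Known limitations

Single error structure (Pagel's λ; no OU or measurement-error models);
no interaction terms; no multi-model averaging; the body-mass-covariate
sensitivity analysis reuses the same machinery via a flag but is not
separately benchmarked; bootstrap CIs for λ are percentile-based and
mildly undercover at moderate n (≈ 86–91% observed at a nominal 95% with
300 tips), which the test suite bounds rather than corrects.
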