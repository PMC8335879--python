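# Methods

This note documents the statistical procedures `survmice` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The modelling problem

The package targets a common situation in prognostic research: a survival
outcome (here overall survival in months, with a binary death/censoring
indicator), a handful of candidate prognostic factors of mixed type, and
substantial covariate missingness in the training cohort. Discarding
incomplete subjects wastes most of the data and can bias the model, so the
strategy is: impute multiply, fit a sparse Cox model in every completed
dataset under one shared penalty, and pool everything — coefficients,
discrimination, calibration, validation — with Rubin's rules.

## Data model and preprocessing

Variables are declared in a schema (continuous or ordinal, with role
predictor / auxiliary / outcome / treatment). Right-skewed positive
markers may carry a `log` or `log1p` transform chosen a priori; transforms
are applied before imputation and are bijective on observed values.

Ordinal predictors with k levels enter the analysis design matrix as k−1
**orthonormal polynomial contrasts** over equally spaced level scores
(linear, quadratic, …; columns zero-sum, mutually orthogonal, unit norm —
the convention of standard statistical software). Continuous predictors
are standardised **after imputation, within each completed dataset**,
using the mean and the *population* standard deviation (divisor n): this
puts them on a common scale so the L1 penalty treats them symmetrically.
Ordinal contrast columns are not standardised — their fixed scores already
live on a comparable scale, and standardising them would obscure the level
structure. Pairwise covariate plots (scatter / stacked bar / box) are
produced for human collinearity review only; no automated exclusion rule
is applied, because that judgement is substantive, not statistical.

## Chained-equations imputation

The number of imputations follows a pre-specified rule: m = 10 when no
variable exceeds 25% missingness, otherwise m = ⌈percent of incomplete
cases⌉; fully observed data passes through. Variables are visited from
least to most missing (schema order breaks ties), with missing cells
initialised from the observed marginals. Each conditional model regresses
its target on the remaining predictors, the auxiliary variables, the
survival time in months and the event indicator; randomised treatment is
excluded. Survival time itself (rather than a cumulative-hazard
transform) is the default outcome representation; the Nelson–Aalen
estimator is available behind a flag (`use_nelson_aalen`).

* **Continuous targets** — Bayesian linear regression with predictive mean
  matching: σ²\* is drawn from the scaled inverse-χ² posterior, β\* from
  N(β̂, σ²\*(XᵀX)⁻¹); each missing entry receives the observed value of a
  donor sampled from the k = 5 candidates whose predictions (under β̂) are
  nearest to the missing entry's prediction (under β\*). Imputed values
  therefore always lie in the observed support.
* **Ordinal targets** — a proportional-odds cumulative-logit model, fitted
  in-module by maximum likelihood with analytic gradients (thresholds kept
  ordered via a log-increment parameterisation; verified against
  statsmodels' `OrderedModel` to ~1e−5). Parameters are drawn from the
  large-sample normal posterior and the imputed level is *sampled* from
  the predicted category distribution, preserving variability.
* Inside the conditional models, ordinal *predictors* enter as numeric
  level codes — a deliberate simplification of the imputation model, not
  of the analysis model.

Defaults: 5 chained cycles, 5 PMM donors. Both are conventional values;
they are configurable and no claim is made that they match any particular
historical analysis. The Bayesian parameter draws are what make the
between-imputation variance in Rubin's rules honest; with them, pooled
Cox coefficients after MCAR masking achieve ~92% empirical coverage at
the nominal 95% level in the test suite's 200-replicate experiment.

## Penalised Cox modelling with one shared penalty

The multivariable model maximises the LASSO-penalised partial
log-likelihood, written on the glmnet scale `(1/n)ℓ(β) − λΣ|βᵢ|` so λ
values are comparable with that software family. Penalised fits use
scikit-survival's Coxnet coordinate-descent solver (Breslow ties);
unpenalised fits (λ = 0, used for univariate analyses, the D-statistic
regression and the coverage experiments) use lifelines' Newton–Raphson
solver (Efron ties). Continuous survival times make ties essentially
irrelevant here; the tie-handling asymmetry between the two solvers is
noted for transparency.

Selecting one λ\* shared across imputations stabilises variable selection.
The λ sequence (100 log-spaced values from λ_max down to 0.001·λ_max) is
generated **once, from the first imputed dataset**, and reused everywhere.
Cross-validation uses 10 event-stratified folds and the subtraction form
of the cross-validated partial-likelihood deviance,
−2·Σ_k [ℓ(β₍₋k₎; all) − ℓ(β₍₋k₎; without fold k)], minimised over the
sequence. One fold assignment is shared by all imputations (the subjects
are identical across them), which also makes the degenerate case of
identical imputed datasets yield exactly equal optima. λ\* is the
arithmetic mean of the m optima; its SD is reported as a diagnostic.

Model-based standard errors are not meaningful after L1 shrinkage, so each
imputation's coefficient SEs come from 100 bootstrap resamples refit at
the fixed λ\* (coefficients shrunk to zero enter the spread as exact
zeros). The baseline cumulative hazard is the Breslow estimator at the
fitted coefficients.

## Rubin pooling with the fixed-m denominator

Pooling is the textbook rule (θ̄, W, B, T = W + (1+1/m)B, normal-reference
95% CIs). The open question with LASSO-plus-imputation is what to do when
a variable is selected in only j of m fits: here the denominator stays m —
the unselected fits contribute coefficient 0 with bootstrap variance 0 —
so a coefficient of 5 selected once in ten pools to 0.5. Variables
selected in *no* imputation are dropped from the reported model. The
subject-level combined prognostic index is the mean over imputations of
each fit applied to its own completed dataset.

## Assessment

**Discrimination — D-statistic.** Subjects are ranked by prognostic index
and assigned scaled rankits by Bloom's approximation,
z_i = (8/π)^(−1/2)·Φ⁻¹((i−3/8)/(n+1/4)); a Cox regression of survival on z
gives D as its slope. D is interpretable as the log hazard ratio between
the prognostically better and worse halves of a cohort, and — the reason
it is used here — it pools across imputations by plain Rubin's rules.
Ties in the index get the Bloom formula at their average rank
(deterministic and permutation-invariant). The scalar slope is polished
with Newton steps on the partial likelihood after the general solver
finishes, so independent reimplementations agree to ~1e−8. Under a normal
index, D ≈ √(8/π)·SD(PI), which anchors the simulation tests.

**Calibration.** Per imputation and horizon (60 days ≈ 1.97 months and 12
months by default), subjects are split at the deciles of their predicted
S(t) (linear-interpolation quantiles; boundary subjects to the lower
group); the group's predicted value is the median prediction and its
observed value the Kaplan–Meier estimate at t with a Greenwood 95% CI.
The calibration slope regresses predicted on observed over the ~10 group
points by unweighted OLS and pools the m slopes by their mean; no CI is
reported for it, as ten points per regression cannot support one.

**Proportional hazards.** Default check: per covariate, OLS of the
*unscaled* Schoenfeld residuals on event time, flagging a covariate when
the time coefficient is significant at 5% in any imputation. This form
never inverts a (possibly singular, e.g. bootstrap) covariance matrix, but
its OLS p-values are **conservative** — the residuals' true sampling
variance shrinks with the risk set, which plain OLS ignores; under exact
proportional hazards it rejects far below 5%. A size-calibrated
alternative is provided (`scaled=True`): the score test with
information-weighted time centering, Σ(g_k−ḡ)r_k squared over
Σ(g_k−ḡ)²V_k with V_k the risk-set covariate variance. It reproduces R's
`survival::cox.zph(transform="identity")` p-values to ~1e−8 and holds its
nominal size in simulation.

**Uno's C** (inverse-probability-of-censoring-weighted concordance at a
fixed horizon) is computed through scikit-survival and reported as the
median (IQR) across imputations, since its Rubin-pooling behaviour is less
well behaved than D's.

## Internal validation (bootstrap first, impute second)

For each of B replicates: resample n subjects with replacement from the
**incomplete** training data; rerun the entire model-building recipe on
the resample (imputation, λ\* selection, penalised fits, pooling) to get a
*sample* model and its apparent performance; apply the sample model's
pooled coefficients to the **original** imputed datasets, as standardised
in the original run (the sample model travels with its coefficients and
pooled baseline only); Rubin-combine those to the *internal-validation*
performance. Optimism is their difference, and
`corrected = apparent − mean optimism` — an identity asserted in the
report object. The D-statistic needs only the prognostic index in step
two; the calibration slope additionally uses the sample model's pooled
baseline hazard. Replicates with no events or degenerate nested fits are
redrawn up to five times, then counted and reported as skipped. B = 100
by default; the test suite and the acceptance script run B = 10–20 so the
nested re-imputation loop stays within desk-scale runtimes — the problem
sizes used are stated with each result.

## External validation and risk groups

Complete-case external validation keeps only test subjects with every
*retained* model variable observed, applies the training transforms,
standardises with the Rubin-pooled training constants, scores with the
pooled coefficients, and reports D, Uno's C and calibration at both
horizons. A sensitivity variant imputes the test data instead (same
imputation specification, m = 10), applies the single pooled model inside
every completed copy and Rubin-combines.

Risk groups are the tertiles of the training combined prognostic index
(type-7 linear-interpolation quantiles; boundary subjects to the lower
group), reused unchanged on the test index; published cutpoints can be
supplied directly by flag since a historical tertile convention is
generally unrecoverable from group counts alone. Kaplan–Meier curves with
Greenwood CIs are produced per group.

## The synthetic generator

`synthetic_data.generate` draws a myeloma-like cohort: age ~ truncated
normal(73.5, 6.5²); WHO performance status categorical on 0–4; LDH
log-normal; CRP a shifted log-normal with a point mass at zero (so the
log1p transform is the natural one); lymphocyte:white-cell ratio ~
Beta(3.2, 9.8); ISS categorical on three stages; Bernoulli sex and
treatment arm. Survival is exponential (Weibull available) with hazard
h₀·exp(PI) where PI uses fixed true coefficients on the transformed,
standardised design scale — sized so that the true D ≈ 0.84 via
D = √(8/π)·SD(PI), with LDH deliberately carrying no effect so the LASSO
has something to discard. Censoring combines staggered-accrual
administrative cutoff with a small exponential drop-out; the training
default yields ~38% deaths, the external-test default (older cohort,
longer follow-up) ~77%.

Missingness is missing-at-random: each incomplete variable's logit
combines always-observed quantities (standardised age, sex, log survival
time, event indicator) with a subject-level latent "work-up completeness"
factor that is independent of everything else; the shared latent makes the
laboratory variables co-missing, producing realistic multi-variable
patterns (training default: LDH ~22.5%, CRP ~14%, complete cases ~66–68%;
test default: LDH ~44%, complete cases ~43–46%). Because the latent is
outcome- and data-independent, the mechanism remains MAR and imputation is
valid.

What the generator does **not** emulate: covariate correlations beyond
what the shared survival model induces (marginals are independent),
treatment effects, measurement error, or any real trial's joint covariate
distribution. Passing tests therefore demonstrate that the *machinery* is
correct and well calibrated under a known MAR proportional-hazards truth —
not that any particular clinical model is transportable.

## Numerical choices and degenerate inputs

* Percentages in missingness tables round half-up to 2 decimals.
* Coordinate-descent convergence 1e−9; λ=0 Newton precision 1e−10 with a
  scalar Newton polish for the D regression.
* Constant columns fail standardisation loudly; an all-tied prognostic
  index makes D undefined and raises; equal tertile cutpoints raise.
* Bootstrap resamples without events are redrawn (5 attempts) then
  reported; CV folds are re-randomised on the same condition.
* All randomness descends from one root seed through named
  `SeedSequence.spawn` streams (generation, imputation, CV folds,
  bootstrap, validation), so identical seed + configuration reproduces
  every artifact bit-for-bit.

## Known limitations

* The unscaled-residual PH check is conservative by construction; use the
  scaled score test when size matters.
* The calibration slope inherits the instability of a 10-point regression;
  it is reported without precision estimates and should be read together
  with the calibration plots.
* Rubin CIs after LASSO shrinkage are approximate: shrunk estimates are
  biased toward zero, so coverage statements in the test suite use
  unpenalised fits.
* The imputation conditional models are linear/proportional-odds in the
  numeric level codes; strongly non-linear conditional structure would
  need richer imputation models than this package provides.
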