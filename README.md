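# survmice

Developing and validating a prognostic model for overall survival when the
**training data has missing covariates**. `survmice` implements the full
strategy as a reusable Python library plus a thin command-line interface:

1. **Multiple imputation by chained equations (MICE)** — predictive mean
   matching for continuous covariates, proportional-odds regression for
   ordinal ones, with the survival time and event indicator in every
   imputation model.
2. **Penalised Cox modelling with a shared penalty** — within each of the
   m completed datasets a LASSO Cox model maximises
   `ℓ(β) − λ Σᵢ|βᵢ|`; the penalty λ\* is the mean of the m cross-validated
   optima, computed on one λ sequence taken from the first imputation.
3. **Rubin's-rules pooling** — pooled coefficient θ̄ = mean of the m
   estimates, total variance `T = W + (1 + 1/m)·B`. Variables the LASSO
   drops in a subset of imputations contribute exact zeros and the
   denominator stays m.
4. **Assessment** — the prognostic-separation **D-statistic** (Cox slope on
   Bloom scaled rankits `zᵢ = (8/π)^{-1/2} Φ⁻¹((i−3/8)/(n+1/4))`, pooled
   across imputations), decile **calibration** plots/slopes at 60 days and
   1 year, a weighted-Schoenfeld-residual **proportional-hazards check**,
   and **Uno's C**.
5. **Optimism-corrected internal validation** — bootstrap *first*, impute
   *second*: every replicate resamples the incomplete data and reruns the
   entire recipe; `corrected = apparent − mean optimism`.
6. **External validation** — complete-case scoring of an independent
   cohort with the training transforms and pooled standardisation
   constants, plus a sensitivity analysis that imputes the test data.
7. **Risk groups** — tertiles of the combined (imputation-averaged)
   prognostic index, with Kaplan-Meier curves per group.

A seeded synthetic-data generator emulates a transplant-ineligible newly
diagnosed multiple myeloma trial cohort (age, WHO performance status,
LDH, CRP, lymphocyte:white-cell ratio, ISS stage; proportional-hazards
survival; missing-at-random covariate patterns), so the whole pipeline can
be exercised, tested and demonstrated with known ground truth.

## Worked example

```python
import numpy as np
from survmice.synthetic_data import default_training_config, generate
from survmice.pipeline import PipelineConfig, build_model
from survmice.validation import internal_validate
from survmice.risk_groups import derive_groups

data, truth = generate(default_training_config(), seed=1)   # n = 1852
result = build_model(data, PipelineConfig(B_se=100), seed=11)

print("m =", result.stack.m)
print("lambda* =", round(result.lam.mean, 4))
print("combined D =", round(result.d_result.combined, 3),
      "CI", tuple(round(x, 3) for x in result.d_result.ci))

reports = internal_validate(data, result.config, B=10, seed=12,
                            apparent=result)
print("corrected D =", round(reports["d"].corrected, 3))

groups = derive_groups(result.combined_pi)
print("tertile cutpoints =", tuple(round(c, 3) for c in groups.cutpoints))
```

Output of this exact snippet:

```
m = 10
lambda* = 0.0044
combined D = 0.877 CI (0.745, 1.009)
corrected D = 0.861
tertile cutpoints = (-0.331, 0.119)
```

The generator's complete-case fraction (~68%), death fraction (~38%) and
true prognostic separation (D ≈ 0.84, via the normal-approximation
identity D = √(8/π)·SD(PI)) are part of its frozen default configuration,
so the fitted combined D landing near 0.84 indicates the imputation,
penalisation and pooling steps are recovering the generating model; the
corrected D sits slightly below the apparent one, the usual sign of mild
overfitting picked up by the bootstrap.

The same pipeline is available from a shell:

```bash
survmice simulate --workdir run --n 1852 --seed 1
survmice all --workdir run --seed 11       # impute → fit → assess → validate
```

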