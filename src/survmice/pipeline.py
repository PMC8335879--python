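"""End-to-end model-building orchestration.

``build_model`` runs the full training recipe on a raw (incomplete)
dataset: transform, summarise missingness, choose m, impute, standardise
within each completed dataset, select one shared LASSO penalty by
cross-validation, fit the penalised Cox model in every imputation,
bootstrap the coefficient standard errors, pool everything by Rubin's
rules, and assess the pooled model (combined D-statistic, decile
calibration with slopes, proportional-hazards check, Uno's C).

The same routine is re-entered, imputation and all, inside every
bootstrap replicate of the internal validation, so it stays configurable
down to the cheap settings used there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assessment import (
    CalibrationResult,
    DStatResult,
    PHCheckResult,
    HORIZON_1Y,
    HORIZON_60D,
    calibration,
    calibration_slope,
    combined_d,
    ph_check,
    uno_c,
)
from .core_data import MissingPatternSummary, Schema, TrialDataset, summarize_missingness
from .mice_engine import ImputationSpec, ImputedStack, choose_m, impute
from .pooling import PooledModel, pool, pool_model, pool_prognostic_index
from .preprocess import (
    StandardizationParams,
    apply_transforms,
    build_design,
    compute_standardization,
    pool_standardization,
)
from .survival_models import LambdaStar, fit_cox, bootstrap_se, lambda_star

__all__ = ["PipelineConfig", "ModelBuildResult", "build_model", "variable_column_groups", "univariate_table"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable settings of the model-building recipe."""

    m: int | None = None  # None: decided by the missingness rule
    missing_threshold: float = 25.0
    cycles: int = 5
    donors: int = 5
    folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.001
    B_se: int = 100  # 0 skips bootstrap SEs (variances enter pooling as 0)
    horizons: tuple = (HORIZON_60D, HORIZON_1Y)
    n_calibration_groups: int = 10
    run_ph_check: bool = True
    run_uno: bool = True
    run_univariate: bool = False


def variable_column_groups(schema: Schema) -> "dict[str, list[str]]":
    """Map each predictor to its design-matrix column(s)."""
    from .preprocess import _contrast_names

    out = {}
    for spec in schema.predictors:
        if spec.kind == "continuous":
            out[spec.name] = [spec.name]
        else:
            out[spec.name] = _contrast_names(spec.name, spec.n_levels)
    return out


def variable_of_column(column: str, schema: Schema) -> str:
    for var, cols in variable_column_groups(schema).items():
        if column in cols:
            return var
    raise KeyError(f"design column {column!r} matches no predictor")


@dataclass
class ModelBuildResult:
    """Everything the downstream assessment/validation steps need."""

    config: PipelineConfig
    data: TrialDataset  # transformed, still incomplete
    summary: MissingPatternSummary
    stack: ImputedStack
    std_params: "list[StandardizationParams]"
    pooled_std: StandardizationParams
    designs: "list[pd.DataFrame]"
    lam: LambdaStar
    pooled: PooledModel
    boot_ses: "list[pd.Series]"
    combined_pi: np.ndarray
    d_result: DStatResult
    calibrations: "dict[float, CalibrationResult]"
    slopes: "dict[float, tuple[float, list[float]]]"
    ph: PHCheckResult | None
    uno: "dict[float, list[float]]"
    univariate: pd.DataFrame | None = None

    @property
    def time(self) -> np.ndarray:
        return self.data.time

    @property
    def event(self) -> np.ndarray:
        return self.data.event

    def imputation_pis(self) -> "list[np.ndarray]":
        return [f.prognostic_index(X) for f, X in zip(self.pooled.fits, self.designs)]


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def univariate_table(
    designs: Sequence[pd.DataFrame],
    schema: Schema,
    time: np.ndarray,
    event: np.ndarray,
) -> pd.DataFrame:
    """Unpenalised one-variable-at-a-time Cox fits, Rubin-pooled, with
    Wald 95% CIs — the informal companion to the multivariable model."""
    groups = variable_column_groups(schema)
    rows = []
    for var, cols in groups.items():
        for col in cols:
            ests, variances = [], []
            for X in designs:
                fit = fit_cox(X[cols], time, event, lam=0.0)
                ests.append(float(fit.coef[col]))
                variances.append(float(fit.cov.loc[col, col]))
            pe = pool(ests, variances)
            lo, hi = pe.ci
            rows.append({"variable": var, "column": col, "coef": pe.estimate,
                         "se": pe.se, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def build_model(
    raw: TrialDataset,
    config: PipelineConfig = PipelineConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> ModelBuildResult:
    """Run the full model-building recipe on an incomplete training dataset."""
    ss = _as_seedseq(seed)
    s_impute, s_cv, s_boot = ss.spawn(3)

    data = apply_transforms(raw)
    summary = summarize_missingness(data)
    m = config.m if config.m is not None else choose_m(summary, config.missing_threshold)
    m = max(m, 2)  # Rubin pooling needs m >= 2; identical copies are a no-op
    spec = ImputationSpec(m=m, cycles=config.cycles, donors=config.donors)
    stack = impute(data, spec, seed=s_impute)

    time, event = data.time, data.event
    std_params = [compute_standardization(ds) for ds in stack]
    designs = [build_design(ds, p) for ds, p in zip(stack, std_params)]
    pooled_std = pool_standardization(std_params)

    lam = lambda_star(
        [(X, time, event) for X in designs],
        folds=config.folds,
        rng=np.random.default_rng(s_cv),
        n_lambdas=config.n_lambdas,
        min_ratio=config.lambda_min_ratio,
    )
    fits = [fit_cox(X, time, event, lam=lam.mean) for X in designs]

    if config.B_se >= 2:
        boot_rngs = [np.random.default_rng(c) for c in s_boot.spawn(m)]
        boot_ses = [
            bootstrap_se(X, time, event, lam.mean, B=config.B_se, rng=r)[0]
            for X, r in zip(designs, boot_rngs)
        ]
    else:
        boot_ses = [pd.Series(0.0, index=f.coef.index) for f in fits]

    pooled = pool_model(fits, boot_ses)
    combined_pi = pool_prognostic_index(designs, fits)

    pis = [f.prognostic_index(X) for f, X in zip(fits, designs)]
    d_result = combined_d(pis, time, event)

    calibrations, slopes = {}, {}
    for horizon in config.horizons:
        cal = calibration(fits, designs, time, event, horizon,
                          n_groups=config.n_calibration_groups)
        calibrations[horizon] = cal
        slopes[horizon] = calibration_slope(cal)

    ph = None
    if config.run_ph_check and any(len(f.selected) for f in fits):
        usable = [(f, X) for f, X in zip(fits, designs) if len(f.selected)]
        ph = ph_check([f for f, _ in usable], [X for _, X in usable], time, event)

    uno = {}
    if config.run_uno:
        for horizon in config.horizons:
            uno[horizon] = [uno_c(pi, time, event, horizon) for pi in pis]

    univariate = None
    if config.run_univariate:
        univariate = univariate_table(designs, data.schema, time, event)

    return ModelBuildResult(
        config=config, data=data, summary=summary, stack=stack,
        std_params=std_params, pooled_std=pooled_std, designs=designs,
        lam=lam, pooled=pooled, boot_ses=boot_ses, combined_pi=combined_pi,
        d_result=d_result, calibrations=calibrations, slopes=slopes,
        ph=ph, uno=uno, univariate=univariate,
    )
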