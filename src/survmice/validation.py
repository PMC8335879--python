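"""Optimism-corrected internal validation and external validation.

Internal validation is bootstrap-first, impute-second: every replicate
resamples the *incomplete* training data with replacement and repeats the
entire model-building recipe — imputation, shared-penalty selection,
penalised fits, pooling — before measuring performance.  For each
replicate

    optimism_b = (sample-model performance in the bootstrap world)
               - (sample-model performance on the original imputed data)

and the corrected measure is the apparent measure minus the mean optimism
over the B replicates.  Both the D-statistic and the calibration slopes at
the two horizons are carried through the same loop.

External validation applies the pooled training model to a test cohort
restricted to subjects with complete data on the model's variables, using
the training transforms and the Rubin-pooled training standardisation
constants; a sensitivity variant imputes the test data instead and pools
the per-imputation measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .assessment import (
    CalibrationResult,
    DStatResult,
    calibration,
    calibration_slope,
    combined_d,
    d_statistic,
    uno_c,
)
from .core_data import TrialDataset
from .mice_engine import ImputationError, ImputationSpec, impute
from .pipeline import ModelBuildResult, PipelineConfig, build_model, variable_of_column
from .preprocess import apply_transforms, expand_ordinal, standardize
from .survival_models import FitError

__all__ = [
    "ValidationReport",
    "ExternalValidationResult",
    "internal_validate",
    "external_validate",
    "external_validate_imputed",
]


@dataclass
class ValidationReport:
    """Apparent / bootstrap / optimism bookkeeping for one measure."""

    measure: str
    apparent: float
    sample_values: "list[float]"
    internal_values: "list[float]"
    B_requested: int
    n_skipped: int = 0

    @property
    def optimisms(self) -> np.ndarray:
        return np.asarray(self.sample_values) - np.asarray(self.internal_values)

    @property
    def B(self) -> int:
        return len(self.sample_values)

    @property
    def mean_optimism(self) -> float:
        return float(self.optimisms.mean()) if self.B else 0.0

    @property
    def sd_optimism(self) -> float:
        return float(self.optimisms.std(ddof=1)) if self.B > 1 else 0.0

    @property
    def corrected(self) -> float:
        return self.apparent - self.mean_optimism

    def to_text(self) -> str:
        return (
            f"measure\t{self.measure}\n"
            f"apparent\t{self.apparent:.6g}\n"
            f"B\t{self.B} (requested {self.B_requested}, skipped {self.n_skipped})\n"
            f"mean_optimism\t{self.mean_optimism:.6g}\n"
            f"sd_optimism\t{self.sd_optimism:.6g}\n"
            f"corrected\t{self.corrected:.6g}\n"
        )


def _bootstrap_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, n, n)


def _slope_against_original(
    sample_fit, designs: Sequence[pd.DataFrame], time, event, horizon, n_groups
) -> float:
    cal = calibration([sample_fit] * len(designs), designs, time, event,
                      horizon, n_groups=n_groups)
    pooled_slope, _ = calibration_slope(cal)
    return pooled_slope


def internal_validate(
    raw_training: TrialDataset,
    config: PipelineConfig,
    B: int = 100,
    seed: int | np.random.SeedSequence = 0,
    apparent: ModelBuildResult | None = None,
    resampler: Callable[[np.random.Generator, int], np.ndarray] = _bootstrap_indices,
    max_redraws: int = 5,
) -> "dict[str, ValidationReport]":
    """Bootstrap-then-impute optimism correction for D and calibration slopes.

    Returns one :class:`ValidationReport` per measure, keyed ``"d"`` and
    ``"slope@<horizon>"``.  Replicates whose resample has no events or whose
    nested model build degenerates are redrawn up to ``max_redraws`` times,
    then counted as skipped.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    s_apparent, s_boot = ss.spawn(2)
    if apparent is None:
        apparent = build_model(raw_training, config, seed=s_apparent)
    inner_config = replace(config, m=apparent.stack.m, B_se=0,
                           run_ph_check=False, run_uno=False, run_univariate=False)

    time, event = apparent.time, apparent.event
    n = raw_training.n
    measures = {"d": apparent.d_result.combined}
    for h in config.horizons:
        measures[f"slope@{h:g}"] = apparent.slopes[h][0]
    samples: dict[str, list[float]] = {k: [] for k in measures}
    internals: dict[str, list[float]] = {k: [] for k in measures}

    n_skipped = 0
    rep_seeds = s_boot.spawn(B)
    for b in range(B):
        rng = np.random.default_rng(rep_seeds[b])
        ok = False
        for attempt in range(max_redraws):
            idx = resampler(rng, n)
            boot_df = raw_training.df.iloc[idx].reset_index(drop=True)
            boot = TrialDataset(raw_training.schema, boot_df)
            if boot.event.sum() < 1:
                continue
            try:
                sample = build_model(boot, inner_config,
                                     seed=np.random.SeedSequence(int(rng.integers(2**31))))
                sample_fit = sample.pooled.as_fit()
                # performance of the sample model in its own bootstrap world
                rep_samples = {"d": sample.d_result.combined}
                for h in config.horizons:
                    rep_samples[f"slope@{h:g}"] = sample.slopes[h][0]
                # performance of the sample model on the original imputed data
                rep_internals = {}
                pis = [sample_fit.prognostic_index(X) for X in apparent.designs]
                rep_internals["d"] = combined_d(pis, time, event).combined
                for h in config.horizons:
                    rep_internals[f"slope@{h:g}"] = _slope_against_original(
                        sample_fit, apparent.designs, time, event, h,
                        config.n_calibration_groups)
            except (ImputationError, FitError, ValueError, np.linalg.LinAlgError):
                continue
            ok = True
            break
        if not ok:
            n_skipped += 1
            continue
        for k in measures:
            samples[k].append(rep_samples[k])
            internals[k].append(rep_internals[k])

    return {
        k: ValidationReport(
            measure=k, apparent=measures[k], sample_values=samples[k],
            internal_values=internals[k], B_requested=B, n_skipped=n_skipped,
        )
        for k in measures
    }


# ---------------------------------------------------------------------------
# External validation


@dataclass
class ExternalValidationResult:
    """Pooled-model performance in an independent test cohort."""

    n_eligible: int
    pi: np.ndarray = field(repr=False)
    d: float
    d_variance: float
    d_ci: tuple[float, float]
    uno: "dict[float, float]"
    calibrations: "dict[float, CalibrationResult]"
    slopes: "dict[float, float]"
    d_result: DStatResult | None = None  # populated by the imputed variant


def _d_ci(d: float, var: float) -> tuple[float, float]:
    from scipy.stats import norm

    z = norm.ppf(0.975)
    half = z * float(np.sqrt(var))
    return (d - half, d + half)


def external_validate(
    model: ModelBuildResult,
    test: TrialDataset,
    horizons: Sequence[float] | None = None,
) -> ExternalValidationResult:
    """Complete-case external validation of the pooled model.

    Subjects qualify when every variable retained in the pooled model is
    observed; training transforms and Rubin-pooled training
    standardisation constants are applied before scoring.
    """
    horizons = tuple(horizons) if horizons is not None else model.config.horizons
    schema = test.schema
    model_vars = sorted({variable_of_column(c, schema) for c in model.pooled.included})
    if not model_vars:
        raise ValueError("pooled model retains no variables")
    eligible_mask = ~test.df[model_vars].isna().any(axis=1)
    n_eligible = int(eligible_mask.sum())
    if n_eligible == 0:
        raise ValueError("no complete-case subjects for the model variables")
    sub = TrialDataset(schema, test.df[eligible_mask].reset_index(drop=True))
    sub = apply_transforms(sub)
    # standardise with the pooled training constants; expand only the model's
    # ordinal variables (other columns may legitimately be missing here)
    frame = standardize(sub, model.pooled_std).df
    design_cols = {}
    from .preprocess import orthonormal_poly_contrasts, _contrast_names

    for var in model_vars:
        spec = schema[var]
        x = frame[var].to_numpy(float)
        if spec.kind == "continuous":
            design_cols[var] = x
        else:
            basis = orthonormal_poly_contrasts(spec.n_levels)
            codes = x.astype(int)
            for j, cname in enumerate(_contrast_names(var, spec.n_levels)):
                design_cols[cname] = basis[codes, j]
    design = pd.DataFrame(design_cols, index=frame.index)

    fit = model.pooled.as_fit()
    pi = fit.prognostic_index(design)
    time, event = sub.time, sub.event
    d, var = d_statistic(pi, time, event)
    uno = {h: uno_c(pi, time, event, h) for h in horizons}
    calibrations, slopes = {}, {}
    for h in horizons:
        cal = calibration([fit], [design], time, event, h,
                          n_groups=model.config.n_calibration_groups)
        calibrations[h] = cal
        slopes[h] = calibration_slope(cal)[0]
    return ExternalValidationResult(
        n_eligible=n_eligible, pi=pi, d=d, d_variance=var, d_ci=_d_ci(d, var),
        uno=uno, calibrations=calibrations, slopes=slopes,
    )


def external_validate_imputed(
    model: ModelBuildResult,
    test: TrialDataset,
    spec: ImputationSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    horizons: Sequence[float] | None = None,
) -> ExternalValidationResult:
    """Sensitivity analysis: impute the test data with the training
    imputation models' specification, score every completed copy with the
    single pooled model, and Rubin-combine the per-imputation measures."""
    horizons = tuple(horizons) if horizons is not None else model.config.horizons
    if spec is None:
        spec = ImputationSpec(m=model.stack.m, cycles=model.config.cycles,
                              donors=model.config.donors)
    data = apply_transforms(test)
    stack = impute(data, spec, seed=seed)
    fit = model.pooled.as_fit()
    time, event = data.time, data.event
    schema = test.schema
    model_vars = sorted({variable_of_column(c, schema) for c in model.pooled.included})

    designs, pis = [], []
    for ds in stack:
        frame = standardize(ds, model.pooled_std)
        design = expand_ordinal(frame)
        designs.append(design)
        pis.append(fit.prognostic_index(design))

    if stack.m >= 2:
        d_result = combined_d(pis, time, event)
        d, var_d = d_result.combined, d_result.pooled.total
        ci = d_result.ci
    else:
        d_result = None
        d, var_d = d_statistic(pis[0], time, event)
        ci = _d_ci(d, var_d)
    pi_mean = np.mean(np.vstack(pis), axis=0)
    uno = {h: float(np.median([uno_c(pi, time, event, h) for pi in pis])) for h in horizons}
    calibrations, slopes = {}, {}
    for h in horizons:
        cal = calibration([fit] * stack.m, designs, time, event, h,
                          n_groups=model.config.n_calibration_groups)
        calibrations[h] = cal
        slopes[h] = calibration_slope(cal)[0]
    return ExternalValidationResult(
        n_eligible=test.n, pi=pi_mean, d=d, d_variance=var_d, d_ci=ci,
        uno=uno, calibrations=calibrations, slopes=slopes, d_result=d_result,
    )
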