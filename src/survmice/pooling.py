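"""Rubin's-rules combination of estimates across imputed datasets.

For m estimates theta_1..theta_m with variances v_1..v_m:

    pooled point  theta_bar = mean(theta_i)
    within        W = mean(v_i)
    between       B = sample variance of theta_i (divisor m - 1)
    total         T = W + (1 + 1/m) B
    95% CI        theta_bar +/- 1.96 sqrt(T)

When the LASSO drops a variable from some imputations' models, the
convention here keeps the denominator at m: the absent fits contribute a
coefficient of exactly 0 with bootstrap variance 0, reflecting that
penalisation to zero happened in those imputations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .survival_models import PenalizedCoxFit

__all__ = ["PooledEstimate", "PooledModel", "pool", "pool_model", "pool_prognostic_index"]


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-pooled point estimate with its variance decomposition."""

    estimate: float
    within: float
    between: float
    m: int
    conf_level: float = 0.95

    @property
    def total(self) -> float:
        return self.within + (1.0 + 1.0 / self.m) * self.between

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))

    @property
    def ci(self) -> tuple[float, float]:
        z = norm.ppf(0.5 + self.conf_level / 2.0)
        return (float(self.estimate - z * self.se), float(self.estimate + z * self.se))


def pool(estimates: Sequence[float], variances: Sequence[float]) -> PooledEstimate:
    """Combine m >= 2 estimates and their variances by Rubin's rules."""
    est = np.asarray(list(estimates), float)
    var = np.asarray(list(variances), float)
    m = len(est)
    if m < 2:
        raise ValueError("Rubin's rules need m >= 2 estimates")
    if len(var) != m:
        raise ValueError("estimates and variances must have equal length")
    if (var < 0).any():
        raise ValueError("variances must be non-negative")
    return PooledEstimate(
        estimate=float(est.mean()),
        within=float(var.mean()),
        between=float(est.var(ddof=1)),
        m=m,
    )


@dataclass
class PooledModel:
    """Per-imputation penalised fits plus the Rubin-pooled prognostic model."""

    fits: "list[PenalizedCoxFit]"
    estimates: "dict[str, PooledEstimate]"
    inclusion_counts: "dict[str, int]"

    @property
    def m(self) -> int:
        return len(self.fits)

    @property
    def coef(self) -> pd.Series:
        """Pooled coefficients over all design columns (including zeros)."""
        return pd.Series({k: v.estimate for k, v in self.estimates.items()})

    @property
    def included(self) -> list[str]:
        """Columns with a nonzero pooled coefficient (the reported model)."""
        return [k for k, v in self.estimates.items() if v.estimate != 0.0]

    def prognostic_index(self, X: pd.DataFrame) -> np.ndarray:
        """Pooled-coefficient linear predictor (nonzero columns only, so
        columns the model dropped may be missing or absent in ``X``)."""
        cols = self.included
        coef = self.coef[cols]
        return X[cols].to_numpy(float) @ coef.to_numpy()

    def as_fit(self) -> PenalizedCoxFit:
        """The pooled model as a scoring object: pooled coefficients over
        the included columns plus the imputation-averaged Breslow baseline."""
        grid, vals = self.pooled_baseline()
        return PenalizedCoxFit(
            lam=self.fits[0].lam,
            coef=self.coef[self.included],
            baseline_times=grid,
            baseline_cumhaz=vals,
            max_followup=float(max(f.max_followup for f in self.fits)),
        )

    def pooled_baseline(self) -> tuple[np.ndarray, np.ndarray]:
        """Baseline cumulative hazard averaged across imputations on the
        union grid of event times (step functions averaged pointwise)."""
        grid = np.unique(np.concatenate([f.baseline_times for f in self.fits]))
        vals = np.zeros_like(grid)
        for f in self.fits:
            pos = np.searchsorted(f.baseline_times, grid, side="right")
            step = np.concatenate([[0.0], f.baseline_cumhaz])
            vals += step[pos]
        return grid, vals / self.m

    def to_table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            if est.estimate == 0.0 and self.inclusion_counts[name] == 0:
                continue  # never selected: omitted from the reported model
            lo, hi = est.ci
            rows.append({
                "variable": name,
                "included_in": self.inclusion_counts[name],
                "coef": est.estimate,
                "se": est.se,
                "ci_low": lo,
                "ci_high": hi,
            })
        return pd.DataFrame(rows)


def pool_model(
    fits: Sequence[PenalizedCoxFit],
    bootstrap_ses: Sequence[pd.Series],
) -> PooledModel:
    """Pool m penalised fits, keeping the denominator at m for columns the
    LASSO dropped in a subset of imputations (0 estimate, 0 variance)."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to pool")
    cols = list(fits[0].coef.index)
    for f in fits[1:]:
        if list(f.coef.index) != cols:
            raise ValueError("mismatched design columns across fits")
    lams = {f.lam for f in fits}
    if len(lams) > 1:
        raise ValueError("fits must share the same penalty")
    estimates, counts = {}, {}
    for name in cols:
        vals, variances = [], []
        for f, se in zip(fits, bootstrap_ses):
            c = float(f.coef[name])
            vals.append(c)
            variances.append(float(se[name]) ** 2 if c != 0.0 else 0.0)
        estimates[name] = pool(vals, variances)
        counts[name] = int(sum(float(f.coef[name]) != 0.0 for f in fits))
    return PooledModel(fits=fits, estimates=estimates, inclusion_counts=counts)


def pool_prognostic_index(
    designs: Sequence[pd.DataFrame],
    fits: Sequence[PenalizedCoxFit],
) -> np.ndarray:
    """Combined prognostic index: subject-level mean of the per-imputation
    linear predictors (each fit applied to its own completed dataset)."""
    if len(designs) != len(fits):
        raise ValueError("need one design per fit")
    n = len(designs[0])
    pis = np.zeros((len(fits), n))
    for i, (X, f) in enumerate(zip(designs, fits)):
        if len(X) != n:
            raise ValueError("subject mismatch across imputations")
        pis[i] = f.prognostic_index(X)
    return pis.mean(axis=0)
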