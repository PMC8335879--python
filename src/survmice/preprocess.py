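"""Covariate transformation, ordinal contrasts and standardisation.

Continuous covariates may be log- or log1p-transformed (chosen a priori by
inspecting their distributions) and are standardised *after* imputation
within each completed dataset using the mean and the population standard
deviation (divisor ``n``), so that the penalty in the downstream LASSO Cox
model treats them on a common scale.  Ordinal covariates are expanded into
orthonormal polynomial contrast columns (linear, quadratic, ...) and are
deliberately not standardised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import Schema, TrialDataset, DataValidationError

__all__ = [
    "StandardizationParams",
    "ContrastBasis",
    "apply_transforms",
    "compute_standardization",
    "standardize",
    "pool_standardization",
    "orthonormal_poly_contrasts",
    "contrast_basis",
    "expand_ordinal",
    "build_design",
    "design_column_names",
    "pairwise_plots",
]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-variable mean and population SD, with their provenance."""

    means: "dict[str, float]"
    sds: "dict[str, float]"
    provenance: str = "single_dataset"  # or "pooled_across_imputations"

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise DataValidationError(f"constant column: {name!r} has zero population SD")

    @property
    def names(self) -> list[str]:
        return list(self.means)


def _standardized_vars(schema: Schema) -> list:
    return [v for v in schema.predictors if v.kind == "continuous" and v.standardize]


def apply_transforms(data: TrialDataset) -> TrialDataset:
    """Apply each variable's declared ``log``/``log1p`` transform in place.

    Missing cells stay missing.  ``log`` requires strictly positive observed
    values; ``log1p`` requires values > -1.
    """
    df = data.df.copy()
    for spec in data.schema:
        if spec.transform == "none":
            continue
        col = df[spec.name].to_numpy(float)
        obs = ~np.isnan(col)
        if spec.transform == "log":
            if (col[obs] <= 0).any():
                raise DataValidationError(f"{spec.name}: non-positive value under log transform")
            col[obs] = np.log(col[obs])
        elif spec.transform == "log1p":
            if (col[obs] <= -1).any():
                raise DataValidationError(f"{spec.name}: value <= -1 under log1p transform")
            col[obs] = np.log1p(col[obs])
        df[spec.name] = col
    return data.with_df(df)


def invert_transforms(data: TrialDataset) -> TrialDataset:
    """Inverse of :func:`apply_transforms` (exp / expm1 on observed cells)."""
    df = data.df.copy()
    for spec in data.schema:
        if spec.transform == "none":
            continue
        col = df[spec.name].to_numpy(float)
        obs = ~np.isnan(col)
        col[obs] = np.exp(col[obs]) if spec.transform == "log" else np.expm1(col[obs])
        df[spec.name] = col
    return data.with_df(df)


def compute_standardization(data: TrialDataset) -> StandardizationParams:
    """Mean and population SD (divisor ``n``) of every flagged variable.

    Runs after imputation, so flagged columns must be complete.
    """
    means, sds = {}, {}
    for spec in _standardized_vars(data.schema):
        x = data.df[spec.name].to_numpy(float)
        if np.isnan(x).any():
            raise DataValidationError(f"{spec.name}: missing values present; standardise after imputation")
        mu = float(x.mean())
        sigma = float(np.sqrt(((x - mu) ** 2).mean()))
        if sigma == 0.0:
            raise DataValidationError(f"constant column: {spec.name!r}")
        means[spec.name] = mu
        sds[spec.name] = sigma
    return StandardizationParams(means, sds)


def standardize(data: TrialDataset, params: StandardizationParams) -> TrialDataset:
    """Apply ``(x - mean) / sd`` to every flagged continuous predictor."""
    df = data.df.copy()
    for spec in _standardized_vars(data.schema):
        if spec.name not in params.means:
            raise DataValidationError(f"no standardisation parameters for {spec.name!r}")
        df[spec.name] = (df[spec.name] - params.means[spec.name]) / params.sds[spec.name]
    return data.with_df(df)


def pool_standardization(params: Sequence[StandardizationParams]) -> StandardizationParams:
    """Combine per-imputation constants by their mean (Rubin point pooling)."""
    if not params:
        raise ValueError("no parameter sets to pool")
    names = params[0].names
    means = {n: float(np.mean([p.means[n] for p in params])) for n in names}
    sds = {n: float(np.mean([p.sds[n] for p in params])) for n in names}
    return StandardizationParams(means, sds, provenance="pooled_across_imputations")


# ---------------------------------------------------------------------------
# Orthogonal polynomial contrasts

_SUFFIXES = (".L", ".Q", ".C")


def _contrast_names(name: str, k: int) -> list[str]:
    out = []
    for degree in range(1, k):
        if degree <= 3:
            out.append(name + _SUFFIXES[degree - 1])
        else:
            out.append(f"{name}.{degree}")
    return out


def orthonormal_poly_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal polynomial contrast matrix over equally spaced scores.

    Columns are mutually orthogonal, sum to zero over the k levels and have
    unit Euclidean norm — the convention of standard statistical software.
    """
    if k < 2:
        raise ValueError("need at least 2 levels")
    scores = np.arange(1, k + 1, dtype=float)
    vander = np.vander(scores, k, increasing=True)  # columns 1, s, s^2, ...
    q, r = np.linalg.qr(vander)
    # fix signs so the linear column increases with the level score
    q = q * np.sign(np.diag(r))
    basis = q[:, 1:]
    return basis


@dataclass(frozen=True)
class ContrastBasis:
    """Orthonormal polynomial contrast columns for one ordinal variable."""

    name: str
    levels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    @property
    def column_names(self) -> list[str]:
        return _contrast_names(self.name, len(self.levels))


def contrast_basis(name: str, levels: Sequence[str]) -> ContrastBasis:
    return ContrastBasis(name, tuple(levels), orthonormal_poly_contrasts(len(levels)))


def expand_ordinal(data: TrialDataset) -> pd.DataFrame:
    """Replace each ordinal predictor by its k-1 polynomial contrast columns.

    Returns a design frame containing the (already transformed /
    standardised) continuous predictors and the contrast columns, named
    ``var.L``, ``var.Q``, ... in level order.
    """
    cols = {}
    for spec in data.schema.predictors:
        x = data.df[spec.name].to_numpy(float)
        if spec.kind == "continuous":
            cols[spec.name] = x
            continue
        if np.isnan(x).any():
            raise DataValidationError(f"{spec.name}: missing values; expand after imputation")
        codes = x.astype(int)
        if codes.min() < 0 or codes.max() >= spec.n_levels:
            raise DataValidationError(f"{spec.name}: level outside declared set")
        basis = orthonormal_poly_contrasts(spec.n_levels)
        for j, cname in enumerate(_contrast_names(spec.name, spec.n_levels)):
            cols[cname] = basis[codes, j]
    return pd.DataFrame(cols, index=data.df.index)


def design_column_names(schema: Schema) -> list[str]:
    """Design-matrix column names in schema order."""
    names = []
    for spec in schema.predictors:
        if spec.kind == "continuous":
            names.append(spec.name)
        else:
            names.extend(_contrast_names(spec.name, spec.n_levels))
    return names


def build_design(data: TrialDataset, params: StandardizationParams | None = None) -> pd.DataFrame:
    """Standardise (optionally with supplied constants) then expand ordinals."""
    if params is None:
        params = compute_standardization(data)
    return expand_ordinal(standardize(data, params))


# ---------------------------------------------------------------------------
# Pairwise correlation-screen plots (for human review, no automated exclusion)


def pairwise_plots(data: TrialDataset, outdir: str | Path, fmt: str = "png") -> list[Path]:
    """Write one plot per predictor pair: scatter (two continuous), stacked
    bar (two ordinal) or box plot (mixed), for visual collinearity review."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    preds = data.schema.predictors
    for i, a in enumerate(preds):
        for b in preds[i + 1:]:
            sub = data.df[[a.name, b.name]].dropna()
            fig, ax = plt.subplots(figsize=(4, 3))
            if a.kind == "continuous" and b.kind == "continuous":
                ax.scatter(sub[a.name], sub[b.name], s=6, alpha=0.4)
                ax.set_xlabel(a.name)
                ax.set_ylabel(b.name)
            elif a.kind == "ordinal" and b.kind == "ordinal":
                tab = pd.crosstab(sub[a.name], sub[b.name])
                tab.plot(kind="bar", stacked=True, ax=ax, legend=False)
                ax.set_xlabel(a.name)
            else:
                cont, cat = (a, b) if a.kind == "continuous" else (b, a)
                groups = [g[cont.name].to_numpy() for _, g in sub.groupby(cat.name)]
                ax.boxplot(groups)
                ax.set_xlabel(cat.name)
                ax.set_ylabel(cont.name)
            fig.tight_layout()
            path = outdir / f"pair_{a.name}_{b.name}.{fmt}"
            fig.savefig(path)
            plt.close(fig)
            written.append(path)
    return written
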