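"""Cox partial-likelihood machinery.

Univariate and multivariable fits, LASSO-penalised fits at a fixed penalty,
cross-validated penalty selection with a single shared penalty across
imputed datasets, bootstrap standard errors, and predicted survival
probabilities from the Breslow baseline hazard.

The penalised objective is the glmnet-style scaled partial log-likelihood

    (1/n) * l(beta) - lambda * sum_i |beta_i|

so penalty values live on the familiar glmnet scale.  Unpenalised fits
(lambda = 0) are delegated to lifelines (Newton-Raphson, Efron ties);
penalised fits are delegated to scikit-survival's coordinate-descent
Coxnet solver (Breslow ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "CoxFit",
    "PenalizedCoxFit",
    "LambdaStar",
    "fit_cox",
    "cox_partial_loglik",
    "breslow_cumhaz",
    "default_lambda_sequence",
    "cv_lambda",
    "lambda_star",
    "bootstrap_se",
    "predict_survival",
    "univariate_cox",
    "coefficient_path",
]


class FitError(RuntimeError):
    pass


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(int)
    if e.sum() < 1:
        raise FitError("no events in data")
    return t, e


def cox_partial_loglik(
    X: np.ndarray | pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Cox partial log-likelihood at ``beta`` (Breslow or Efron ties)."""
    X = np.asarray(X, float)
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(int)
    order = np.argsort(t, kind="stable")
    X, t, e = X[order], t[order], e[order]
    eta = X @ np.asarray(beta, float)
    r = np.exp(eta)
    if ties == "breslow":
        # vectorised: risk-set sums via reverse cumulative sums over tied groups
        suffix = np.cumsum(r[::-1])[::-1]
        uniq, starts = np.unique(t, return_index=True)
        riskset = suffix[starts]  # risk set at each unique time
        d = np.add.reduceat(e.astype(float), starts)
        return float(eta[e == 1].sum() - np.sum(d * np.log(riskset)))
    if ties != "efron":
        raise ValueError(f"unknown tie method {ties!r}")
    ll = 0.0
    cum_suffix = np.cumsum(r[::-1])[::-1]
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        cum = cum_suffix[i]
        d_idx = [k for k in range(i, j) if e[k] == 1]
        d = len(d_idx)
        if d:
            ll += eta[d_idx].sum()
            tie_sum = r[d_idx].sum()
            for l in range(d):
                ll -= np.log(cum - (l / d) * tie_sum)
        i = j
    return float(ll)


def breslow_cumhaz(
    time: np.ndarray, event: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard at event times."""
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(int)
    r = np.exp(np.asarray(pi, float))
    order = np.argsort(t, kind="stable")
    t, e, r = t[order], e[order], r[order]
    suffix = np.cumsum(r[::-1])[::-1]  # risk-set mass at each sorted index
    times, increments = [], []
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        if d > 0:
            times.append(t[i])
            increments.append(d / suffix[i])
        i = j
    return np.asarray(times), np.cumsum(increments)


@dataclass
class CoxFit:
    """Unpenalised Cox fit (maximum partial likelihood)."""

    coef: pd.Series
    cov: pd.DataFrame
    loglik: float
    ties: str
    baseline_times: np.ndarray = field(repr=False)
    baseline_cumhaz: np.ndarray = field(repr=False)
    max_followup: float = np.inf

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.coef.index)

    def prognostic_index(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.coef.index].to_numpy(float) @ self.coef.to_numpy()


@dataclass
class PenalizedCoxFit:
    """LASSO-penalised Cox fit at a fixed penalty ``lam``."""

    lam: float
    coef: pd.Series
    baseline_times: np.ndarray = field(repr=False)
    baseline_cumhaz: np.ndarray = field(repr=False)
    max_followup: float = np.inf
    lambda_sequence: np.ndarray | None = field(default=None, repr=False)

    @property
    def selected(self) -> list[str]:
        return list(self.coef.index[self.coef != 0.0])

    def prognostic_index(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.coef.index].to_numpy(float) @ self.coef.to_numpy()


def _lifelines_fit(X: pd.DataFrame, time, event, ties: str) -> CoxFit:
    df = X.copy()
    df["_time"] = np.asarray(time, float)
    df["_event"] = np.asarray(event, float).astype(int)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event",
                fit_options={"precision": 1e-10, "max_steps": 500})
    coef = pd.Series(cph.params_.to_numpy(), index=list(X.columns))
    cov = pd.DataFrame(cph.variance_matrix_.to_numpy(), index=coef.index, columns=coef.index)
    pi = X.to_numpy(float) @ coef.to_numpy()
    bt, bh = breslow_cumhaz(time, event, pi)
    return CoxFit(
        coef=coef, cov=cov, loglik=float(cph.log_likelihood_), ties=ties,
        baseline_times=bt, baseline_cumhaz=bh, max_followup=float(np.max(time)),
    )


def _coxnet_fit(X: pd.DataFrame, time, event, alphas: Sequence[float]) -> np.ndarray:
    y = Surv.from_arrays(event=np.asarray(event, bool), time=np.asarray(time, float))
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=list(alphas), normalize=False,
        fit_baseline_model=False, tol=1e-9, max_iter=100000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X.to_numpy(float), y)
    return model  # .coef_ is (p, n_alphas)


def fit_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    lam: float = 0.0,
    ties: str = "efron",
) -> CoxFit | PenalizedCoxFit:
    """Maximise ``(1/n) l(beta) - lam * sum |beta_i|``.

    ``lam = 0`` returns an unpenalised :class:`CoxFit` with model-based
    variances; ``lam > 0`` returns a sparse :class:`PenalizedCoxFit`.
    The baseline cumulative hazard is the Breslow estimator at the fitted
    coefficients.
    """
    _as_arrays(time, event)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if lam == 0.0:
        return _lifelines_fit(X, time, event, ties)
    model = _coxnet_fit(X, time, event, [lam])
    coef = pd.Series(model.coef_[:, 0], index=list(X.columns))
    pi = X.to_numpy(float) @ coef.to_numpy()
    bt, bh = breslow_cumhaz(time, event, pi)
    return PenalizedCoxFit(
        lam=float(lam), coef=coef, baseline_times=bt, baseline_cumhaz=bh,
        max_followup=float(np.max(time)),
    )


def default_lambda_sequence(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_lambdas: int = 100,
    min_ratio: float = 0.001,
) -> np.ndarray:
    """Log-spaced penalty sequence from lambda_max (all-zero solution) down
    to ``min_ratio * lambda_max``."""
    y = Surv.from_arrays(event=np.asarray(event, bool), time=np.asarray(time, float))
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_lambdas, alpha_min_ratio=min_ratio,
        normalize=False, fit_baseline_model=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X.to_numpy(float), y)
    return np.asarray(model.alphas_, float)


def coefficient_path(X, time, event, alphas) -> pd.DataFrame:
    """Coefficients along the penalty sequence (columns = penalty values)."""
    model = _coxnet_fit(X, time, event, alphas)
    return pd.DataFrame(model.coef_, index=list(X.columns), columns=list(model.alphas_))


def _stratified_event_folds(event: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels balancing events across folds."""
    e = np.asarray(event).astype(int)
    labels = np.empty(len(e), int)
    for group in (np.flatnonzero(e == 1), np.flatnonzero(e == 0)):
        perm = rng.permutation(group)
        labels[perm] = np.arange(len(perm)) % folds
    return labels


def cv_lambda(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    folds: int = 10,
    alphas: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    retries: int = 5,
    fold_labels: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Cross-validated penalty choice minimising partial-likelihood deviance.

    The deviance contribution of fold k uses the subtraction formulation:
    ``-2 * [l(beta_{-k}; all data) - l(beta_{-k}; data without fold k)]``,
    summed over folds; Breslow ties, matching the coordinate-descent solver.
    Returns the optimal penalty and the deviance curve over ``alphas``.
    ``fold_labels`` fixes the fold assignment externally (used to share one
    assignment across imputed datasets).
    """
    if folds < 3:
        raise ValueError("need at least 3 folds")
    t, e = _as_arrays(time, event)
    rng = rng or np.random.default_rng()
    if alphas is None:
        alphas = default_lambda_sequence(X, t, e)
    alphas = np.asarray(list(alphas), float)
    if len(alphas) > 1 and not np.all(np.diff(alphas) < 0):
        raise ValueError("penalty sequence must be strictly decreasing")
    if len(alphas) == 1:
        return float(alphas[0]), np.zeros(1)
    Xa = X.to_numpy(float)
    if fold_labels is not None:
        labels = np.asarray(fold_labels, int)
        folds = int(labels.max()) + 1
        if not all(e[labels != k].sum() > 0 for k in range(folds)):
            raise FitError("supplied folds leave a training split without events")
    else:
        for attempt in range(retries):
            labels = _stratified_event_folds(e, folds, rng)
            if all(e[labels != k].sum() > 0 for k in range(folds)):
                break
        else:
            raise FitError("could not build folds with events in every training split")
    deviance = np.zeros(len(alphas))
    for k in range(folds):
        train = labels != k
        model = _coxnet_fit(X.iloc[train], t[train], e[train], alphas)
        fitted_alphas = np.asarray(model.alphas_, float)
        for j, lam in enumerate(alphas):
            beta = model.coef_[:, int(np.argmin(np.abs(fitted_alphas - lam)))]
            ll_all = cox_partial_loglik(Xa, t, e, beta, ties="breslow")
            ll_train = cox_partial_loglik(Xa[train], t[train], e[train], beta, ties="breslow")
            deviance[j] += -2.0 * (ll_all - ll_train)
    best = int(np.argmin(deviance))
    return float(alphas[best]), deviance


@dataclass
class LambdaStar:
    """Shared penalty: mean of the per-imputation cross-validated optima."""

    per_imputation: list[float]
    sequence: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_imputation))

    @property
    def sd(self) -> float:
        if len(self.per_imputation) < 2:
            return 0.0
        return float(np.std(self.per_imputation, ddof=1))


def lambda_star(
    designs: Sequence[tuple[pd.DataFrame, np.ndarray, np.ndarray]],
    folds: int = 10,
    rng: np.random.Generator | None = None,
    n_lambdas: int = 100,
    min_ratio: float = 0.001,
) -> LambdaStar:
    """Shared penalty across imputed datasets.

    The penalty sequence is generated once, from the first imputed dataset,
    and reused for every imputation's cross-validation; one fold assignment
    (the subjects are the same in every imputation) is likewise shared, so
    identical imputed datasets yield identical optima.  The shared penalty
    is the arithmetic mean of the per-imputation optima.
    """
    if not designs:
        raise ValueError("no imputed designs supplied")
    rng = rng or np.random.default_rng()
    X0, t0, e0 = designs[0]
    sequence = default_lambda_sequence(X0, t0, e0, n_lambdas=n_lambdas, min_ratio=min_ratio)
    e_arr = np.asarray(e0).astype(int)
    for attempt in range(5):
        labels = _stratified_event_folds(e_arr, folds, rng)
        if all(e_arr[labels != k].sum() > 0 for k in range(folds)):
            break
    else:
        raise FitError("could not build folds with events in every training split")
    optima = []
    for X, t, e in designs:
        lam, _ = cv_lambda(X, t, e, folds=folds, alphas=sequence, fold_labels=labels)
        optima.append(lam)
    return LambdaStar(per_imputation=optima, sequence=sequence)


def bootstrap_se(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    lam: float,
    B: int = 100,
    rng: np.random.Generator | None = None,
    retries: int = 5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Bootstrap SEs of penalised coefficients at a fixed penalty.

    Each of the B resamples refits at ``lam``; coefficients shrunk to zero
    enter the spread as exact zeros.  Returns (SE per column, B x p
    coefficient matrix).
    """
    if B < 2:
        raise ValueError("need B >= 2 resamples")
    t, e = _as_arrays(time, event)
    rng = rng or np.random.default_rng()
    n = len(t)
    rows = []
    for _ in range(B):
        for attempt in range(retries):
            idx = rng.integers(0, n, n)
            if e[idx].sum() > 0:
                break
        else:
            raise FitError("bootstrap resample without events after retries")
        fit = fit_cox(X.iloc[idx], t[idx], e[idx], lam=lam)
        rows.append(fit.coef)
    coefs = pd.DataFrame(rows).reset_index(drop=True)
    se = coefs.std(ddof=1)
    return se, coefs


def predict_survival(
    fit: CoxFit | PenalizedCoxFit,
    X: pd.DataFrame,
    t: float,
) -> np.ndarray:
    """Predicted S(t | x) = exp(-Lambda0(t) * exp(PI)) per subject."""
    if t < 0:
        raise ValueError("horizon must be >= 0")
    if t > fit.max_followup:
        warnings.warn("horizon beyond observed follow-up; extrapolating flat")
    times, cumhaz = fit.baseline_times, fit.baseline_cumhaz
    pos = np.searchsorted(times, t, side="right")
    lam0 = 0.0 if pos == 0 else float(cumhaz[pos - 1])
    pi = fit.prognostic_index(X)
    return np.exp(-lam0 * np.exp(pi))


def univariate_cox(
    design: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    groups: dict[str, list[str]],
) -> dict[str, CoxFit]:
    """One unpenalised Cox fit per variable (its design columns alone)."""
    out = {}
    for var, cols in groups.items():
        out[var] = fit_cox(design[cols], time, event, lam=0.0)
    return out
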