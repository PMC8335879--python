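"""Multiple imputation by chained equations (MICE).

Continuous targets are imputed by Bayesian linear regression with
predictive mean matching (PMM): regression parameters are drawn from their
large-sample posterior, missing entries receive the observed value of a
donor whose predicted mean is among the k nearest to the missing entry's
prediction.  Ordinal targets are imputed from a proportional-odds
cumulative-logit model, sampling a level from the predicted category
distribution (not the modal category) after a posterior parameter draw.

Each imputation model regresses its target on the remaining predictors,
the auxiliary variables (e.g. sex), the survival time in months and the
event indicator; randomised treatment is excluded.  Variables are visited
from least to most missing; missing cells are initialised by random draws
from the observed marginals before the first cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import MissingPatternSummary, Schema, TrialDataset

__all__ = [
    "ImputationSpec",
    "ImputedStack",
    "ImputationError",
    "choose_m",
    "impute",
]


class ImputationError(RuntimeError):
    """A conditional imputation model failed (variable and cycle in message)."""


def choose_m(summary: MissingPatternSummary, threshold: float = 25.0) -> int:
    """Number of imputed datasets from the pre-specified missingness rule.

    If no variable exceeds ``threshold`` percent missing, use 10; otherwise
    fall back to the rule of thumb m = ceil(percent of incomplete cases).
    Fully observed data needs no imputation (m = 1, pass-through).
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    if summary.complete_count == summary.n:
        return 1
    if summary.max_variable_percent <= threshold:
        return 10
    return int(math.ceil(summary.incomplete_percent))


@dataclass(frozen=True)
class ImputationSpec:
    """Configuration of the chained-equations run."""

    m: int = 10
    cycles: int = 5
    donors: int = 5
    use_nelson_aalen: bool = False  # survival representation in the models

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.cycles < 1 or self.donors < 1:
            raise ValueError("cycles and donors must be >= 1")


@dataclass
class ImputedStack:
    """m completed copies of a dataset plus imputation metadata."""

    datasets: "list[TrialDataset]"
    spec: ImputationSpec
    visit_order: "list[str]"
    seed_entropy: object = None

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def to_long(self) -> pd.DataFrame:
        """Long-format export with an imputation-index column."""
        frames = []
        for i, ds in enumerate(self.datasets, start=1):
            df = ds.df.copy()
            df.insert(0, "_imputation", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _visit_order(data: TrialDataset) -> list[str]:
    """Predictors with missing values, least missing first; schema order
    breaks ties."""
    mask = data.missing_mask()
    counts = mask.sum(axis=0)
    with_missing = [(int(counts[name]), j, name)
                    for j, name in enumerate(data.schema.predictor_names)
                    if counts[name] > 0]
    return [name for _, _, name in sorted(with_missing)]


def _model_columns(schema: Schema, target: str, spec: ImputationSpec,
                   na_cumhaz: bool) -> list[str]:
    cols = [v.name for v in schema.predictors if v.name != target]
    cols += [v.name for v in schema.auxiliaries]
    cols += ["_surv" if na_cumhaz else schema.time_var, schema.event_var]
    return cols


def _nelson_aalen(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    at_risk = n - np.arange(n)
    increments = np.where(e == 1, 1.0 / at_risk, 0.0)
    cum = np.cumsum(increments)
    out = np.empty(n)
    out[order] = cum
    return out


def _bayes_linear_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Posterior draw (beta*, sigma*) for a normal linear model and the
    least-squares point estimate beta_hat."""
    n, p = X.shape
    xtx = X.T @ X
    # ridge jitter guards against exactly collinear resamples
    xtx_inv = np.linalg.pinv(xtx + 1e-10 * np.eye(p))
    beta_hat = xtx_inv @ X.T @ y
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2_star = sigma2_hat * dof / max(rng.chisquare(dof), 1e-12)
    cov = sigma2_star * xtx_inv
    cov = (cov + cov.T) / 2.0
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise ImputationError(f"singular design: {exc}") from None
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    return beta_hat, beta_star


def _pmm_impute(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
                donors: int, rng: np.random.Generator) -> np.ndarray:
    beta_hat, beta_star = _bayes_linear_draw(X_obs, y_obs, rng)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_star
    k = min(donors, len(y_obs))
    out = np.empty(len(yhat_mis))
    dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    for i in range(len(yhat_mis)):
        nearest = np.argpartition(dist[i], k - 1)[:k]
        out[i] = y_obs[nearest[rng.integers(0, k)]]
    return out


# -- proportional-odds (cumulative-logit) machinery -------------------------
# Parameterisation: params = [beta (p), theta (K-1)] with thresholds
# alpha = cumsum([theta_0, exp(theta_1), ...]) guaranteeing alpha increasing.
# Analytic gradients keep the chained-equations loop fast.


def _po_thresholds(theta: np.ndarray) -> np.ndarray:
    inc = np.concatenate([[theta[0]], np.exp(theta[1:])])
    return np.cumsum(inc)


def _po_probs(params: np.ndarray, X: np.ndarray, K: int) -> np.ndarray:
    from scipy.special import expit

    p = X.shape[1]
    beta, theta = params[:p], params[p:]
    alpha = _po_thresholds(theta)
    eta = X @ beta
    gamma = expit(alpha[None, :] - eta[:, None])  # (n, K-1) cumulative probs
    full = np.column_stack([np.zeros(len(X)), gamma, np.ones(len(X))])
    return np.diff(full, axis=1)  # (n, K) category probabilities


def _po_negloglik_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray, K: int):
    from scipy.special import expit

    n, p = X.shape
    beta, theta = params[:p], params[p:]
    alpha = _po_thresholds(theta)
    eta = X @ beta
    # sigma and density at each threshold, per subject
    a = alpha[None, :] - eta[:, None]
    gamma = expit(a)
    phi = gamma * (1.0 - gamma)
    gfull = np.column_stack([np.zeros(n), gamma, np.ones(n)])
    prob = gfull[np.arange(n), y + 1] - gfull[np.arange(n), y]
    prob = np.maximum(prob, 1e-300)
    ll = float(np.log(prob).sum())
    # d ll_i / d eta_i = (-phi_{y} + phi_{y-1}) / prob  (phi_{-1}=phi_{K-1}=0)
    phifull = np.column_stack([np.zeros(n), phi, np.zeros(n)])
    dll_deta = (phifull[np.arange(n), y] - phifull[np.arange(n), y + 1]) / prob
    grad_beta = X.T @ dll_deta
    # d ll_i / d alpha_j = phi_j * ([y_i = j] - [y_i = j+1]) / prob_i
    grad_alpha = np.zeros(K - 1)
    for j in range(K - 1):
        sign = (y == j).astype(float) - (y == j + 1).astype(float)
        grad_alpha[j] = np.sum(phi[:, j] * sign / prob)
    # chain rule alpha -> theta
    grad_theta = np.empty(K - 1)
    grad_theta[0] = grad_alpha.sum()
    for j in range(1, K - 1):
        grad_theta[j] = np.exp(theta[j]) * grad_alpha[j:].sum()
    return -ll, -np.concatenate([grad_beta, grad_theta])


def _po_fit(y: np.ndarray, X: np.ndarray, K: int, start: np.ndarray | None = None):
    """Maximum-likelihood proportional-odds fit; returns (params, cov)."""
    from scipy.optimize import minimize

    n, p = X.shape
    if start is None:
        freq = np.bincount(y, minlength=K) + 0.5
        cum = np.cumsum(freq[:-1]) / freq.sum()
        alpha0 = np.log(cum / (1 - cum))
        theta0 = np.concatenate([[alpha0[0]], np.log(np.maximum(np.diff(alpha0), 1e-3))])
        start = np.concatenate([np.zeros(p), theta0])
    res = minimize(_po_negloglik_grad, start, args=(X, y, K), jac=True,
                   method="L-BFGS-B", options={"maxiter": 300})
    params = res.x
    if not np.all(np.isfinite(params)):
        raise ImputationError("non-finite ordinal model parameters")
    # observed-information covariance via finite differences of the gradient
    d = len(params)
    eps = 1e-5
    H = np.empty((d, d))
    for j in range(d):
        step = np.zeros(d)
        step[j] = eps
        _, gp = _po_negloglik_grad(params + step, X, y, K)
        _, gm = _po_negloglik_grad(params - step, X, y, K)
        H[:, j] = (gp - gm) / (2 * eps)
    H = (H + H.T) / 2.0
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError as exc:
        raise ImputationError(f"singular ordinal information matrix: {exc}") from None
    return params, cov


def _ordinal_impute(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
                    n_levels: int, rng: np.random.Generator,
                    start_cache: dict, cache_key) -> np.ndarray:
    observed_levels = np.unique(y_obs.astype(int))
    if len(observed_levels) == 1:
        return np.full(len(X_mis), float(observed_levels[0]))
    # compress to consecutive codes over the observed levels
    remap = {lvl: j for j, lvl in enumerate(observed_levels)}
    y_c = np.array([remap[v] for v in y_obs.astype(int)])
    K = len(observed_levels)
    start = start_cache.get(cache_key)
    if start is not None and len(start) != X_obs.shape[1] + K - 1:
        start = None
    try:
        params, cov = _po_fit(y_c, X_obs, K, start=start)
    except ImputationError:
        raise
    except Exception as exc:  # singular / separation
        raise ImputationError(str(exc)) from None
    start_cache[cache_key] = params
    cov = (cov + cov.T) / 2.0
    try:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(params)))
    except np.linalg.LinAlgError as exc:
        raise ImputationError(f"singular ordinal information matrix: {exc}") from None
    params_star = params + chol @ rng.standard_normal(len(params))
    probs = _po_probs(params_star, X_mis, K)
    probs = np.clip(probs, 1e-12, None)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(X_mis))
    picked = (u[:, None] > cum).sum(axis=1)
    return observed_levels[picked].astype(float)


def impute(
    data: TrialDataset,
    spec: ImputationSpec,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> ImputedStack:
    """Run chained equations and return m completed copies of ``data``.

    Observed cells are identical (bit-for-bit) across the m datasets; the
    same seed and spec always reproduce the same stack.
    """
    mask = data.missing_mask()
    visit = _visit_order(data)
    if not visit:
        datasets = [data.copy() for _ in range(spec.m)]
        return ImputedStack(datasets=datasets, spec=spec, visit_order=[])

    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed if isinstance(seed, int) else seed.integers(2**31))
    children = ss.spawn(spec.m)

    schema = data.schema
    time = data.time
    event = data.event
    surv = _nelson_aalen(time, event.astype(float)) if spec.use_nelson_aalen else None

    datasets = []
    for i in range(spec.m):
        rng = np.random.default_rng(children[i])
        df = data.df.copy()
        if spec.use_nelson_aalen:
            df["_surv"] = surv
        # initialise missing cells from observed marginals
        for var in visit:
            col = df[var].to_numpy(float)
            miss = mask[var].to_numpy()
            obs_vals = col[~miss]
            col[miss] = rng.choice(obs_vals, size=int(miss.sum()), replace=True)
            df[var] = col
        start_cache: dict = {}
        for cycle in range(spec.cycles):
            for var in visit:
                vspec = schema[var]
                miss = mask[var].to_numpy()
                pred_cols = _model_columns(schema, var, spec, spec.use_nelson_aalen)
                X = df[pred_cols].to_numpy(float)
                X = np.column_stack([np.ones(len(X)), X])
                y = df[var].to_numpy(float)
                try:
                    if vspec.kind == "continuous":
                        imputed = _pmm_impute(y[~miss], X[~miss], X[miss],
                                              spec.donors, rng)
                    else:
                        # no intercept column: the cumulative-logit thresholds
                        # absorb the constant
                        imputed = _ordinal_impute(
                            data.df[var].to_numpy(float)[~miss],
                            X[~miss][:, 1:], X[miss][:, 1:],
                            vspec.n_levels, rng, start_cache, var,
                        )
                except ImputationError as exc:
                    raise ImputationError(
                        f"imputation model for {var!r} failed in cycle {cycle + 1}: {exc}"
                    ) from None
                y[miss] = imputed
                df[var] = y
        if spec.use_nelson_aalen:
            df = df.drop(columns=["_surv"])
        datasets.append(TrialDataset(schema, df))
    return ImputedStack(datasets=datasets, spec=spec, visit_order=visit,
                        seed_entropy=ss.entropy)
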