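"""Model assessment: discrimination, calibration and the PH assumption.

Discrimination uses the prognostic-separation D-statistic: subjects are
ordered by prognostic index, assigned scaled rankits

    z_i = (8/pi)^(-1/2) * Phi^{-1}((i - 3/8) / (n + 1/4))

(Bloom's approximation to the expected normal order statistics), and
overall survival is regressed on z in a Cox model; D is the slope.  D is
a log hazard ratio between prognostically "typical" halves of the cohort
and, unlike concordance measures, pools cleanly across imputed datasets
by Rubin's rules.  Uno's inverse-probability-of-censoring-weighted C is
reported alongside at fixed horizons.

Calibration splits each imputed dataset into ten groups by deciles of the
predicted survival probability at a horizon and compares the group median
predicted probability with the Kaplan-Meier observed probability; the
calibration slope regresses predicted on observed over the group points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import norm, rankdata, linregress

from .pooling import PooledEstimate, pool
from .survival_models import CoxFit, PenalizedCoxFit, fit_cox, predict_survival

__all__ = [
    "DStatResult",
    "CalibrationResult",
    "PHCheckResult",
    "bloom_rankits",
    "scaled_rankits_for",
    "d_statistic",
    "combined_d",
    "km_estimate_at",
    "calibration",
    "calibration_slope",
    "schoenfeld_residuals",
    "ph_check",
    "uno_c",
]

SCALE = float(np.sqrt(np.pi / 8.0))  # (8/pi)^(-1/2)

# analysis horizons, in months (survival time unit): 60 days and 1 year
HORIZON_60D = 60.0 / (365.25 / 12.0)
HORIZON_1Y = 12.0


def bloom_rankits(n: int) -> np.ndarray:
    """Scaled rankits z_1 < ... < z_n by Bloom's approximation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(1, n + 1, dtype=float)
    return SCALE * norm.ppf((i - 0.375) / (n + 0.25))


def scaled_rankits_for(pi: np.ndarray) -> np.ndarray:
    """Assign scaled rankits by ascending prognostic index.

    Ties share the Bloom formula evaluated at their average rank
    (mid-rankits), keeping the assignment deterministic and
    permutation-invariant.
    """
    pi = np.asarray(pi, float)
    if not np.all(np.isfinite(pi)):
        raise ValueError("prognostic index must be finite")
    n = len(pi)
    ranks = rankdata(pi, method="average")
    return SCALE * norm.ppf((ranks - 0.375) / (n + 0.25))


def d_statistic(
    pi: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
) -> tuple[float, float]:
    """Prognostic-separation D and its model-based variance.

    Invariant under strictly increasing transformations of the prognostic
    index (only the ranks enter).
    """
    from .survival_models import cox_partial_loglik

    pi = np.asarray(pi, float)
    if np.all(pi == pi[0]):
        raise ValueError("all-tied prognostic index: D undefined")
    z = scaled_rankits_for(pi)
    X = pd.DataFrame({"rankit": z})
    fit = fit_cox(X, time, event, lam=0.0, ties=ties)
    d = float(fit.coef["rankit"])
    # polish the scalar estimate with Newton steps on the partial likelihood
    # (the general-purpose solver stops a little short of machine precision)
    Xa = z[:, None]
    h = 1e-5
    hess = -1.0 / float(fit.cov.loc["rankit", "rankit"])
    for _ in range(20):
        lp = cox_partial_loglik(Xa, time, event, np.array([d + h]), ties)
        lm = cox_partial_loglik(Xa, time, event, np.array([d - h]), ties)
        l0 = cox_partial_loglik(Xa, time, event, np.array([d]), ties)
        grad = (lp - lm) / (2 * h)
        hess = (lp - 2 * l0 + lm) / h**2
        if hess >= 0:
            break
        step = grad / hess
        d -= step
        if abs(step) < 1e-11:
            break
    var = -1.0 / hess if hess < 0 else float(fit.cov.loc["rankit", "rankit"])
    return d, var


@dataclass
class DStatResult:
    """Per-imputation D-statistics and the Rubin-combined D."""

    per_imputation: "list[tuple[float, float]]"  # (D, variance)
    pooled: PooledEstimate

    @property
    def combined(self) -> float:
        return self.pooled.estimate

    @property
    def ci(self) -> tuple[float, float]:
        return self.pooled.ci


def combined_d(
    pis: Sequence[np.ndarray],
    time: np.ndarray,
    event: np.ndarray,
) -> DStatResult:
    """D-statistic per imputation (shared outcome columns), Rubin-pooled."""
    if len(pis) < 2:
        raise ValueError("need m >= 2 imputations to combine")
    per = [d_statistic(pi, time, event) for pi in pis]
    pooled = pool([d for d, _ in per], [v for _, v in per])
    return DStatResult(per_imputation=per, pooled=pooled)


def km_estimate_at(
    time: np.ndarray,
    event: np.ndarray,
    t: float,
    conf_level: float = 0.95,
) -> tuple[float, float, float]:
    """Kaplan-Meier S(t) with Greenwood confidence limits."""
    kmf = KaplanMeierFitter(alpha=1 - conf_level)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(time, event)
        s = float(kmf.predict(t))
        ci = kmf.confidence_interval_survival_function_
        lo = float(ci.iloc[:, 0].asof(t))
        hi = float(ci.iloc[:, 1].asof(t))
    return s, lo, hi


@dataclass
class CalibrationResult:
    """Decile-group calibration at one horizon, per imputed dataset."""

    horizon: float
    tables: "list[pd.DataFrame]"  # per imputation: group, n, predicted, observed, ci

    @property
    def m(self) -> int:
        return len(self.tables)

    def to_tsv(self, path=None) -> str:
        frames = []
        for i, tab in enumerate(self.tables, start=1):
            tab = tab.copy()
            tab.insert(0, "imputation", i)
            frames.append(tab)
        text = pd.concat(frames, ignore_index=True).to_csv(sep="\t", index=False)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def plot(self, path) -> None:
        """Predicted vs observed probabilities per imputation, with CIs and
        the identity line."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for i, tab in enumerate(self.tables, start=1):
            usable = tab.dropna(subset=["observed"])
            ax.errorbar(
                usable["observed"], usable["predicted"],
                xerr=[usable["observed"] - usable["ci_low"],
                      usable["ci_high"] - usable["observed"]],
                fmt="o", ms=3, alpha=0.6, capsize=2,
                label=f"imputation {i}" if self.m <= 3 else None,
            )
        lims = (0.0, 1.0)
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlim(lims)
        ax.set_ylim(lims)
        ax.set_xlabel("observed survival probability (KM)")
        ax.set_ylabel("predicted survival probability")
        ax.set_title(f"calibration at t = {self.horizon:.2f} months")
        if self.m <= 3:
            ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def _group_by_deciles(p: np.ndarray, n_groups: int) -> np.ndarray:
    qs = np.quantile(p, np.linspace(0, 1, n_groups + 1)[1:-1])
    qs = np.unique(qs)  # ties may force fewer groups
    return np.searchsorted(qs, p, side="left")


def calibration(
    fits: Sequence[CoxFit | PenalizedCoxFit],
    designs: Sequence[pd.DataFrame],
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
    n_groups: int = 10,
) -> CalibrationResult:
    """Predicted vs KM-observed survival in predicted-probability deciles.

    Per imputation: subjects are grouped by the deciles of their predicted
    S(horizon); each group's predicted value is the median prediction and
    its observed value the Kaplan-Meier estimate at the horizon with a
    Greenwood 95% CI.  Groups with nobody at risk at the horizon report an
    unavailable (NaN) observed probability.
    """
    t_arr = np.asarray(time, float)
    if horizon > t_arr.max():
        raise ValueError("horizon beyond maximum follow-up")
    e_arr = np.asarray(event, float).astype(int)
    tables = []
    for fit, X in zip(fits, designs):
        p = predict_survival(fit, X, horizon)
        groups = _group_by_deciles(p, n_groups)
        rows = []
        for g in np.unique(groups):
            sel = groups == g
            tg, eg = t_arr[sel], e_arr[sel]
            if (tg >= horizon).sum() == 0 and eg[tg < horizon].sum() == 0:
                obs = lo = hi = np.nan
            else:
                obs, lo, hi = km_estimate_at(tg, eg, horizon)
            rows.append({
                "group": int(g),
                "n": int(sel.sum()),
                "predicted": float(np.median(p[sel])),
                "observed": obs,
                "ci_low": lo,
                "ci_high": hi,
            })
        tables.append(pd.DataFrame(rows))
    return CalibrationResult(horizon=horizon, tables=tables)


def calibration_slope(result: CalibrationResult) -> tuple[float, list[float]]:
    """Pooled calibration slope: per imputation, the OLS slope of the group
    predicted probabilities regressed on the observed probabilities; the m
    slopes combine by their mean (no CI — only ~10 points per regression)."""
    slopes = []
    for tab in result.tables:
        usable = tab.dropna(subset=["observed"])
        if len(usable) < 2:
            raise ValueError("fewer than 2 usable calibration points")
        if np.allclose(usable["observed"].var(), 0.0):
            raise ValueError("constant observed probabilities: slope undefined")
        slope = float(np.polyfit(usable["observed"], usable["predicted"], 1)[0])
        slopes.append(slope)
    return float(np.mean(slopes)), slopes


def schoenfeld_residuals(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray | pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled Schoenfeld residuals at ``beta``: one row per event,
    x_i minus the risk-set weighted covariate mean.  Returns (event times,
    residual matrix) sorted by event time."""
    Xa = np.asarray(X, float)
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(int)
    b = np.asarray(beta, float)
    order = np.argsort(t, kind="stable")
    Xa, t, e = Xa[order], t[order], e[order]
    w = np.exp(Xa @ b)
    # suffix sums: risk set = subjects with time >= t_i
    w_suffix = np.cumsum(w[::-1])[::-1]
    wx_suffix = np.cumsum((w[:, None] * Xa)[::-1], axis=0)[::-1]
    # for tied times the risk set starts at the first index of the tie group
    first_idx = np.zeros(len(t), dtype=int)
    uniq, starts = np.unique(t, return_index=True)
    first_idx[starts] = starts
    first_idx = np.maximum.accumulate(first_idx)
    ev = np.flatnonzero(e == 1)
    fi = first_idx[ev]
    resid = Xa[ev] - wx_suffix[fi] / w_suffix[fi][:, None]
    return t[ev], resid


def _schoenfeld_with_variance(X, time, event, beta):
    """Schoenfeld residuals plus the risk-set covariate variance V_k at each
    event (diagonal only), needed for the scaled (Grambsch-Therneau) test."""
    Xa = np.asarray(X, float)
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(int)
    b = np.asarray(beta, float)
    order = np.argsort(t, kind="stable")
    Xa, t, e = Xa[order], t[order], e[order]
    w = np.exp(Xa @ b)
    w_suffix = np.cumsum(w[::-1])[::-1]
    wx_suffix = np.cumsum((w[:, None] * Xa)[::-1], axis=0)[::-1]
    wx2_suffix = np.cumsum((w[:, None] * Xa**2)[::-1], axis=0)[::-1]
    first_idx = np.zeros(len(t), dtype=int)
    uniq, starts = np.unique(t, return_index=True)
    first_idx[starts] = starts
    first_idx = np.maximum.accumulate(first_idx)
    ev = np.flatnonzero(e == 1)
    fi = first_idx[ev]
    mean = wx_suffix[fi] / w_suffix[fi][:, None]
    resid = Xa[ev] - mean
    var = wx2_suffix[fi] / w_suffix[fi][:, None] - mean**2
    return t[ev], resid, np.maximum(var, 1e-300)


@dataclass
class PHCheckResult:
    """Per-covariate, per-imputation slope of Schoenfeld residuals on time."""

    table: pd.DataFrame  # columns: imputation, covariate, slope, p_value
    alpha: float = 0.05

    def verdict(self) -> "dict[str, str]":
        out = {}
        for cov, sub in self.table.groupby("covariate"):
            out[str(cov)] = "violated" if (sub["p_value"] < self.alpha).any() else "ok"
        return out

    @property
    def any_violation(self) -> bool:
        return any(v == "violated" for v in self.verdict().values())


def ph_check(
    fits: Sequence[CoxFit | PenalizedCoxFit],
    designs: Sequence[pd.DataFrame],
    time: np.ndarray,
    event: np.ndarray,
    alpha: float = 0.05,
    scaled: bool = False,
) -> PHCheckResult:
    """Proportional-hazards check per covariate in each imputed dataset.

    Default (``scaled=False``): ordinary least squares of the *unscaled*
    Schoenfeld residuals of each fitted covariate on event time;
    proportional hazards for a covariate is accepted when the time
    coefficient is not significantly different from zero at the ``alpha``
    level in any imputation.  The unscaled form avoids inverting a possibly
    singular (e.g. bootstrap) variance matrix but its OLS p-values are
    conservative, since the residuals' true sampling variance shrinks with
    the risk set.

    ``scaled=True`` runs the Grambsch-Therneau score test instead
    (statistic ``[sum (g_k - gbar) r_k]^2 / sum (g_k - gbar)^2 V_k`` with
    g = event time and V_k the risk-set covariate variance), which has
    approximately nominal size.
    """
    if np.asarray(event).astype(int).sum() < 3:
        raise ValueError("need at least 3 events to test proportional hazards")
    from scipy.stats import chi2

    rows = []
    for i, (fit, X) in enumerate(zip(fits, designs), start=1):
        cols = [c for c in fit.coef.index if fit.coef[c] != 0.0]
        if not cols:
            raise ValueError("fitted model has no covariates to check")
        sub = X[cols]
        if scaled:
            et, resid, var = _schoenfeld_with_variance(sub, time, event, fit.coef[cols])
            for j, cov_name in enumerate(cols):
                vj = var[:, j]
                # information-weighted centering of the time axis gives the
                # per-covariate score test nominal size
                gbar = float((et * vj).sum() / vj.sum())
                g = et - gbar
                theta = float(g @ resid[:, j])
                denom = float((g**2) @ vj)
                stat = theta**2 / denom if denom > 0 else 0.0
                rows.append({
                    "imputation": i,
                    "covariate": cov_name,
                    "slope": theta / denom if denom > 0 else 0.0,
                    "p_value": float(chi2.sf(stat, 1)),
                })
        else:
            et, resid = schoenfeld_residuals(sub, time, event, fit.coef[cols])
            for j, cov_name in enumerate(cols):
                res = linregress(et, resid[:, j])
                rows.append({
                    "imputation": i,
                    "covariate": cov_name,
                    "slope": float(res.slope),
                    "p_value": float(res.pvalue),
                })
    return PHCheckResult(table=pd.DataFrame(rows), alpha=alpha)


def uno_c(
    pi: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    tau: float,
) -> float:
    """Uno's IPCW concordance at horizon ``tau``.

    Censoring-robust concordance over comparable pairs whose earlier time
    falls before ``tau``, weighted 1/G(t)^2 by the censoring-distribution
    Kaplan-Meier.  Equals exhaustively enumerated Harrell's C when there is
    no censoring.
    """
    from sksurv.metrics import concordance_index_ipcw
    from sksurv.util import Surv

    if tau <= 0:
        raise ValueError("horizon must be positive")
    y = Surv.from_arrays(event=np.asarray(event, bool), time=np.asarray(time, float))
    c, *_ = concordance_index_ipcw(y, y, np.asarray(pi, float), tau=tau)
    return float(c)
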