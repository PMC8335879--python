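"""Tertile risk stratification from the combined prognostic index.

Cutpoints are the empirical 1/3 and 2/3 quantiles of the *training*
combined prognostic index (linear-interpolation quantile convention) and
are reused unchanged to trichotomise any other cohort; assignment is
monotone in the index with boundary subjects going to the lower group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["RiskGrouping", "derive_groups", "assign_groups", "km_by_group", "plot_km"]

GROUP_LABELS = ("low", "medium", "high")


@dataclass
class RiskGrouping:
    """Tertile cutpoints plus a per-subject group assignment."""

    cutpoints: tuple[float, float]
    groups: np.ndarray = field(repr=False)  # values in GROUP_LABELS

    def counts(self, event: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for lab in GROUP_LABELS:
            sel = self.groups == lab
            row = {"group": lab, "n": int(sel.sum())}
            if event is not None:
                row["events"] = int(np.asarray(event)[sel].astype(int).sum())
            rows.append(row)
        return pd.DataFrame(rows)


def _cutpoints(training_pi: np.ndarray) -> tuple[float, float]:
    pi = np.asarray(training_pi, float)
    if len(pi) == 0:
        raise ValueError("training prognostic index is empty")
    c1, c2 = np.quantile(pi, [1.0 / 3.0, 2.0 / 3.0])
    if not c1 < c2:
        raise ValueError("degenerate cutpoints: prognostic index too concentrated")
    return float(c1), float(c2)


def assign_groups(pi: np.ndarray, cutpoints: tuple[float, float]) -> np.ndarray:
    """low: PI <= c1; medium: c1 < PI <= c2; high: PI > c2."""
    pi = np.asarray(pi, float)
    c1, c2 = cutpoints
    idx = (pi > c1).astype(int) + (pi > c2).astype(int)
    return np.asarray(GROUP_LABELS, dtype=object)[idx]


def derive_groups(
    training_pi: np.ndarray,
    test_pi: np.ndarray | None = None,
    cutpoints: tuple[float, float] | None = None,
) -> RiskGrouping | tuple[RiskGrouping, RiskGrouping]:
    """Tertile grouping of the training index; optionally reuse the same
    cutpoints on a test index.  Externally supplied ``cutpoints`` (e.g. a
    published pair) override the empirical tertiles."""
    cuts = cutpoints if cutpoints is not None else _cutpoints(training_pi)
    train = RiskGrouping(cutpoints=cuts, groups=assign_groups(training_pi, cuts))
    if test_pi is None:
        return train
    test = RiskGrouping(cutpoints=cuts, groups=assign_groups(test_pi, cuts))
    return train, test


def km_by_group(
    grouping: RiskGrouping,
    time: np.ndarray,
    event: np.ndarray,
    conf_level: float = 0.95,
) -> "dict[str, pd.DataFrame]":
    """Product-limit survival curve per risk group with Greenwood CIs.

    Returns one table per group: (time, at_risk, events, survival, ci)."""
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(int)
    out = {}
    for lab in GROUP_LABELS:
        sel = grouping.groups == lab
        if sel.sum() == 0:
            raise ValueError(f"empty risk group {lab!r}")
        kmf = KaplanMeierFitter(alpha=1 - conf_level)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmf.fit(t[sel], e[sel])
        tab = kmf.event_table.copy()
        sf = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_survival_function_
        out[lab] = pd.DataFrame({
            "time": tab.index.to_numpy(float),
            "at_risk": tab["at_risk"].to_numpy(int),
            "events": tab["observed"].to_numpy(int),
            "survival": sf.to_numpy(float),
            "ci_low": ci.iloc[:, 0].to_numpy(float),
            "ci_high": ci.iloc[:, 1].to_numpy(float),
        })
    return out


def plot_km(curves: "dict[str, pd.DataFrame]", path) -> None:
    """Stacked KM step curves per risk group with CI bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for lab in GROUP_LABELS:
        if lab not in curves:
            continue
        tab = curves[lab]
        ax.step(tab["time"], tab["survival"], where="post", label=lab)
        ax.fill_between(tab["time"], tab["ci_low"], tab["ci_high"],
                        step="post", alpha=0.15)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(title="risk group")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
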