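"""Data model, CSV/config I/O and missing-data-pattern summaries.

A :class:`TrialDataset` is a subject-level survival table: one row per
subject with a strictly positive survival time (months), a binary event
indicator (1 = death, 0 = censored) and a set of typed covariates
(continuous or ordinal) of which only the *predictor* columns may contain
missing values.  The schema is a collection of :class:`VariableSpec`
entries declaring the type, transform and role of every column.

:func:`summarize_missingness` computes the multi-variable missing-data
pattern table (which subsets of predictors are jointly missing, with
counts and percentages) that drives the choice of the number of imputed
datasets downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "Schema",
    "TrialDataset",
    "MissingPatternSummary",
    "DataValidationError",
    "read_dataset",
    "write_dataset",
    "summarize_missingness",
    "count_eligible_complete_cases",
    "dataset_from_pattern_counts",
]

KINDS = ("continuous", "ordinal")
TRANSFORMS = ("none", "log", "log1p")
ROLES = ("predictor", "auxiliary", "outcome_time", "outcome_event", "treatment", "id")

DEFAULT_NA_VALUES = ("", "NA")


class DataValidationError(ValueError):
    """Raised when a dataset or schema violates its declared contract."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as the conventional table percentages do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single dataset column."""

    name: str
    kind: str = "continuous"
    role: str = "predictor"
    transform: str = "none"
    levels: tuple[str, ...] | None = None
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DataValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.role not in ROLES:
            raise DataValidationError(f"{self.name}: unknown role {self.role!r}")
        if self.transform not in TRANSFORMS:
            raise DataValidationError(f"{self.name}: unknown transform {self.transform!r}")
        if self.kind == "ordinal":
            if self.levels is None or len(self.levels) < 2:
                raise DataValidationError(f"{self.name}: ordinal variables need >=2 levels")
            if self.transform != "none":
                raise DataValidationError(f"{self.name}: transforms apply to continuous variables only")
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))

    @property
    def n_levels(self) -> int:
        return 0 if self.levels is None else len(self.levels)


class Schema:
    """Ordered collection of :class:`VariableSpec` with role lookups."""

    def __init__(self, variables: Iterable[VariableSpec]):
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise DataValidationError("duplicate variable names in schema")
        for role in ("outcome_time", "outcome_event"):
            if sum(v.role == role for v in self.variables) != 1:
                raise DataValidationError(f"schema needs exactly one {role} variable")
        self._by_name = {v.name: v for v in self.variables}

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown variable name {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def predictors(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.role == "predictor"]

    @property
    def predictor_names(self) -> list[str]:
        return [v.name for v in self.predictors]

    @property
    def auxiliaries(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.role == "auxiliary"]

    @property
    def time_var(self) -> str:
        return next(v.name for v in self.variables if v.role == "outcome_time")

    @property
    def event_var(self) -> str:
        return next(v.name for v in self.variables if v.role == "outcome_event")

    @property
    def id_var(self) -> str | None:
        return next((v.name for v in self.variables if v.role == "id"), None)

    # -- configuration file round trip -------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Schema":
        specs = []
        for entry in doc["variables"]:
            entry = dict(entry)
            if "levels" in entry and entry["levels"] is not None:
                entry["levels"] = tuple(str(v) for v in entry["levels"])
            specs.append(VariableSpec(**entry))
        return cls(specs)

    def to_dict(self) -> dict:
        out = []
        for v in self.variables:
            d = {"name": v.name, "kind": v.kind, "role": v.role}
            if v.transform != "none":
                d["transform"] = v.transform
            if v.levels is not None:
                d["levels"] = list(v.levels)
            if v.standardize:
                d["standardize"] = True
            out.append(d)
        return {"variables": out}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class TrialDataset:
    """Subject-level survival table with typed covariates.

    Ordinal columns are stored as float level codes (0-based, ``NaN`` for
    missing); the schema retains the label <-> code mapping for I/O.
    """

    schema: Schema
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ----------------------------------------------------------
    def validate(self) -> None:
        df, schema = self.df, self.schema
        missing_cols = [n for n in schema.names if n not in df.columns]
        if missing_cols:
            raise DataValidationError(f"missing required column(s): {missing_cols}")
        if len(df) < 1:
            raise DataValidationError("dataset must contain at least one row")
        t = df[schema.time_var].to_numpy(float)
        if np.isnan(t).any() or (t <= 0).any():
            raise DataValidationError("non-positive or missing survival time")
        e = df[schema.event_var].to_numpy(float)
        if not np.isin(e, (0.0, 1.0)).all():
            raise DataValidationError("non-binary event indicator")
        predictor = set(schema.predictor_names)
        for v in schema.variables:
            if v.role in ("outcome_time", "outcome_event", "id"):
                continue
            if v.name not in predictor and df[v.name].isna().any():
                raise DataValidationError(
                    f"missing values only allowed in predictors, found in {v.name!r}"
                )
            if v.kind == "ordinal":
                vals = df[v.name].dropna().to_numpy(float)
                if len(vals) and not np.isin(vals, np.arange(v.n_levels)).all():
                    raise DataValidationError(f"{v.name}: ordinal code outside declared levels")

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def time(self) -> np.ndarray:
        return self.df[self.schema.time_var].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.df[self.schema.event_var].to_numpy(float).astype(int)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missingness over the predictor columns."""
        return self.df[self.schema.predictor_names].isna()

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.schema, self.df.copy())

    def with_df(self, df: pd.DataFrame) -> "TrialDataset":
        return TrialDataset(self.schema, df)


@dataclass
class MissingPatternSummary:
    """Missing-data pattern table: which predictor subsets are jointly missing.

    ``patterns`` maps a frozenset of missing-variable names (empty set =
    complete cases) to ``(count, percent)``; entries are ordered by
    descending count, ties broken lexicographically.  Percentages are
    rounded half-up to two decimals, as in conventional trial reports.
    """

    n: int
    patterns: "dict[frozenset, tuple[int, float]]"
    per_variable: "dict[str, tuple[int, float]]"

    @property
    def complete_count(self) -> int:
        return self.patterns.get(frozenset(), (0, 0.0))[0]

    @property
    def complete_percent(self) -> float:
        return self.patterns.get(frozenset(), (0, 0.0))[1]

    @property
    def incomplete_percent(self) -> float:
        return round_half_up(100.0 * (self.n - self.complete_count) / self.n)

    @property
    def max_variable_percent(self) -> float:
        if not self.per_variable:
            return 0.0
        return max(pct for _, pct in self.per_variable.values())

    def to_tsv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        buf.write("pattern\tcount\tpercent\n")
        for pat, (count, pct) in self.patterns.items():
            label = "complete cases" if not pat else " and ".join(sorted(pat))
            buf.write(f"{label}\t{count}\t{pct:.2f}\n")
        for var, (count, pct) in sorted(self.per_variable.items()):
            buf.write(f"[total] {var}\t{count}\t{pct:.2f}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def _pattern_sort_key(item):
    pat, count = item
    return (-count, " and ".join(sorted(pat)))


def summarize_missingness(data: TrialDataset) -> MissingPatternSummary:
    """Tabulate multi-variable missing-data patterns over the predictors.

    Every row belongs to exactly one pattern, so pattern counts partition
    ``n``; the per-variable missing total equals the sum of the counts of
    all patterns containing that variable.
    """
    mask = data.missing_mask()
    n = data.n
    counts: dict[frozenset, int] = {}
    cols = np.asarray(mask.columns)
    arr = mask.to_numpy(bool)
    for row in arr:
        pat = frozenset(cols[row])
        counts[pat] = counts.get(pat, 0) + 1
    counts.setdefault(frozenset(), 0)
    patterns = {
        pat: (c, round_half_up(100.0 * c / n))
        for pat, c in sorted(counts.items(), key=_pattern_sort_key)
    }
    per_variable = {}
    for j, var in enumerate(cols):
        c = int(arr[:, j].sum())
        per_variable[var] = (c, round_half_up(100.0 * c / n))
    return MissingPatternSummary(n=n, patterns=patterns, per_variable=per_variable)


def count_eligible_complete_cases(data: TrialDataset, required_vars: Iterable[str]) -> int:
    """Number of subjects with no missing value among ``required_vars``."""
    required = list(required_vars)
    predictors = set(data.schema.predictor_names)
    unknown = [v for v in required if v not in predictors]
    if unknown:
        raise KeyError(f"unknown variable name(s): {unknown}")
    if not required:
        return data.n
    return int((~data.df[required].isna().any(axis=1)).sum())


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_column(raw: pd.Series, spec: VariableSpec, na_values: Sequence[str]) -> pd.Series:
    stripped = raw.astype(str).str.strip()
    is_na = stripped.isin(list(na_values))
    if spec.kind == "ordinal" and spec.role not in ("outcome_time", "outcome_event", "id"):
        mapping = {lab: float(code) for code, lab in enumerate(spec.levels)}
        out = pd.Series(np.nan, index=raw.index, dtype=float)
        obs = ~is_na
        unknown = sorted(set(stripped[obs]) - set(mapping))
        if unknown:
            raise DataValidationError(
                f"{spec.name}: ordinal label(s) {unknown} not in declared levels {list(spec.levels)}"
            )
        out[obs] = stripped[obs].map(mapping)
        return out
    out = pd.Series(np.nan, index=raw.index, dtype=float)
    obs = ~is_na
    try:
        out[obs] = stripped[obs].astype(float)
    except ValueError as exc:
        raise DataValidationError(f"{spec.name}: non-numeric value ({exc})") from None
    return out


def read_dataset(
    path: str | Path,
    schema: Schema,
    na_values: Sequence[str] = DEFAULT_NA_VALUES,
) -> TrialDataset:
    """Read a header-ed CSV into a typed :class:`TrialDataset`.

    Missing cells must be encoded as one of ``na_values`` (empty string and
    ``"NA"`` by default).  Ordinal labels are mapped onto their declared
    level order; malformed rows raise :class:`DataValidationError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [n for n in schema.names if n not in raw.columns]
    if missing_cols:
        raise DataValidationError(f"missing required column(s): {missing_cols}")
    out = pd.DataFrame(index=raw.index)
    for spec in schema:
        if spec.role == "id":
            out[spec.name] = raw[spec.name].astype(str)
            continue
        out[spec.name] = _parse_column(raw[spec.name], spec, na_values)
    return TrialDataset(schema, out)


def write_dataset(data: TrialDataset, path: str | Path) -> None:
    """Write a :class:`TrialDataset` back to CSV (missing cells as empty)."""
    df = data.df.copy()
    for spec in data.schema:
        if spec.kind == "ordinal" and spec.role not in ("outcome_time", "outcome_event"):
            col = df[spec.name]
            labels = np.asarray(spec.levels, dtype=object)
            obs = ~col.isna()
            out = pd.Series("", index=col.index, dtype=object)
            out[obs] = labels[col[obs].astype(int).to_numpy()]
            df[spec.name] = out
    df.to_csv(path, index=False, na_rep="")


def dataset_from_pattern_counts(
    schema: Schema,
    pattern_counts: Mapping[Sequence[str] | frozenset, int],
) -> TrialDataset:
    """Reconstruct a skeleton dataset from a printed pattern-count table.

    Each entry maps a collection of jointly missing predictor names (the
    empty collection = complete cases) to its row count.  Observed cells
    are filled with placeholder values; only the missingness structure is
    meaningful, which is all the pattern/eligibility computations need.
    """
    rows = []
    predictors = schema.predictor_names
    for pat, count in pattern_counts.items():
        pat = frozenset(pat)
        unknown = pat - set(predictors)
        if unknown:
            raise KeyError(f"unknown variable name(s) in pattern: {sorted(unknown)}")
        base = {}
        for spec in schema:
            if spec.role == "outcome_time":
                base[spec.name] = 1.0
            elif spec.role == "outcome_event":
                base[spec.name] = 0.0
            elif spec.role == "id":
                base[spec.name] = ""
            elif spec.name in pat:
                base[spec.name] = np.nan
            else:
                base[spec.name] = 0.0 if spec.kind == "ordinal" else 1.0
        rows.extend([dict(base)] * int(count))
    df = pd.DataFrame(rows).reset_index(drop=True)
    return TrialDataset(schema, df)
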