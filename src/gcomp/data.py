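"""Unit-level data container, validation, and positivity diagnostics.

The package works on a rectangular table with one binary treatment column
(1 = index level, 0 = reference level), one binary outcome column, and one
or more covariate columns (numeric or categorical).  :func:`validate` turns
such a table plus an explicit column-role mapping into an
:class:`ObservedData`, the canonical in-memory form every estimator
consumes.  :func:`check_positivity` cross-classifies the covariates
(quantile-binning continuous ones) and flags strata in which one treatment
arm is empty — the empirical footprint of a positivity violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = ["ColumnRoles", "ObservedData", "PositivityReport", "validate", "check_positivity"]


@dataclass(frozen=True)
class ColumnRoles:
    """Explicit mapping from table columns to analysis roles.

    Level mappings are never inferred: if the treatment or outcome column is
    not already coded 0/1, the caller must say which label is the index
    level (coded 1) and which is the reference (coded 0).
    """

    treatment: str
    outcome: str
    covariates: tuple[str, ...]
    treatment_levels: Mapping[Any, int] | None = None
    outcome_levels: Mapping[Any, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if len(self.covariates) == 0:
            raise ConfigurationError("at least one covariate column is required")
        names = [self.treatment, self.outcome, *self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"column roles overlap: {names}")


@dataclass(frozen=True)
class ObservedData:
    """Validated unit-level data: treatment A, outcome Y, covariates C.

    ``treatment`` and ``outcome`` are int arrays in {0, 1}; ``covariates``
    is a DataFrame whose rows align positionally with them.  ``unit_id``
    values are unique.
    """

    treatment: np.ndarray
    outcome: np.ndarray
    covariates: pd.DataFrame
    unit_id: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.treatment)
        y = np.asarray(self.outcome)
        if a.ndim != 1 or y.ndim != 1 or len(a) != len(y) or len(a) != len(self.covariates):
            raise DataError("treatment, outcome and covariates must have equal length")
        if len(a) == 0:
            raise DataError("empty dataset")
        for name, col in (("treatment", a), ("outcome", y)):
            bad = ~np.isin(col, (0, 1))
            if bad.any():
                raise DataError(
                    f"{name} takes values outside {{0,1}} at rows {np.flatnonzero(bad)[:5].tolist()}"
                )
        if a.sum() == 0:
            raise DataError("no treated units (treatment = 1) in the data")
        if a.sum() == len(a):
            raise DataError("no untreated units (treatment = 0) in the data")
        uid = np.asarray(self.unit_id)
        if len(np.unique(uid)) != len(uid):
            raise DataError("unit_id values are not unique")
        if self.covariates.isna().any().any():
            raise DataError("covariates contain missing values")
        object.__setattr__(self, "treatment", a.astype(np.int8))
        object.__setattr__(self, "outcome", y.astype(np.int8))
        object.__setattr__(self, "unit_id", uid)

    @property
    def n_units(self) -> int:
        return len(self.treatment)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.covariates.columns)

    @property
    def n_treated(self) -> int:
        return int(self.treatment.sum())

    @property
    def treated_fraction(self) -> float:
        return self.n_treated / self.n_units

    def to_frame(self, treatment: str = "treatment", outcome: str = "outcome") -> pd.DataFrame:
        """Rectangular table with unit_id index, treatment, outcome, covariates."""
        df = self.covariates.copy()
        df.insert(0, outcome, self.outcome)
        df.insert(0, treatment, self.treatment)
        df.index = pd.Index(self.unit_id, name="unit_id")
        return df

    def take(self, indices: np.ndarray) -> "ObservedData":
        """Positional row subset/resample with fresh unique unit ids.

        Used by bootstrap resampling, where source rows repeat.
        """
        idx = np.asarray(indices)
        return ObservedData(
            treatment=self.treatment[idx],
            outcome=self.outcome[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            unit_id=np.arange(len(idx)),
        )

    def equals(self, other: "ObservedData") -> bool:
        return (
            np.array_equal(self.treatment, other.treatment)
            and np.array_equal(self.outcome, other.outcome)
            and np.array_equal(self.unit_id, other.unit_id)
            and self.covariates.reset_index(drop=True).equals(
                other.covariates.reset_index(drop=True)
            )
        )


def validate(table: pd.DataFrame, roles: ColumnRoles) -> ObservedData:
    """Validate a raw table against a column-role mapping.

    Raises
    ------
    ConfigurationError
        If a named column is absent from the table.
    DataError
        On missing values (naming the first offending row and column), on
        non-binary treatment/outcome after level recoding, or if either
        treatment arm is empty.  Complete-case filtering is deliberately the
        caller's responsibility.
    """
    for col in (roles.treatment, roles.outcome, *roles.covariates):
        if col not in table.columns:
            raise ConfigurationError(
                f"column {col!r} not found in table (have: {list(table.columns)})"
            )
    used = [roles.treatment, roles.outcome, *roles.covariates]
    sub = table[used]
    na = sub.isna()
    if na.any().any():
        col = next(c for c in used if na[c].any())
        row = na[col].idxmax()
        raise DataError(f"missing value in column {col!r} at row {row!r}")

    def recode(series: pd.Series, mapping: Mapping[Any, int] | None, what: str) -> np.ndarray:
        if mapping is not None:
            unknown = set(series.unique()) - set(mapping)
            if unknown:
                raise DataError(f"{what} column has unmapped levels {sorted(map(str, unknown))}")
            series = series.map(dict(mapping))
        vals = series.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = sorted({v for v in vals if v not in (0, 1)}, key=str)
            raise DataError(f"{what} column is not binary after recoding; saw {bad[:5]}")
        return vals.astype(np.int8)

    a = recode(sub[roles.treatment], roles.treatment_levels, "treatment")
    y = recode(sub[roles.outcome], roles.outcome_levels, "outcome")
    return ObservedData(
        treatment=a,
        outcome=y,
        covariates=sub[list(roles.covariates)].reset_index(drop=True),
        unit_id=np.arange(len(table)),
    )


@dataclass(frozen=True)
class PositivityReport:
    """Per-stratum treatment-arm counts after cross-classifying covariates.

    ``strata`` has one row per non-empty stratum: the (discretized)
    covariate pattern, ``n_treated`` and ``n_untreated``.  ``flagged`` lists
    the patterns with zero units in one arm — strata where the data carry no
    information about one of the two interventions.
    """

    strata: pd.DataFrame
    flagged: tuple[tuple, ...]
    bins_per_continuous: int
    binned_covariates: tuple[str, ...]
    n_units: int

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    @property
    def ok(self) -> bool:
        return not self.flagged

    def summary(self) -> str:
        lines = [
            f"{len(self.strata)} covariate strata over {self.n_units} units "
            f"(continuous covariates {self.binned_covariates or '(none)'} in "
            f"{self.bins_per_continuous} quantile bins)"
        ]
        if self.flagged:
            lines.append(f"{len(self.flagged)} strata with an empty treatment arm:")
            for pat in self.flagged:
                lines.append(f"  {pat}")
        else:
            lines.append("all strata contain both treated and untreated units")
        return "\n".join(lines)


def _discretize(covariates: pd.DataFrame, bins: int) -> tuple[pd.DataFrame, tuple[str, ...]]:
    out = {}
    binned = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > bins:
            cut = pd.qcut(col, q=bins, duplicates="drop")
            out[name] = cut.astype(str)
            binned.append(name)
        else:
            out[name] = col.astype(str)
    return pd.DataFrame(out), tuple(binned)


def check_positivity(data: ObservedData, bins_per_continuous_covariate: int = 5) -> PositivityReport:
    """Cross-classify covariates and count treated/untreated units per stratum.

    Continuous covariates (numeric, with more distinct values than bins) are
    discretized into quantile bins — quintiles by default — for this
    diagnostic only; the estimators use them unbinned.  The healthy outcome
    is an empty ``flagged`` list.
    """
    bins = int(bins_per_continuous_covariate)
    if bins < 2:
        raise ConfigurationError("bins_per_continuous_covariate must be >= 2")
    disc, binned = _discretize(data.covariates, bins)
    disc = disc.copy()
    disc["__arm__"] = data.treatment
    counts = (
        disc.groupby(list(data.covariate_names), observed=True, sort=True)["__arm__"]
        .agg(n_treated="sum", size="count")
        .reset_index()
    )
    counts["n_untreated"] = counts["size"] - counts["n_treated"]
    counts = counts.drop(columns="size")
    flagged = tuple(
        tuple(row[c] for c in data.covariate_names)
        for _, row in counts.iterrows()
        if row["n_treated"] == 0 or row["n_untreated"] == 0
    )
    return PositivityReport(
        strata=counts,
        flagged=flagged,
        bins_per_continuous=bins,
        binned_covariates=binned,
        n_units=data.n_units,
    )
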