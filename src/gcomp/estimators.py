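"""G-computation estimators for ATE, ATT and ATU with a binary outcome.

The algorithm has three steps:

1. Fit a flexible logistic outcome model E(Y | A, C) — by default with all
   2- and 3-way treatment-by-covariate product terms — and keep the
   coefficients.
2. Resample the data with replacement K times into a pooled dataset, stack
   two copies of it, set the intervention to the index level (A = 1) in one
   copy and the reference level (A = 0) in the other, and fill in potential
   outcomes: the observed outcome where the intervention matches the
   treatment actually received (consistency), a Bernoulli draw at the
   model-predicted probability where it does not (conditional
   exchangeability).
3. Contrast the two arms' potential-outcome means — a risk difference, or
   an odds ratio of the two marginal risks.

For ATT the potential outcomes are defined for the treated units only; for
ATU, for the untreated only; for ATE, for everyone.

Two deterministic variants are also provided: a plug-in *standardization*
estimate that averages model predictions instead of simulating
(:func:`standardization_estimate`, the default method because it carries no
Monte Carlo noise), and a *restriction* estimate that computes the
ATE-style contrast over the treated (or untreated) subgroup only
(:func:`restriction_estimate`).  :func:`nonparametric_standardization`
evaluates the standardization formulas directly from empirical cell means,
with no model at all — for discrete covariates and a saturated model
specification it is the exact oracle the parametric routes must match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .data import ObservedData, check_positivity
from .exceptions import (
    ConfigurationError,
    DataError,
    DegenerateOddsError,
    EstimationError,
    FitError,
    PositivityError,
    SeparationError,
)

__all__ = [
    "TREATMENT",
    "ESTIMANDS",
    "SCALES",
    "METHODS",
    "OutcomeModelSpec",
    "FittedOutcomeModel",
    "CounterfactualStack",
    "EstimandRequest",
    "fit_outcome_model",
    "build_counterfactual_stack",
    "assign_potential_outcomes",
    "marginal_contrast",
    "standardization_estimate",
    "restriction_estimate",
    "nonparametric_standardization",
    "gcompute",
]

#: Symbol standing for the treatment variable in model-term tuples.
TREATMENT = "A"

ESTIMANDS = ("ATE", "ATT", "ATU")
SCALES = ("RD", "OR")
METHODS = ("standardization", "simulation", "restriction")

_RESERVED = (TREATMENT, "_Y_")


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


def _normalize_term(term: Iterable[str]) -> tuple[str, ...]:
    parts = list(dict.fromkeys(term))  # dedupe, keep order
    parts.sort(key=lambda p: (p != TREATMENT, p))  # treatment first, covariates alphabetical
    return tuple(parts)


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Terms of the logistic outcome model for Y on A and C.

    The treatment main effect and every covariate main effect are always
    included; ``product_terms`` lists the extra product terms, each a tuple
    of variable names in which :data:`TREATMENT` (``"A"``) denotes the
    treatment.  The default specification carries all treatment-by-covariate
    2-way products and all treatment-by-covariate-by-covariate 3-way
    products, but no covariate-covariate products without the treatment.

    ``reference_levels`` optionally pins the reference level of a
    categorical covariate; otherwise the most frequent level is used.
    Standardized (prediction-based) estimands are invariant to this choice;
    fixing it keeps coefficient vectors reproducible.
    """

    product_terms: tuple[tuple[str, ...], ...] = ()
    reference_levels: Mapping[str, Any] | None = None
    categorical: tuple[str, ...] | None = None  # force-categorical covariates; None = by dtype

    def __post_init__(self):
        terms = tuple(_normalize_term(t) for t in self.product_terms)
        if len(set(terms)) != len(terms):
            dupes = [t for t in terms if terms.count(t) > 1]
            raise ConfigurationError(f"duplicate model terms: {sorted(set(dupes))}")
        for t in terms:
            if len(t) < 2:
                raise ConfigurationError(f"product term {t} needs at least two variables")
        object.__setattr__(self, "product_terms", terms)
        if self.categorical is not None:
            object.__setattr__(self, "categorical", tuple(self.categorical))

    @classmethod
    def default(cls, covariate_names: Sequence[str], **kw) -> "OutcomeModelSpec":
        """All A:C_i and A:C_i:C_j products (the package default)."""
        covs = list(covariate_names)
        terms = [(TREATMENT, c) for c in covs]
        terms += [
            (TREATMENT, covs[i], covs[j])
            for i in range(len(covs))
            for j in range(i + 1, len(covs))
        ]
        return cls(product_terms=tuple(terms), **kw)

    @classmethod
    def saturated(cls, covariate_names: Sequence[str], **kw) -> "OutcomeModelSpec":
        """Full factorial in A and all covariates (every product of >= 2 variables)."""
        from itertools import combinations

        names = [TREATMENT, *covariate_names]
        terms = [
            combo for r in range(2, len(names) + 1) for combo in combinations(names, r)
        ]
        return cls(product_terms=tuple(terms), **kw)

    @classmethod
    def main_effects_only(cls, **kw) -> "OutcomeModelSpec":
        return cls(product_terms=(), **kw)

    # -- formula construction -------------------------------------------

    def _is_categorical(self, name: str, col: pd.Series) -> bool:
        if self.categorical is not None:
            return name in self.categorical
        return not pd.api.types.is_numeric_dtype(col)

    def _cov_expr(self, name: str, col: pd.Series) -> str:
        if self._is_categorical(name, col):
            if self.reference_levels and name in self.reference_levels:
                ref = self.reference_levels[name]
            else:
                counts = col.value_counts()
                top = counts.max()
                ref = sorted(str(v) for v, c in counts.items() if c == top)[0]
            return f"C(Q({name!r}), Treatment(reference={str(ref)!r}))"
        return f"Q({name!r})"

    def formula(self, data: ObservedData) -> str:
        """Patsy formula for this specification against a concrete dataset."""
        covs = data.covariate_names
        for bad in _RESERVED:
            if bad in covs:
                raise ConfigurationError(
                    f"covariate name {bad!r} is reserved for internal use; rename the column"
                )
        exprs = {c: self._cov_expr(c, data.covariates[c]) for c in covs}
        exprs[TREATMENT] = TREATMENT
        for term in self.product_terms:
            for v in term:
                if v not in exprs:
                    raise ConfigurationError(
                        f"model term {term} references unknown variable {v!r} "
                        f"(covariates: {list(covs)})"
                    )
        rhs = [TREATMENT] + [exprs[c] for c in covs]
        rhs += [":".join(exprs[v] for v in term) for term in self.product_terms]
        return "_Y_ ~ " + " + ".join(rhs)


# ---------------------------------------------------------------------------
# design matrices and the fitted model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _DesignSet:
    """Design matrices for one dataset under observed, index and reference treatment."""

    y: np.ndarray
    a: np.ndarray
    X: np.ndarray  # at observed treatment
    X1: np.ndarray  # treatment set to 1 for everyone
    X0: np.ndarray  # treatment set to 0 for everyone
    column_names: tuple[str, ...]
    design_info: Any
    formula: str

    @property
    def n(self) -> int:
        return len(self.y)

    def rows(self, idx: np.ndarray) -> "_DesignSet":
        """Row subset/resample; the design columns stay fixed."""
        return _DesignSet(
            y=self.y[idx],
            a=self.a[idx],
            X=self.X[idx],
            X1=self.X1[idx],
            X0=self.X0[idx],
            column_names=self.column_names,
            design_info=self.design_info,
            formula=self.formula,
        )


def _frame_for_design(data: ObservedData) -> pd.DataFrame:
    df = data.covariates.copy()
    df[TREATMENT] = data.treatment.astype(float)
    df["_Y_"] = data.outcome.astype(float)
    return df


def build_design(data: ObservedData, spec: OutcomeModelSpec) -> _DesignSet:
    """Materialize y, A and the three design matrices for ``spec`` on ``data``."""
    df = _frame_for_design(data)
    formula = spec.formula(data)
    ymat, X = patsy.dmatrices(formula, df, return_type="dataframe", NA_action="raise")
    di = X.design_info
    df1 = df.copy()
    df1[TREATMENT] = 1.0
    df0 = df.copy()
    df0[TREATMENT] = 0.0
    X1 = np.asarray(patsy.build_design_matrices([di], df1)[0])
    X0 = np.asarray(patsy.build_design_matrices([di], df0)[0])
    return _DesignSet(
        y=np.asarray(ymat).ravel(),
        a=data.treatment.astype(float),
        X=np.asarray(X),
        X1=X1,
        X0=X0,
        column_names=tuple(X.columns),
        design_info=di,
        formula=formula,
    )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dependent = tuple(names[i] for i in sorted(piv[rank:]))
        raise FitError(
            f"rank-deficient design: columns {list(dependent)} are collinear with the rest",
            columns=dependent,
        )


def _fit_params(
    y: np.ndarray, X: np.ndarray, names: Sequence[str], check_rank: bool = True
) -> tuple[np.ndarray, Any]:
    """Maximum-likelihood logistic fit; raises on separation or non-convergence."""
    if check_rank:
        _check_rank(X, names)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always", PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
        except PerfectSeparationError as exc:  # older statsmodels raises
            raise SeparationError(str(exc)) from exc
    if any(issubclass(w.category, PerfectSeparationWarning) for w in rec):
        big = np.abs(res.params) > 10
        cols = tuple(n for n, b in zip(names, big) if b)
        raise SeparationError(
            "complete or quasi-complete separation detected; the logistic MLE "
            f"does not exist (extreme coefficients: {list(cols) or list(names)})",
            columns=cols,
        )
    if not res.converged or not np.isfinite(res.params).all():
        raise FitError("logistic fit did not converge")
    return np.asarray(res.params), res


@dataclass(frozen=True)
class FittedOutcomeModel:
    """Fitted step-1 logistic model: coefficients plus a prediction contract.

    ``predict(covariates, treatment_value)`` returns E(Y | A = value, C) as
    the inverse-logit of the linear predictor, strictly inside (0, 1).
    """

    params: np.ndarray
    column_names: tuple[str, ...]
    design_info: Any
    converged: bool
    n_iter: int
    llf: float
    spec: OutcomeModelSpec

    def linear_predictor(self, covariates: pd.DataFrame, treatment_value: int) -> np.ndarray:
        df = covariates.copy()
        df[TREATMENT] = float(treatment_value)
        X = np.asarray(patsy.build_design_matrices([self.design_info], df)[0])
        return X @ self.params

    def predict(self, covariates: pd.DataFrame, treatment_value: int) -> np.ndarray:
        """Predicted outcome probability with treatment set to ``treatment_value``."""
        return expit(self.linear_predictor(covariates, treatment_value))

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.params, index=list(self.column_names))


def fit_outcome_model(data: ObservedData, spec: OutcomeModelSpec) -> FittedOutcomeModel:
    """Step 1: fit the flexible logistic outcome model and keep the coefficients.

    Raises
    ------
    FitError
        On a rank-deficient design (naming the collinear columns) or
        non-convergence.
    SeparationError
        When the MLE does not exist because a design column separates the
        outcome.
    """
    ds = build_design(data, spec)
    params, res = _fit_params(ds.y, ds.X, ds.column_names)
    return FittedOutcomeModel(
        params=params,
        column_names=ds.column_names,
        design_info=ds.design_info,
        converged=bool(res.converged),
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        llf=float(res.llf),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# the counterfactual stack (step 2)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CounterfactualStack:
    """Two-arm stacked Monte Carlo resample with potential-outcome columns.

    The pooled resample has ``K * n_source`` rows; each row appears once in
    the index arm (intervention A = 1, column ``po_index``) and once in the
    reference arm (A = 0, ``po_reference``), so the stack conceptually holds
    ``2 * K * n_source`` rows.  Potential-outcome entries are NaN where the
    estimand leaves them undefined (e.g. untreated units under ATT).
    """

    estimand: str
    k: int
    n_source: int
    source_index: np.ndarray  # positions into the source data
    unit_id: np.ndarray
    replicate: np.ndarray  # 1..K
    covariates: pd.DataFrame
    observed_treatment: np.ndarray
    observed_outcome: np.ndarray
    po_index: np.ndarray  # potential outcome under intervention A = 1 (float, NaN = undefined)
    po_reference: np.ndarray  # under intervention A = 0

    @property
    def n_pooled(self) -> int:
        return len(self.source_index)

    @property
    def n_rows(self) -> int:
        """Total stacked rows across the two intervention copies."""
        return 2 * self.n_pooled

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (pooled row, intervention arm)."""
        base = self.covariates.copy()
        base["unit_id"] = self.unit_id
        base["replicate"] = self.replicate
        base["observed_treatment"] = self.observed_treatment
        base["observed_outcome"] = self.observed_outcome
        top = base.copy()
        top["intervention"] = 1
        top["potential_outcome"] = self.po_index
        bot = base.copy()
        bot["intervention"] = 0
        bot["potential_outcome"] = self.po_reference
        return pd.concat([top, bot], ignore_index=True)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_counterfactual_stack(
    data: ObservedData, estimand: str, K: int, seed
) -> CounterfactualStack:
    """Step 2a: resample with replacement K times, stack two intervention copies.

    ``seed`` may be an integer, a ``SeedSequence`` or an existing
    ``numpy.random.Generator`` (which is then advanced in place — this is
    how :func:`gcompute` chains the resampling and the counterfactual draws
    on one stream).
    """
    if estimand not in ESTIMANDS:
        raise ConfigurationError(f"unknown estimand {estimand!r}; expected one of {ESTIMANDS}")
    K = int(K)
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    rng = _as_rng(seed)
    n = data.n_units
    idx = rng.integers(0, n, size=K * n)
    nan = np.full(K * n, np.nan)
    return CounterfactualStack(
        estimand=estimand,
        k=K,
        n_source=n,
        source_index=idx,
        unit_id=data.unit_id[idx],
        replicate=np.repeat(np.arange(1, K + 1), n),
        covariates=data.covariates.iloc[idx].reset_index(drop=True),
        observed_treatment=data.treatment[idx],
        observed_outcome=data.outcome[idx],
        po_index=nan.copy(),
        po_reference=nan.copy(),
    )


def _fill_potential_outcomes(
    estimand: str,
    a_obs: np.ndarray,
    y_obs: np.ndarray,
    p1: np.ndarray,
    p0: np.ndarray,
    rng: np.random.Generator,
    ate_mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill the two arm columns; Bernoulli draws consume ``rng`` in (arm, row) order."""
    n = len(a_obs)
    po1 = np.full(n, np.nan)
    po0 = np.full(n, np.nan)
    treated = a_obs == 1
    if estimand == "ATT":
        # index arm: observed outcome by consistency; reference arm: simulated
        po1[treated] = y_obs[treated]
        po0[treated] = rng.binomial(1, p0[treated])
    elif estimand == "ATU":
        # index arm: simulated; reference arm: observed outcome by consistency
        po1[~treated] = rng.binomial(1, p1[~treated])
        po0[~treated] = y_obs[~treated]
    elif estimand == "ATE":
        if ate_mode == "simulate":
            po1[:] = rng.binomial(1, p1)
            po0[:] = rng.binomial(1, p0)
        elif ate_mode == "consistency":
            po1[treated] = y_obs[treated]
            po1[~treated] = rng.binomial(1, p1[~treated])
            po0[treated] = rng.binomial(1, p0[treated])
            po0[~treated] = y_obs[~treated]
        else:
            raise ConfigurationError(f"unknown ATE mode {ate_mode!r}")
    else:
        raise ConfigurationError(f"unknown estimand {estimand!r}")
    return po1, po0


def assign_potential_outcomes(
    stack: CounterfactualStack,
    model: FittedOutcomeModel,
    seed,
    ate_mode: str = "simulate",
) -> CounterfactualStack:
    """Step 2b: fill potential outcomes from the fitted model.

    Where the intervention arm matches the treatment a unit actually
    received, the potential outcome is the observed outcome (consistency) —
    copied exactly, no randomness.  Where it does not, the counterfactual is
    a Bernoulli draw at the model-predicted probability for that arm
    (conditional exchangeability).  For ATT only treated units get defined
    potential outcomes; for ATU only untreated; for ATE everyone.  The
    default ATE mode simulates both arms from the model; ``ate_mode =
    "consistency"`` keeps the observed outcome in the factual arm instead —
    both converge to the same standardized contrast.
    """
    if not model.converged:
        raise FitError("cannot assign potential outcomes from an unconverged model")
    rng = _as_rng(seed)
    p1 = model.predict(stack.covariates, 1)
    p0 = model.predict(stack.covariates, 0)
    po1, po0 = _fill_potential_outcomes(
        stack.estimand,
        stack.observed_treatment,
        stack.observed_outcome,
        p1,
        p0,
        rng,
        ate_mode,
    )
    return replace(stack, po_index=po1, po_reference=po0)


# ---------------------------------------------------------------------------
# contrasts (step 3) and scale handling
# ---------------------------------------------------------------------------


def _contrast(risk_index: float, risk_reference: float, scale: str) -> float:
    if scale == "RD":
        return float(risk_index - risk_reference)
    if scale == "OR":
        for r in (risk_index, risk_reference):
            if r <= 0.0 or r >= 1.0:
                raise DegenerateOddsError(
                    f"marginal risk {r} gives degenerate odds; the odds ratio is undefined"
                )
        return float((risk_index / (1 - risk_index)) / (risk_reference / (1 - risk_reference)))
    raise ConfigurationError(f"unknown scale {scale!r}; expected one of {SCALES}")


def marginal_contrast(stack: CounterfactualStack, scale: str = "RD") -> float:
    """Step 3: contrast the two arms' potential-outcome means.

    Rows with undefined potential outcomes are excluded; for a binary arm
    indicator the closed-form contrast of arm means is identical to the
    (exponentiated) slope of a regression of the potential outcome on the
    intervention, because that regression is saturated.
    """
    def arm_mean(values: np.ndarray, arm: str) -> float:
        defined = values[~np.isnan(values)]
        if defined.size == 0:
            raise EstimationError(f"no defined potential outcomes in the {arm} arm")
        return float(defined.mean())

    p_index = arm_mean(stack.po_index, "index (A=1)")
    p_reference = arm_mean(stack.po_reference, "reference (A=0)")
    return _contrast(p_index, p_reference, scale)


def _standardized_risks_from_design(
    ds: _DesignSet, params: np.ndarray, estimand: str, restriction: bool = False
) -> tuple[float, float]:
    """Marginal risks under the two interventions for the target subpopulation.

    ``restriction=True`` computes the ATE-style model contrast restricted to
    the estimand's subgroup (model predictions in both arms); otherwise the
    factual arm uses the subgroup's observed outcome mean, per the plug-in
    standardization formulas.
    """
    p1 = expit(ds.X1 @ params)
    p0 = expit(ds.X0 @ params)
    treated = ds.a == 1
    if estimand == "ATT":
        m = treated
        r1 = float(p1[m].mean()) if restriction else float(ds.y[m].mean())
        r0 = float(p0[m].mean())
    elif estimand == "ATU":
        m = ~treated
        r1 = float(p1[m].mean())
        r0 = float(p0[m].mean()) if restriction else float(ds.y[m].mean())
    elif estimand == "ATE":
        r1 = float(p1.mean())
        r0 = float(p0.mean())
    else:
        raise ConfigurationError(f"unknown estimand {estimand!r}")
    return r1, r0


def standardization_estimate(
    data: ObservedData,
    spec: OutcomeModelSpec,
    estimand: str,
    scale: str = "RD",
) -> float:
    """Plug-in g-computation without simulation.

    Fits the outcome model once and averages its predictions over the
    target subpopulation's covariate distribution:

    * ATT: observed risk among the treated minus the mean of E(Y | A=0, C_i)
      over treated units;
    * ATU: mean of E(Y | A=1, C_i) over untreated units minus their observed
      risk;
    * ATE: mean of E(Y | A=1, C_i) - E(Y | A=0, C_i) over everyone.

    On the OR scale the same two marginal risks are converted to odds and
    divided.
    """
    if estimand not in ESTIMANDS:
        raise ConfigurationError(f"unknown estimand {estimand!r}")
    ds = build_design(data, spec)
    params, _ = _fit_params(ds.y, ds.X, ds.column_names)
    r1, r0 = _standardized_risks_from_design(ds, params, estimand)
    return _contrast(r1, r0, scale)


def restriction_estimate(
    data: ObservedData,
    spec: OutcomeModelSpec,
    estimand: str,
    scale: str = "RD",
) -> float:
    """ATT/ATU via the ATE contrast restricted to the relevant subgroup.

    Fits the model on the full data, then averages the model contrast
    E(Y | A=1, C_i) - E(Y | A=0, C_i) over the treated (ATT) or untreated
    (ATU) units only.  With a treatment-interacted model this equals the
    plug-in standardization estimate, because the score equations force the
    subgroup's predicted factual risk to match its observed risk.
    """
    if estimand not in ("ATT", "ATU"):
        raise ConfigurationError("restriction_estimate is defined for ATT and ATU only")
    ds = build_design(data, spec)
    params, _ = _fit_params(ds.y, ds.X, ds.column_names)
    r1, r0 = _standardized_risks_from_design(ds, params, estimand, restriction=True)
    return _contrast(r1, r0, scale)


def nonparametric_standardization(
    data: ObservedData, estimand: str, scale: str = "RD"
) -> float:
    """Model-free standardization over discrete covariate strata.

    Evaluates the identification formulas directly from empirical cell
    means and stratum frequencies:

    * ATE = sum_c [E(Y|A=1,c) - E(Y|A=0,c)] P(c)
    * ATT = E(Y|A=1) - sum_c E(Y|A=0,c) P(c|A=1)
    * ATU = sum_c E(Y|A=1,c) P(c|A=0) - E(Y|A=0)

    All covariates are treated as discrete (each distinct value pattern is a
    stratum).  Serves as the exact oracle for saturated-model estimators.

    Raises
    ------
    PositivityError
        If a stratum required by the formula has no units in the
        conditioning arm.
    """
    if estimand not in ESTIMANDS:
        raise ConfigurationError(f"unknown estimand {estimand!r}")
    covs = list(data.covariate_names)
    df = data.covariates.copy()
    df["__a__"] = data.treatment
    df["__y__"] = data.outcome
    grp = df.groupby(covs, sort=True, observed=True)
    agg = grp.apply(
        lambda g: pd.Series(
            {
                "n1": int((g["__a__"] == 1).sum()),
                "n0": int((g["__a__"] == 0).sum()),
                "y1": g.loc[g["__a__"] == 1, "__y__"].mean(),
                "y0": g.loc[g["__a__"] == 0, "__y__"].mean(),
            }
        ),
        include_groups=False,
    )

    def need(col: str, weight_col: str, arm_label: str) -> pd.Series:
        rows = agg[agg[weight_col] > 0]
        missing = rows[rows[col].isna()]
        if len(missing):
            stratum = missing.index[0]
            stratum = stratum if isinstance(stratum, tuple) else (stratum,)
            raise PositivityError(
                f"stratum {dict(zip(covs, stratum))} has no units with treatment "
                f"{arm_label}; the {estimand} formula is not identified",
                stratum=stratum,
            )
        return rows

    y_all = data.outcome
    a_all = data.treatment
    if estimand == "ATT":
        rows = need("y0", "n1", "A=0")
        r1 = float(y_all[a_all == 1].mean())
        r0 = float((rows["y0"] * rows["n1"]).sum() / rows["n1"].sum())
    elif estimand == "ATU":
        rows = need("y1", "n0", "A=1")
        r1 = float((rows["y1"] * rows["n0"]).sum() / rows["n0"].sum())
        r0 = float(y_all[a_all == 0].mean())
    else:  # ATE needs both arms in every non-empty stratum
        rows = need("y0", "n1", "A=0")
        rows = need("y1", "n0", "A=1")
        n_c = agg["n1"] + agg["n0"]
        r1 = float((agg["y1"] * n_c).sum() / n_c.sum())
        r0 = float((agg["y0"] * n_c).sum() / n_c.sum())
    return _contrast(r1, r0, scale)


# ---------------------------------------------------------------------------
# request and orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EstimandRequest:
    """What to estimate and how.

    Defaults: K = 200 Monte Carlo resamples for the simulation method,
    J = 500 bootstrap replicates (J = 0 means point estimate only),
    percentile confidence intervals.
    """

    estimand: str
    scale: str = "RD"
    method: str = "standardization"
    K: int = 200
    J: int = 500
    seed: int = 0
    ci_method: str = "percentile"
    ate_mode: str = "simulate"
    max_failure_fraction: float = 0.10
    positivity_bins: int = 5

    def __post_init__(self):
        if self.estimand not in ESTIMANDS:
            raise ConfigurationError(f"unknown estimand {self.estimand!r}; expected {ESTIMANDS}")
        if self.scale not in SCALES:
            raise ConfigurationError(f"unknown scale {self.scale!r}; expected {SCALES}")
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}; expected {METHODS}")
        if self.method == "restriction" and self.estimand == "ATE":
            raise ConfigurationError("the restriction method is defined for ATT and ATU only")
        if int(self.K) < 1:
            raise ConfigurationError("K must be >= 1")
        if int(self.J) < 0:
            raise ConfigurationError("J must be >= 0")
        if self.ci_method not in ("percentile", "bca"):
            raise ConfigurationError("ci_method must be 'percentile' or 'bca'")


class PointEstimator:
    """End-to-end point estimator over fixed design columns.

    Builds the design matrices once from the original data; every
    (re)estimate — on the full sample or on a bootstrap resample given by
    row indices — refits the outcome model and, for the simulation method,
    redraws the K resamples and the counterfactual Bernoulli outcomes from
    the stream it is handed.  Fixing the design columns at the original
    sample keeps bootstrap replicates comparable when a rare categorical
    level drops out of a resample.
    """

    def __init__(self, data: ObservedData, spec: OutcomeModelSpec, request: EstimandRequest):
        self.request = request
        self.spec = spec
        self.design = build_design(data, spec)
        _check_rank(self.design.X, self.design.column_names)

    def __call__(self, idx: np.ndarray | None, seed) -> float:
        req = self.request
        ds = self.design if idx is None else self.design.rows(np.asarray(idx))
        params, _ = _fit_params(ds.y, ds.X, ds.column_names, check_rank=False)
        if req.method in ("standardization", "restriction"):
            r1, r0 = _standardized_risks_from_design(
                ds, params, req.estimand, restriction=(req.method == "restriction")
            )
            return _contrast(r1, r0, req.scale)
        # simulation: resample K times, then draw counterfactuals, on one stream
        rng = _as_rng(seed)
        n = ds.n
        ridx = rng.integers(0, n, size=req.K * n)
        p1 = expit(ds.X1[ridx] @ params)
        p0 = expit(ds.X0[ridx] @ params)
        po1, po0 = _fill_potential_outcomes(
            req.estimand, ds.a[ridx], ds.y[ridx], p1, p0, rng, req.ate_mode
        )
        def arm_mean(v, arm):
            d = v[~np.isnan(v)]
            if d.size == 0:
                raise EstimationError(f"no defined potential outcomes in the {arm} arm")
            return float(d.mean())
        return _contrast(arm_mean(po1, "index"), arm_mean(po0, "reference"), req.scale)


def gcompute(
    data: ObservedData,
    request: EstimandRequest,
    spec: OutcomeModelSpec | None = None,
):
    """Run the full g-computation pipeline for one estimand.

    Dispatches to the requested method for the point estimate and, when
    ``request.J > 0``, to :func:`gcomp.inference.bootstrap_estimate` for the
    standard error and confidence interval.  The positivity report is
    always computed and attached to the result's metadata; violations warn
    but do not abort.

    Returns a :class:`gcomp.inference.EffectEstimate`.
    """
    from . import inference  # deferred to avoid an import cycle

    if spec is None:
        spec = OutcomeModelSpec.default(data.covariate_names)
    report = check_positivity(data, request.positivity_bins)
    if not report.ok:
        warnings.warn(
            f"positivity: {report.n_flagged} covariate strata lack one treatment arm",
            UserWarning,
            stacklevel=2,
        )
    return inference.bootstrap_estimate(data, request, spec, positivity=report)
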