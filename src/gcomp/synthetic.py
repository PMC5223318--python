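"""Synthetic confounded datasets with known true ATT, ATU and ATE.

The generative model mirrors the structure of the motivating application —
a cross-sectional health survey with a binary education-like treatment, a
binary angina-like outcome, an age-like continuous covariate and a
gender-like binary covariate:

* covariates: Z ~ Normal(loc, scale), G ~ Bernoulli(p)
* treatment:  A ~ Bernoulli(expit(alpha . [1, Z, G]))           (confounded)
* outcome:    Y ~ Bernoulli(expit(beta . [1, A, Z, G, A*Z, A*G]))

Nonzero treatment-by-covariate coefficients make the treatment effect
heterogeneous, so ATT, ATU and ATE genuinely differ and each estimator can
be checked against the truth.  The truth itself is computed by
:func:`true_effects` as a brute-force Monte Carlo average of the
closed-form per-unit potential-outcome probabilities — no simulated
outcomes, so the oracle carries no Bernoulli noise beyond the covariate and
treatment draws.

:func:`toy_fixture` returns a fixed 14-row dataset with one binary
covariate whose standardized effects have exact rational values (ATT risk
difference 5/12, ATU 3/8, ATE 11/28), used throughout the test suite as a
hand-checkable oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ObservedData
from .exceptions import ConfigurationError

__all__ = ["SyntheticConfig", "TrueEffects", "generate_dataset", "true_effects", "toy_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Coefficients of the generative model, on the log-odds scale.

    ``alpha`` = (intercept, age, gender) for the treatment model;
    ``beta`` = (intercept, treatment, age, gender, treatment*age,
    treatment*gender) for the outcome model.  The defaults describe a
    survey-like population with a moderately protective treatment whose
    effect strengthens with age and is confounded by both covariates, so the
    three estimands separate (ATT strongest, ATE in between).
    """

    n: int = 1000
    age_loc: float = 0.0
    age_scale: float = 1.0
    p_gender: float = 0.5
    alpha: tuple[float, float, float] = (-0.4, 0.3, 0.2)
    beta: tuple[float, float, float, float, float, float] = (
        -1.4,
        -0.35,
        0.4,
        0.25,
        -0.25,
        -0.15,
    )
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not (0.0 < self.p_gender < 1.0):
            raise ConfigurationError("p_gender must be in (0, 1)")
        if self.age_scale <= 0:
            raise ConfigurationError("age_scale must be positive")
        coef = np.concatenate([self.alpha, self.beta])
        if not np.isfinite(coef).all():
            raise ConfigurationError("all coefficients must be finite")
        if len(self.alpha) != 3 or len(self.beta) != 6:
            raise ConfigurationError("alpha has 3 coefficients, beta has 6")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "age_loc": self.age_loc,
            "age_scale": self.age_scale,
            "p_gender": self.p_gender,
            "alpha": list(self.alpha),
            "beta": list(self.beta),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        for key in ("alpha", "beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _draw_covariates(config: SyntheticConfig, rng: np.random.Generator, n: int):
    age = rng.normal(config.age_loc, config.age_scale, size=n)
    gender = rng.binomial(1, config.p_gender, size=n)
    return age, gender


def _treatment_probability(config: SyntheticConfig, age, gender):
    a0, a1, a2 = config.alpha
    return expit(a0 + a1 * age + a2 * gender)


def _outcome_probability(config: SyntheticConfig, a, age, gender):
    b0, bA, bZ, bG, bAZ, bAG = config.beta
    return expit(b0 + bA * a + bZ * age + bG * gender + bAZ * a * age + bAG * a * gender)


def generate_dataset(config: SyntheticConfig) -> ObservedData:
    """Draw one dataset from the generative model (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    age, gender = _draw_covariates(config, rng, config.n)
    a = rng.binomial(1, _treatment_probability(config, age, gender))
    y = rng.binomial(1, _outcome_probability(config, a, age, gender))
    return ObservedData(
        treatment=a,
        outcome=y,
        covariates=pd.DataFrame({"age": age, "gender": gender}),
        unit_id=np.arange(config.n),
    )


@dataclass(frozen=True)
class TrueEffects:
    """Population-level causal contrasts implied by a :class:`SyntheticConfig`.

    Risk differences, odds ratios, and the marginal risks under each
    intervention for each target population, with Monte Carlo standard
    errors of the risk differences.  On the same Monte Carlo draw the exact
    identity ATE = p*ATT + (1-p)*ATU holds, p being the realized treated
    fraction.
    """

    att_rd: float
    atu_rd: float
    ate_rd: float
    att_or: float
    atu_or: float
    ate_or: float
    treated_fraction: float
    n_mc: int
    mc_se: Mapping[str, float] = field(default_factory=dict)

    def rd(self, estimand: str) -> float:
        return {"ATT": self.att_rd, "ATU": self.atu_rd, "ATE": self.ate_rd}[estimand]

    def odds_ratio(self, estimand: str) -> float:
        return {"ATT": self.att_or, "ATU": self.atu_or, "ATE": self.ate_or}[estimand]


def true_effects(config: SyntheticConfig, n_mc: int = 10**6, seed: int = 12345) -> TrueEffects:
    """Brute-force oracle for the true ATT/ATU/ATE under ``config``.

    Draws ``n_mc`` units, computes both potential-outcome probabilities per
    unit in closed form from ``beta`` (treatment set to 1 and to 0),
    realizes treatment from ``alpha``, and averages: ATE over everyone, ATT
    over the realized treated, ATU over the realized untreated.  Odds ratios
    come from the corresponding averaged risks.  ``n_mc >= 1e5`` is
    recommended; Monte Carlo standard errors of the risk differences are
    attached.
    """
    rng = np.random.default_rng(seed)
    age, gender = _draw_covariates(config, rng, n_mc)
    a = rng.binomial(1, _treatment_probability(config, age, gender))
    p1 = _outcome_probability(config, 1, age, gender)
    p0 = _outcome_probability(config, 0, age, gender)
    diff = p1 - p0
    treated = a == 1

    def _odds(p):
        return p / (1 - p)

    def summarize(mask):
        m = int(mask.sum())
        rd = float(diff[mask].mean())
        se = float(diff[mask].std(ddof=1) / np.sqrt(m))
        orr = float(_odds(p1[mask].mean()) / _odds(p0[mask].mean()))
        return rd, orr, se

    att_rd, att_or, att_se = summarize(treated)
    atu_rd, atu_or, atu_se = summarize(~treated)
    ate_rd, ate_or, ate_se = summarize(np.ones(n_mc, dtype=bool))
    return TrueEffects(
        att_rd=att_rd,
        atu_rd=atu_rd,
        ate_rd=ate_rd,
        att_or=att_or,
        atu_or=atu_or,
        ate_or=ate_or,
        treated_fraction=float(treated.mean()),
        n_mc=n_mc,
        mc_se={"ATT": att_se, "ATU": atu_se, "ATE": ate_se},
    )


_TOY_ROWS = [
    # (A, C, Y)
    (1, 1, 1), (1, 1, 1), (1, 1, 1), (1, 1, 0),
    (1, 0, 1), (1, 0, 0),
    (0, 1, 1), (0, 1, 0), (0, 1, 0), (0, 1, 0),
    (0, 0, 1), (0, 0, 0), (0, 0, 0), (0, 0, 0),
]


def toy_fixture() -> ObservedData:
    """Fixed 14-row dataset with one binary covariate and exact rational effects.

    Cell means: E(Y|A=1,C=1) = 3/4, E(Y|A=1,C=0) = 1/2,
    E(Y|A=0,C=1) = 1/4, E(Y|A=0,C=0) = 1/4; treated fraction 6/14.
    Standardization gives ATT RD = 5/12, ATU RD = 3/8, ATE RD = 11/28 and
    odds ratios 6.0, 5.0 and 5.4.
    """
    arr = np.array(_TOY_ROWS, dtype=np.int8)
    return ObservedData(
        treatment=arr[:, 0],
        outcome=arr[:, 2],
        covariates=pd.DataFrame({"C": arr[:, 1].astype(np.int64)}),
        unit_id=np.arange(len(arr)),
    )
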