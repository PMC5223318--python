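"""Nonparametric bootstrap inference for g-computation estimators.

Standard errors and confidence intervals follow the resampling recipe:
steps 1-3 of the algorithm are repeated end-to-end on J samples drawn with
replacement from the original data (model refit, fresh Monte Carlo
resamples, fresh counterfactual draws); the standard deviation of the J
point estimates is the standard error, and the 2.5th and 97.5th percentiles
are the 95% confidence limits.  Bias-corrected and accelerated (BCa)
intervals are available as an alternative to the percentile interval.

Percentile convention: linear interpolation between order statistics
(``numpy.percentile`` with ``method="linear"``); recorded in the run
metadata.  Each bootstrap replicate consumes an independent random stream
spawned from the master seed, so replicates are exchangeable and the whole
run is reproducible from (data, request, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .data import ObservedData, PositivityReport
from .exceptions import (
    BootstrapError,
    DegenerateDrawsError,
    DegenerateOddsError,
    EstimationError,
    FitError,
    GcompError,
)

__all__ = ["EffectEstimate", "bootstrap_estimate", "bca_interval", "percentile_interval"]

_PERCENTILE_CONVENTION = "linear interpolation between order statistics"
_GENERATOR = "PCG64"


def percentile_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of the bootstrap draws."""
    lo = 100 * (1 - level) / 2
    lo_v, hi_v = np.percentile(np.asarray(draws, dtype=float), [lo, 100 - lo], method="linear")
    return float(lo_v), float(hi_v)


def bca_interval(
    draws: Sequence[float],
    point: float,
    jackknife: Sequence[float],
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    The bias correction ``z0`` comes from the fraction of draws below the
    point estimate; the acceleration ``a`` from the skewness of
    leave-one-unit-out jackknife estimates.  With ``z0 = 0`` and ``a = 0``
    the interval reduces to the plain percentile interval under the same
    percentile convention.

    Raises
    ------
    DegenerateDrawsError
        If all draws are identical, or the point estimate lies outside the
        draws' support so the bias correction is infinite.
    """
    d = np.asarray(draws, dtype=float)
    if d.size < 2 or np.all(d == d[0]):
        raise DegenerateDrawsError(
            "bootstrap draws are all identical; BCa is undefined "
            "(use the percentile interval)"
        )
    frac_below = float(np.mean(d < point))
    if frac_below in (0.0, 1.0):
        raise DegenerateDrawsError(
            "every bootstrap draw lies on one side of the point estimate; "
            "the BCa bias correction is infinite"
        )
    z0 = norm.ppf(frac_below)
    jk = np.asarray(jackknife, dtype=float)
    dev = jk.mean() - jk
    denom = np.sum(dev**2) ** 1.5
    a = float(np.sum(dev**3) / (6 * denom)) if denom > 0 else 0.0
    z_alpha = norm.ppf((1 - level) / 2)
    bounds = []
    for z in (z_alpha, -z_alpha):
        adj = z0 + (z0 + z) / (1 - a * (z0 + z))
        bounds.append(float(np.percentile(d, 100 * norm.cdf(adj), method="linear")))
    return bounds[0], bounds[1]


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with bootstrap uncertainty and full run metadata.

    ``se``, ``ci_low`` and ``ci_high`` are ``None`` when no bootstrap was
    run (J = 0): absence of inference, not zero uncertainty.  ``draws``
    stores every successful replicate estimate; ``se`` is their sample
    standard deviation.
    """

    estimand: str
    scale: str
    point: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str = "percentile"
    draws: tuple[float, ...] = ()
    n_failed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise GcompError("confidence interval bounds are inverted")
        if self.draws and self.se is not None:
            sd = float(np.std(self.draws, ddof=1))
            if abs(sd - self.se) > 1e-12:
                raise GcompError("stored SE does not match the bootstrap draws")

    @property
    def has_inference(self) -> bool:
        return self.se is not None

    def summary(self) -> str:
        s = f"{self.estimand} ({self.scale}): {self.point:.3f}"
        if self.has_inference:
            s += f" (SE {self.se:.3f}, 95% CI {self.ci_low:.3f}, {self.ci_high:.3f})"
        return s


def bootstrap_estimate(
    data: ObservedData,
    request,
    spec,
    estimator: Callable[[np.ndarray | None, object], float] | None = None,
    positivity: PositivityReport | None = None,
) -> EffectEstimate:
    """Point estimate plus bootstrap SE/CI for one estimand request.

    ``estimator`` is a point-estimator contract: a callable taking
    (row-index array or ``None`` for the original sample, random stream)
    and returning a point estimate, re-running the whole pipeline on that
    resample.  By default a :class:`gcomp.estimators.PointEstimator` for
    the request's method is built, which refits the outcome model (and for
    the simulation method redraws the K resamples and counterfactual
    outcomes) inside every replicate.

    Replicates that fail (separation in a resample, degenerate odds) are
    dropped and counted as long as they stay at or below
    ``request.max_failure_fraction`` of J; beyond that the whole run raises
    :class:`BootstrapError`.
    """
    from .estimators import PointEstimator  # deferred to avoid an import cycle

    if estimator is None:
        estimator = PointEstimator(data, spec, request)

    master = np.random.SeedSequence(request.seed)
    point_ss, boot_ss, jack_ss = master.spawn(3)
    point = float(estimator(None, point_ss))

    metadata = {
        "estimand": request.estimand,
        "scale": request.scale,
        "method": request.method,
        "K": int(request.K),
        "J": int(request.J),
        "seed": int(request.seed),
        "generator": _GENERATOR,
        "percentile_convention": _PERCENTILE_CONVENTION,
        "n_units": data.n_units,
        "n_treated": data.n_treated,
    }
    if positivity is not None:
        metadata["positivity_n_flagged"] = positivity.n_flagged
        metadata["positivity_flagged"] = [list(map(str, f)) for f in positivity.flagged]

    J = int(request.J)
    if J == 0:
        return EffectEstimate(
            estimand=request.estimand,
            scale=request.scale,
            point=point,
            ci_method=request.ci_method,
            metadata=metadata,
        )

    n = data.n_units
    draws: list[float] = []
    n_failed = 0
    for child in boot_ss.spawn(J):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        try:
            draws.append(float(estimator(idx, rng)))
        except (FitError, DegenerateOddsError, EstimationError):
            n_failed += 1
    if n_failed > request.max_failure_fraction * J:
        raise BootstrapError(
            f"{n_failed}/{J} bootstrap replicates failed "
            f"(limit {request.max_failure_fraction:.0%}); the resampling "
            "distribution cannot be trusted",
            n_failed=n_failed,
            n_total=J,
        )
    if n_failed:
        warnings.warn(
            f"{n_failed}/{J} bootstrap replicates failed and were dropped",
            UserWarning,
            stacklevel=2,
        )
    arr = np.asarray(draws)
    se = float(np.std(arr, ddof=1))
    if request.ci_method == "bca":
        jack = _jackknife(estimator, n, jack_ss)
        ci_low, ci_high = bca_interval(arr, point, jack)
    else:
        ci_low, ci_high = percentile_interval(arr)
    metadata["n_failed_replicates"] = n_failed
    return EffectEstimate(
        estimand=request.estimand,
        scale=request.scale,
        point=point,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_method=request.ci_method,
        draws=tuple(arr.tolist()),
        n_failed=n_failed,
        metadata=metadata,
    )


def _jackknife(estimator, n: int, seed_seq) -> np.ndarray:
    """Leave-one-unit-out point estimates on the original sample."""
    out = np.empty(n)
    children = seed_seq.spawn(n)
    base = np.arange(n)
    for i in range(n):
        idx = np.delete(base, i)
        out[i] = estimator(idx, children[i])
    return out
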