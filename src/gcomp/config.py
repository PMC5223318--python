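"""Run configuration: a flat YAML file plus command-line overrides.

A run is fully described by one structured-text config (column roles, level
mappings, estimands, scales, method, model terms, K, J, seed, CI method,
output paths), so every result can be reproduced from an artifact on disk.
Unknown keys are errors, not warnings; a command-line flag that contradicts
the file is an error too — silent precedence rules are how analyses stop
being reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .data import ColumnRoles
from .estimators import ESTIMANDS, METHODS, SCALES, TREATMENT, EstimandRequest, OutcomeModelSpec
from .exceptions import ConfigurationError

__all__ = ["RunConfig", "read_config", "DEFAULTS"]

logger = logging.getLogger("gcomp")

#: Defaults applied when a key is absent (each application is logged).
DEFAULTS: dict[str, Any] = {
    "estimands": ["ATT", "ATU", "ATE"],
    "scales": ["RD", "OR"],
    "method": "standardization",
    "model_terms": "default",
    "K": 200,
    "J": 500,
    "seed": 0,
    "ci_method": "percentile",
    "ate_mode": "simulate",
    "positivity_bins": 5,
    "include_draws": False,
    "output": None,
    "output_json": None,
    "treatment_levels": None,
    "outcome_levels": None,
}

_REQUIRED = ("input", "treatment", "outcome", "covariates")
VALID_KEYS = tuple(_REQUIRED) + tuple(DEFAULTS)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one estimation run."""

    input: str
    treatment: str
    outcome: str
    covariates: tuple[str, ...]
    treatment_levels: Mapping[Any, int] | None = None
    outcome_levels: Mapping[Any, int] | None = None
    estimands: tuple[str, ...] = ("ATT", "ATU", "ATE")
    scales: tuple[str, ...] = ("RD", "OR")
    method: str = "standardization"
    model_terms: Any = "default"  # "default" | "saturated" | "main_effects" | list of term lists
    K: int = 200
    J: int = 500
    seed: int = 0
    ci_method: str = "percentile"
    ate_mode: str = "simulate"
    positivity_bins: int = 5
    include_draws: bool = False
    output: str | None = None
    output_json: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "estimands", tuple(self.estimands))
        object.__setattr__(self, "scales", tuple(self.scales))
        for e in self.estimands:
            if e not in ESTIMANDS:
                raise ConfigurationError(f"unknown estimand {e!r}; expected one of {ESTIMANDS}")
        for s in self.scales:
            if s not in SCALES:
                raise ConfigurationError(f"unknown scale {s!r}; expected one of {SCALES}")
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.method == "restriction" and "ATE" in self.estimands:
            raise ConfigurationError(
                "method 'restriction' is defined for ATT and ATU only; "
                "drop ATE from estimands or choose another method"
            )

    def roles(self) -> ColumnRoles:
        return ColumnRoles(
            treatment=self.treatment,
            outcome=self.outcome,
            covariates=self.covariates,
            treatment_levels=self.treatment_levels,
            outcome_levels=self.outcome_levels,
        )

    def model_spec(self) -> OutcomeModelSpec:
        terms = self.model_terms
        if terms == "default":
            return OutcomeModelSpec.default(self.covariates)
        if terms == "saturated":
            return OutcomeModelSpec.saturated(self.covariates)
        if terms == "main_effects":
            return OutcomeModelSpec.main_effects_only()
        if isinstance(terms, (list, tuple)):
            return OutcomeModelSpec(product_terms=tuple(tuple(t) for t in terms))
        raise ConfigurationError(
            f"model_terms must be 'default', 'saturated', 'main_effects' or a "
            f"list of term lists, got {terms!r}"
        )

    def requests(self) -> list[EstimandRequest]:
        return [
            EstimandRequest(
                estimand=e,
                scale=s,
                method=self.method,
                K=self.K,
                J=self.J,
                seed=self.seed,
                ci_method=self.ci_method,
                ate_mode=self.ate_mode,
                positivity_bins=self.positivity_bins,
            )
            for e in self.estimands
            for s in self.scales
        ]

    def to_dict(self) -> dict:
        d = {
            "input": self.input,
            "treatment": self.treatment,
            "outcome": self.outcome,
            "covariates": list(self.covariates),
            "estimands": list(self.estimands),
            "scales": list(self.scales),
            "method": self.method,
            "model_terms": self.model_terms
            if isinstance(self.model_terms, str)
            else [list(t) for t in self.model_terms],
            "K": self.K,
            "J": self.J,
            "seed": self.seed,
            "ci_method": self.ci_method,
            "ate_mode": self.ate_mode,
            "positivity_bins": self.positivity_bins,
            "include_draws": self.include_draws,
            "output": self.output,
            "output_json": self.output_json,
        }
        if self.treatment_levels is not None:
            d["treatment_levels"] = dict(self.treatment_levels)
        if self.outcome_levels is not None:
            d["outcome_levels"] = dict(self.outcome_levels)
        return d


def read_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Resolve a config file and/or command-line overrides into a RunConfig.

    Raises
    ------
    ConfigurationError
        On unknown keys (listing the valid ones), on a flag that contradicts
        the file, or on missing required keys.
    """
    file_cfg: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        file_cfg = loaded
    unknown = set(file_cfg) - set(VALID_KEYS)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(VALID_KEYS)}"
        )
    overrides = {k: v for k, v in (overrides or {}).items() if v is not None}
    unknown = set(overrides) - set(VALID_KEYS)
    if unknown:
        raise ConfigurationError(
            f"unknown override keys {sorted(unknown)}; valid keys: {sorted(VALID_KEYS)}"
        )
    for key, value in overrides.items():
        if key in file_cfg and file_cfg[key] != value:
            raise ConfigurationError(
                f"flag --{key.replace('_', '-')}={value!r} contradicts config "
                f"file value {file_cfg[key]!r}; change one of them"
            )
    merged = {**file_cfg, **overrides}
    missing = [k for k in _REQUIRED if k not in merged]
    if missing:
        raise ConfigurationError(f"missing required config keys: {missing}")
    for key, default in DEFAULTS.items():
        if key not in merged:
            merged[key] = default
            if default is not None:
                logger.info("config default applied: %s = %r", key, default)
    return RunConfig(**merged)
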