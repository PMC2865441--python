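"""Pluggable 5-year glaucoma risk model.

A case's risk factors enter a linear predictor (weighted sum plus
intercept); the predictor maps to a probability through one of two link
families: plain logistic, or a survival-based complementary-log-log form
``1 - S0^exp(lp)`` with a baseline 5-year survival ``S0`` (the structure
of published proportional-hazards risk calculators).  Coefficients are
config-supplied, never built in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .cases import CONTINUOUS_FACTORS

LOGISTIC = "logistic"
CLOGLOG_SURVIVAL = "cloglog_survival"
_LINKS = (LOGISTIC, CLOGLOG_SURVIVAL)

#: Case fields a coefficient may reference (gender is carried but unused).
COEFFICIENT_FIELDS = CONTINUOUS_FACTORS + ("diabetes",)


@dataclass(frozen=True)
class RiskModelConfig:
    """Linear-predictor risk model: coefficients, intercept and link."""

    coefficients: Mapping[str, float]
    intercept: float = 0.0
    link: str = LOGISTIC
    baseline_survival: float | None = None
    risk_horizon_years: float | None = 5.0

    def __post_init__(self) -> None:
        unknown = [k for k in self.coefficients if k not in COEFFICIENT_FIELDS]
        if unknown:
            raise ValueError(
                f"coefficients reference unknown case fields: {unknown}; "
                f"allowed: {list(COEFFICIENT_FIELDS)}"
            )
        if self.link not in _LINKS:
            raise ValueError(f"link must be one of {_LINKS}, got {self.link!r}")
        if self.link == CLOGLOG_SURVIVAL:
            s0 = self.baseline_survival
            if s0 is None or not (0.0 < s0 < 1.0):
                raise ValueError(
                    f"baseline_survival must be in (0, 1) for the "
                    f"{CLOGLOG_SURVIVAL} link, got {s0!r}"
                )
        for k, v in self.coefficients.items():
            if not math.isfinite(v):
                raise ValueError(f"coefficient {k!r} is not finite")
        if not math.isfinite(self.intercept):
            raise ValueError("intercept is not finite")


def linear_predictor(case: Mapping, config: RiskModelConfig) -> float:
    """``intercept + sum(coef * value)`` for one case (mapping or Series)."""
    case_id = case.get("case_id", "<unknown>")
    lp = config.intercept
    for factor, coef in config.coefficients.items():
        try:
            value = case[factor]
        except KeyError:
            raise ValueError(
                f"case {case_id!r}: missing factor {factor!r}"
            ) from None
        value = float(value)
        if not math.isfinite(value):
            raise ValueError(
                f"case {case_id!r}: factor {factor!r} is not finite ({value})"
            )
        lp += coef * value
    return float(lp)


def risk_from_linear_predictor(lp, config: RiskModelConfig):
    """Map linear predictor(s) to probability of disease in (0, 1).

    Both links are strictly increasing bijections from the reals onto
    (0, 1).  Accepts scalars or arrays.
    """
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    if config.link == LOGISTIC:
        out = expit(lp)
    else:
        # 1 - S0^exp(lp) computed as -expm1(exp(lp) * ln S0) for accuracy
        log_s0 = math.log(config.baseline_survival)
        out = -np.expm1(np.exp(lp) * log_s0)
    if out.ndim == 0:
        return float(out)
    return out


def compute_risks(cases: pd.DataFrame, config: RiskModelConfig) -> np.ndarray:
    """One risk per case row, in case-table order."""
    if len(cases) == 0:
        return np.empty(0)
    lp = np.full(len(cases), config.intercept, dtype=float)
    for factor, coef in config.coefficients.items():
        if factor not in cases.columns:
            raise ValueError(f"case table lacks factor column {factor!r}")
        col = pd.to_numeric(cases[factor], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            cid = cases.iloc[bad[0]].get("case_id", f"row {bad[0]}")
            raise ValueError(
                f"case {cid!r}: factor {factor!r} is missing or non-numeric"
            )
        lp += coef * col
    return np.asarray(risk_from_linear_predictor(lp, config))
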