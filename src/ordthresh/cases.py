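"""Synthetic ocular-hypertension case generation.

Cases are vectors of glaucoma risk factors (age, intraocular pressure,
cup-disc ratio, pattern standard deviation, central corneal thickness,
diabetes status, gender).  Continuous factors are drawn independently from
truncated normal distributions via rejection resampling against configured
eligibility bounds; binary/categorical factors from stated proportions.
The derived risk distribution of a cohort can be summarized by a
moment-matched log-normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Continuous risk factors carried by every case, in canonical column order.
CONTINUOUS_FACTORS = ("age", "iop", "cdr", "psd", "cct")

#: Full case-table column schema.
CASE_COLUMNS = ("case_id", "age", "iop", "cdr", "psd", "cct", "diabetes", "gender")

#: Factors constrained to be strictly positive (all but the [0, 1] ratio).
_POSITIVE_FACTORS = ("age", "iop", "psd", "cct")


@dataclass(frozen=True)
class FactorSpec:
    """Marginal distribution of one continuous factor.

    ``lower``/``upper`` are eligibility truncation bounds; sampling rejects
    and redraws values outside them (clipping would distort the shape).
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def validate(self, name: str) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"factor {name!r}: mean must be finite")
        if not (self.sd >= 0):
            raise ValueError(f"factor {name!r}: sd must be >= 0, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError(
                f"factor {name!r}: bounds must satisfy lower < upper, "
                f"got [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class PopulationConfig:
    """Summary statistics defining a synthetic case population.

    ``factors`` must provide a :class:`FactorSpec` for each of
    :data:`CONTINUOUS_FACTORS`.  Unbounded specs are tightened to the
    domain of the factor (positive scales; cup-disc ratio in [0, 1]) so
    that emitted cases always satisfy the case invariants.
    """

    factors: Mapping[str, FactorSpec]
    p_diabetes: float
    p_female: float
    n_cases: int
    seed: int
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        missing = [f for f in CONTINUOUS_FACTORS if f not in self.factors]
        if missing:
            raise ValueError(f"missing factor specs: {missing}")
        for name in CONTINUOUS_FACTORS:
            self.factors[name].validate(name)
        for label, p in (("p_diabetes", self.p_diabetes), ("p_female", self.p_female)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{label} must be in [0, 1], got {p}")
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be positive")

    def effective_bounds(self, name: str) -> tuple[float, float]:
        """Truncation bounds after tightening to the factor's domain."""
        spec = self.factors[name]
        lower, upper = spec.lower, spec.upper
        if name in _POSITIVE_FACTORS:
            lower = max(lower, 0.0)
        elif name == "cdr":
            lower = max(lower, 0.0)
            upper = min(upper, 1.0)
        if not lower < upper:
            raise ValueError(
                f"factor {name!r}: domain-tightened bounds empty: [{lower}, {upper}]"
            )
        return lower, upper


@dataclass(frozen=True)
class DistributionSummary:
    """Sample moments of a risk vector and the moment-matched log-normal."""

    mean: float
    variance: float
    lognormal_mu: float
    lognormal_sigma: float
    n: int


class UnsatisfiableBoundsError(RuntimeError):
    """Rejection sampling exhausted its attempt budget for a factor."""

    def __init__(self, factor: str, attempts: int):
        self.factor = factor
        super().__init__(
            f"factor {factor!r}: no draw fell inside its truncation bounds "
            f"after {attempts} attempts per value"
        )


def _sample_truncated_normal(
    rng: np.random.Generator,
    n: int,
    spec: FactorSpec,
    bounds: tuple[float, float],
    name: str,
    max_attempts: int,
) -> np.ndarray:
    lower, upper = bounds
    out = np.empty(n)
    pending = np.arange(n)
    for _ in range(max_attempts):
        if pending.size == 0:
            break
        draws = rng.normal(spec.mean, spec.sd, size=pending.size)
        ok = (draws >= lower) & (draws <= upper)
        out[pending[ok]] = draws[ok]
        pending = pending[~ok]
    if pending.size:
        raise UnsatisfiableBoundsError(name, max_attempts)
    return out


def simulate_cases(config: PopulationConfig) -> pd.DataFrame:
    """Draw a case table of ``config.n_cases`` synthetic patients.

    Returns a DataFrame with columns :data:`CASE_COLUMNS`; identical
    configs (including seed) produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    data: dict[str, np.ndarray] = {}
    width = max(3, len(str(max(n, 1))))
    data["case_id"] = np.array([f"case_{i + 1:0{width}d}" for i in range(n)])
    for name in CONTINUOUS_FACTORS:
        data[name] = _sample_truncated_normal(
            rng, n, config.factors[name], config.effective_bounds(name),
            name, config.max_attempts,
        )
    data["diabetes"] = (rng.random(n) < config.p_diabetes).astype(int)
    data["gender"] = np.where(rng.random(n) < config.p_female, "female", "male")
    return pd.DataFrame(data, columns=list(CASE_COLUMNS))


def summarize_risk_distribution(risks) -> DistributionSummary:
    """Sample mean/variance of a risk vector plus the log-normal with the
    same first two moments.

    The match solves ``sigma^2 = ln(1 + v/m^2)`` and
    ``mu = ln(m) - sigma^2/2``, so the log-normal's mean and variance
    reproduce the sample moments exactly.
    """
    r = np.asarray(risks, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need a 1-d vector of at least 2 risks")
    bad = np.flatnonzero(~((r > 0.0) & (r < 1.0)))
    if bad.size:
        raise ValueError(
            f"risk at index {bad[0]} is {r[bad[0]]!r}, outside (0, 1)"
        )
    m = float(np.mean(r))
    v = float(np.var(r))  # population variance: the matched moments are exact
    sigma2 = math.log1p(v / (m * m))
    sigma = math.sqrt(sigma2)
    mu = math.log(m) - sigma2 / 2.0
    return DistributionSummary(
        mean=m, variance=v, lognormal_mu=mu, lognormal_sigma=sigma, n=r.size
    )
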