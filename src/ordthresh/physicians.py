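"""Synthetic physician panels and 7-point ordinal treatment recommendations.

Each simulated physician has a latent treatment threshold r* (the disease
risk at which they are equally likely to say Yes and No), a discrimination
slope, and six cutpoint offsets defining the 7-level response scale.
Responses follow a proportional-odds model with cumulative logits

    logit P(t >= j | r) = kappa_j + beta * r,   kappa_j = -beta * r* + s_j

for levels j = 2..7.  With the inner offsets symmetric about zero
(s3 = -s6), the collapsed 3-level model's balance point equals r* exactly,
which makes the threshold estimator's recovery testable against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

#: The 7-point recommendation scale, ascending from no-treatment.
LEVELS7 = (
    "DefinitelyNo",
    "ProbablyNo",
    "PossiblyNo",
    "Unsure",
    "PossiblyYes",
    "ProbablyYes",
    "DefinitelyYes",
)

#: The collapsed 3-point analysis scale, ascending.
LEVELS3 = ("No", "Unsure", "Yes")

#: 7 -> 3 collapse: the two strongest No levels map to No, the two
#: strongest Yes levels to Yes, and the hedged middle three to Unsure.
COLLAPSE_MAP = {
    "DefinitelyNo": "No",
    "ProbablyNo": "No",
    "PossiblyNo": "Unsure",
    "Unsure": "Unsure",
    "PossiblyYes": "Unsure",
    "ProbablyYes": "Yes",
    "DefinitelyYes": "Yes",
}

#: Default cutpoint offsets s2..s7 (dimensionless, strictly decreasing,
#: with s3 = -s6 so the collapsed threshold equals r*).
DEFAULT_SPACING = (3.0, 1.5, 0.5, -0.5, -1.5, -3.0)


@dataclass(frozen=True)
class PhysicianParams:
    """Generative parameters for one simulated physician."""

    physician_id: str
    threshold: float            # latent r*, a probability
    discrimination: float       # beta, per unit risk (> 0)
    spacing: Sequence[float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if not self.discrimination > 0:
            raise ValueError("discrimination must be positive")
        s = tuple(float(x) for x in self.spacing)
        if len(s) != 6:
            raise ValueError("spacing must have six offsets (levels 2..7)")
        if not all(a > b for a, b in zip(s, s[1:])):
            raise ValueError("spacing offsets must be strictly decreasing")
        if abs(s[1] + s[4]) > 1e-12:
            raise ValueError(
                "inner offsets must satisfy s3 = -s6 so the collapsed "
                f"threshold equals r*; got s3={s[1]}, s6={s[4]}"
            )
        object.__setattr__(self, "spacing", s)

    @property
    def cutpoints(self) -> np.ndarray:
        """kappa_j = -beta * r* + s_j for j = 2..7."""
        return -self.discrimination * self.threshold + np.asarray(self.spacing)


def collapse_scale(response: str) -> str:
    """Collapse one 7-point level to {No, Unsure, Yes} (order-preserving)."""
    try:
        return COLLAPSE_MAP[response]
    except KeyError:
        raise ValueError(f"unknown response level: {response!r}") from None


def collapse_responses(responses: Iterable[str]) -> list[str]:
    """Vector form of :func:`collapse_scale`; 3-level inputs pass through."""
    out = []
    for r in responses:
        if r in LEVELS3:
            out.append(r)
        else:
            out.append(collapse_scale(r))
    return out


def simulate_physician_panel(
    n_physicians: int,
    threshold_beta_shapes: tuple[float, float] = (2.56, 9.14),
    discrimination_range: tuple[float, float] = (20.0, 60.0),
    spacing: Sequence[float] = DEFAULT_SPACING,
    seed: int | None = None,
) -> list[PhysicianParams]:
    """Draw a panel whose latent thresholds are i.i.d. Beta(a, b).

    Discriminations are uniform on ``discrimination_range``.  The default
    shapes reproduce a right-skewed threshold population with mean ~0.22
    of the kind observed among glaucoma specialists.
    """
    a, b = threshold_beta_shapes
    if not (a > 0 and b > 0):
        raise ValueError(f"beta shapes must be positive, got ({a}, {b})")
    lo, hi = discrimination_range
    if not (0 < lo <= hi):
        raise ValueError(f"discrimination range must satisfy 0 < lo <= hi, got ({lo}, {hi})")
    if n_physicians < 0:
        raise ValueError("n_physicians must be non-negative")
    rng = np.random.default_rng(seed)
    thresholds = rng.beta(a, b, size=n_physicians)
    # keep thresholds strictly interior for the proportional-odds generator
    thresholds = np.clip(thresholds, 1e-9, 1.0 - 1e-9)
    discs = rng.uniform(lo, hi, size=n_physicians)
    width = max(3, len(str(max(n_physicians, 1))))
    return [
        PhysicianParams(
            physician_id=f"phys_{i + 1:0{width}d}",
            threshold=float(thresholds[i]),
            discrimination=float(discs[i]),
            spacing=tuple(spacing),
        )
        for i in range(n_physicians)
    ]


def response_probabilities(params: PhysicianParams, risks) -> np.ndarray:
    """(n_cases, 7) matrix of category probabilities under the model."""
    r = np.atleast_1d(np.asarray(risks, dtype=float))
    # cumulative P(t >= j), j = 2..7, shape (n, 6); decreasing across j
    cum = expit(np.add.outer(params.discrimination * r, params.cutpoints))
    probs = np.empty((r.size, 7))
    probs[:, 0] = 1.0 - cum[:, 0]
    probs[:, 1:6] = cum[:, :5] - cum[:, 1:]
    probs[:, 6] = cum[:, 5]
    return probs


def simulate_responses(
    panel: Sequence[PhysicianParams],
    risks,
    case_ids: Sequence[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One 7-point recommendation per (physician, case).

    Returns a DataFrame with columns ``physician_id, case_id, response``;
    deterministic under ``seed``.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    r = np.asarray(risks, dtype=float)
    if r.ndim != 1:
        raise ValueError("risks must be a 1-d vector")
    if not np.all((r > 0) & (r < 1)):
        raise ValueError("all risks must lie strictly in (0, 1)")
    if case_ids is None:
        width = max(3, len(str(max(r.size, 1))))
        case_ids = [f"case_{i + 1:0{width}d}" for i in range(r.size)]
    elif len(case_ids) != r.size:
        raise ValueError("case_ids length must match risks")
    rng = np.random.default_rng(seed)
    levels = np.asarray(LEVELS7)
    frames = []
    for params in panel:
        cum = expit(np.add.outer(params.discrimination * r, params.cutpoints))
        u = rng.random(r.size)
        # t >= j  iff  u <= P(t >= j); level index = number of exceeded cutpoints
        idx = (u[:, None] <= cum).sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "physician_id": params.physician_id,
                    "case_id": list(case_ids),
                    "response": levels[idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
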