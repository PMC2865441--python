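"""Population-level analysis of per-physician treatment thresholds.

Screens out physicians whose recommendations are not risk-based (those
who treat on an intraocular-pressure cutoff alone), estimates a threshold
for every included physician, and characterizes the population threshold
distribution — sample summaries, a histogram, and a maximum-likelihood
beta fit with standard errors from the observed information.
"""

from __future__ import annotations

import math
import warnings as _warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, polygamma

from .estimate import ThresholdEstimate, estimate_threshold


@dataclass(frozen=True)
class ScreeningAnswers:
    """One physician's screening-question answers."""

    physician_id: str
    always_treats: bool = False
    never_treats: bool = False
    iop_only_rule: bool = False


@dataclass(frozen=True)
class BetaFit:
    """Maximum-likelihood beta shape parameters for the threshold population."""

    shape_a: float
    shape_b: float
    se_a: float
    se_b: float
    loglik: float
    n: int


@dataclass(frozen=True)
class PopulationSummary:
    """Descriptive summary of a collection of threshold estimates."""

    mean_threshold: float
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    modal_interval: tuple[float, float]
    n_included: int
    n_excluded: int
    method_counts: dict[str, int]


def screen_physicians(answers: Sequence[ScreeningAnswers]) -> pd.DataFrame:
    """Inclusion flags with exclusion reasons.

    Physicians treating on a pressure cutoff alone are not using overall
    disease risk and are excluded; always- and never-treat physicians are
    kept (their thresholds are assigned by the degenerate rules
    downstream) but their flags are recorded.
    """
    rows = []
    for a in answers:
        if a.iop_only_rule:
            included, reason = False, "treats on intraocular-pressure cutoff alone"
        else:
            included, reason = True, ""
        rows.append(
            {
                "physician_id": a.physician_id,
                "included": included,
                "reason": reason,
                "always_treats": a.always_treats,
                "never_treats": a.never_treats,
            }
        )
    return pd.DataFrame(rows)


def estimate_all_thresholds(
    responses: pd.DataFrame,
    risks: pd.DataFrame,
    included_ids: Sequence[str] | None = None,
) -> list[ThresholdEstimate]:
    """One :class:`ThresholdEstimate` per included physician.

    Output order follows first appearance in the response table.  Every
    included physician must have at least one response row.
    """
    order = responses["physician_id"].drop_duplicates().tolist()
    if included_ids is not None:
        included = set(included_ids)
        missing = included - set(order)
        if missing:
            raise ValueError(f"included physicians with no responses: {sorted(missing)}")
        order = [p for p in order if p in included]
    return [
        estimate_threshold(responses[responses["physician_id"] == pid], risks)
        for pid in order
    ]


def _beta_nll(params, x):
    a, b = params
    if a <= 0 or b <= 0:
        return np.inf
    return -float(np.sum((a - 1) * np.log(x) + (b - 1) * np.log1p(-x)) - x.size * betaln(a, b))


def fit_beta_mle(thresholds, boundary_nudge: float = 1e-6) -> BetaFit:
    """Two-parameter beta fit of the threshold distribution by maximum
    likelihood, with standard errors from the inverse observed information.

    Values exactly on the unit-interval boundary are nudged inward by
    ``boundary_nudge`` (with a warning), since the beta likelihood is
    unbounded there; values outside [0, 1] are rejected.
    """
    x = np.asarray(thresholds, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ValueError("need at least 5 threshold values")
    if np.any((x < 0) | (x > 1)):
        bad = np.flatnonzero((x < 0) | (x > 1))[0]
        raise ValueError(f"threshold at index {bad} is outside [0, 1]: {x[bad]}")
    on_boundary = (x <= 0) | (x >= 1)
    if np.any(on_boundary):
        _warnings.warn(
            f"{int(on_boundary.sum())} boundary threshold(s) nudged inward by "
            f"{boundary_nudge}", UserWarning, stacklevel=2,
        )
        x = np.clip(x, boundary_nudge, 1.0 - boundary_nudge)

    a0, b0, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    # polish: guarantee a gradient-level optimum even if the library fit
    # terminated loosely; fall back to a moment start if it went astray
    m, v = float(np.mean(x)), float(np.var(x))
    common = m * (1 - m) / max(v, 1e-12) - 1.0
    starts = [(a0, b0)]
    if common > 0:
        starts.append((m * common, (1 - m) * common))
    best = None
    for s in starts:
        res = optimize.minimize(
            _beta_nll, np.asarray(s, dtype=float), args=(x,),
            method="L-BFGS-B", bounds=[(1e-8, None), (1e-8, None)],
            options={"ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)) or np.any(best.x <= 0):
        raise RuntimeError("beta maximum-likelihood fit did not converge")
    a, b = best.x
    n = x.size
    # observed information for the beta family is analytic (trigamma terms)
    tri_ab = polygamma(1, a + b)
    info = n * np.array(
        [
            [polygamma(1, a) - tri_ab, -tri_ab],
            [-tri_ab, polygamma(1, b) - tri_ab],
        ]
    )
    cov = np.linalg.inv(info)
    return BetaFit(
        shape_a=float(a), shape_b=float(b),
        se_a=float(np.sqrt(cov[0, 0])), se_b=float(np.sqrt(cov[1, 1])),
        loglik=-float(best.fun), n=int(n),
    )


def summarize_population(
    estimates: Sequence[ThresholdEstimate],
    n_excluded: int = 0,
    bin_width: float = 0.05,
) -> PopulationSummary:
    """Mean, histogram (default 0.05-wide bins on [0, 1]), modal interval
    and method tallies.  Physicians with undefined thresholds are counted
    but excluded from the mean and histogram."""
    if len(estimates) == 0:
        raise ValueError("no estimates to summarize")
    numeric = [e.threshold for e in estimates if e.threshold is not None]
    if len(numeric) == 0:
        raise ValueError("no numeric thresholds to summarize")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts, edges = np.histogram(numeric, bins=edges)
    k = int(np.argmax(counts))
    return PopulationSummary(
        mean_threshold=float(np.mean(numeric)),
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        modal_interval=(float(edges[k]), float(edges[k + 1])),
        n_included=len(estimates),
        n_excluded=int(n_excluded),
        method_counts=dict(Counter(e.method for e in estimates)),
    )
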