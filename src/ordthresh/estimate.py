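"""Per-physician treatment-threshold estimation — the core method.

A physician's collapsed recommendations (No < Unsure < Yes) on cases with
known disease risk r follow a proportional-odds model

    logit P(t >= j | r) = alpha_j + beta * r,   j in {Unsure, Yes}.

The treatment threshold is the risk at which Yes and No recommendations
are equally likely.  Since P(No | r) = 1 - P(t >= Unsure | r) and
P(Yes | r) = P(t >= Yes | r), setting them equal gives the closed form

    r* = -(alpha_U + alpha_Y) / (2 * beta).

The likelihood is maximized in-package by quasi-Newton iteration on
(alpha_U, gamma, beta) with alpha_Y = alpha_U - exp(gamma), which enforces
the cutpoint ordering alpha_U > alpha_Y.  Note the cumulative logit here is
P(t >= j); fitters that model P(t <= j) (e.g. statsmodels' OrderedModel)
report cutpoints c_j with alpha_j = -c_j and the same beta — convert before
applying the threshold formula, or the threshold's sign is wrong.

Physicians who never (or always) recommend treatment carry no information
about the balance point inside the observed risk range; they receive
assigned thresholds: never-treat gets the midpoint of the highest observed
case risk and 100%, always-treat the midpoint of the lowest observed risk
and 0%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .physicians import LEVELS3, collapse_responses

#: |beta| above this is treated as divergence / separation.
BETA_DIVERGENCE_BOUND = 1e4

_CODE = {lvl: i for i, lvl in enumerate(LEVELS3)}  # No=0, Unsure=1, Yes=2
_TINY = 1e-300


@dataclass(frozen=True)
class OrdinalFit:
    """Fitted proportional-odds coefficients for one physician."""

    alpha_U: float
    alpha_Y: float
    beta: float
    se_alpha_U: float
    se_alpha_Y: float
    se_beta: float
    loglik_full: float
    loglik_null: float
    n: int
    converged: bool
    separation: bool


@dataclass(frozen=True)
class BinaryFit:
    """Fitted binary logistic coefficients: logit P(Yes | r) = alpha + beta r."""

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    loglik_full: float
    loglik_null: float
    n: int
    converged: bool
    separation: bool


@dataclass
class ThresholdEstimate:
    """A physician's estimated treatment threshold with provenance."""

    physician_id: str
    threshold: float | None
    method: str  # ordinal | binary | never_treat | always_treat | separation_midpoint | undefined
    r2_nagelkerke: float | None = None
    concordance: float | None = None
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# likelihood machinery


def _encode(responses3: Sequence[str]) -> np.ndarray:
    try:
        return np.array([_CODE[x] for x in responses3])
    except KeyError as exc:
        raise ValueError(f"unknown collapsed response level: {exc.args[0]!r}") from None


def _ordinal_nll_grad(params, r, y):
    """Negative log-likelihood and gradient in (alpha_U, gamma, beta)."""
    a_u, gamma, b = params
    a_y = a_u - math.exp(gamma)
    eta_u = a_u + b * r
    eta_y = a_y + b * r
    s_u = expit(eta_u)
    s_y = expit(eta_y)
    p = np.where(y == 0, 1.0 - s_u, np.where(y == 1, s_u - s_y, s_y))
    p = np.clip(p, _TINY, 1.0)
    nll = -float(np.sum(np.log(p)))
    # dloglik/deta at each observation
    g_u = np.where(y == 0, -s_u, np.where(y == 1, s_u * (1.0 - s_u) / p, 0.0))
    g_y = np.where(y == 2, 1.0 - s_y, np.where(y == 1, -s_y * (1.0 - s_y) / p, 0.0))
    d_au = float(np.sum(g_u + g_y))
    d_gamma = float(np.sum(g_y) * (-math.exp(gamma)))
    d_b = float(np.sum((g_u + g_y) * r))
    return nll, -np.array([d_au, d_gamma, d_b])


def _ordinal_nll_grad_natural(theta, r, y):
    """Same likelihood in the natural (alpha_U, alpha_Y, beta) chart."""
    a_u, a_y, b = theta
    s_u = expit(a_u + b * r)
    s_y = expit(a_y + b * r)
    p = np.where(y == 0, 1.0 - s_u, np.where(y == 1, s_u - s_y, s_y))
    p = np.clip(p, _TINY, 1.0)
    nll = -float(np.sum(np.log(p)))
    g_u = np.where(y == 0, -s_u, np.where(y == 1, s_u * (1.0 - s_u) / p, 0.0))
    g_y = np.where(y == 2, 1.0 - s_y, np.where(y == 1, -s_y * (1.0 - s_y) / p, 0.0))
    grad = -np.array(
        [float(np.sum(g_u)), float(np.sum(g_y)), float(np.sum((g_u + g_y) * r))]
    )
    return nll, grad


def _numeric_hessian(grad_fn, theta, args):
    k = theta.size
    hess = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        hess[:, j] = (grad_fn(tp, *args)[1] - grad_fn(tm, *args)[1]) / (2 * h)
    return 0.5 * (hess + hess.T)


def _standard_errors(grad_fn, theta, args):
    try:
        hess = _numeric_hessian(grad_fn, theta, args)
        cov = np.linalg.inv(hess)
        var = np.diag(cov)
        if np.any(var <= 0):
            return np.full(theta.size, np.nan)
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return np.full(theta.size, np.nan)


def _null_loglik(y: np.ndarray) -> float:
    """Intercept-only log-likelihood from category proportions."""
    n = y.size
    ll = 0.0
    for c in np.unique(y):
        nc = int(np.sum(y == c))
        ll += nc * math.log(nc / n)
    return ll


def is_separated(risks: np.ndarray, y: np.ndarray) -> bool:
    """True when the response categories occupy disjoint, ordered risk
    ranges (in either direction), so the MLE slope diverges."""
    cats = np.unique(y)
    if cats.size < 2:
        return False
    ranges = [(risks[y == c].min(), risks[y == c].max()) for c in cats]
    asc = all(ranges[i][1] < ranges[i + 1][0] for i in range(len(ranges) - 1))
    desc = all(ranges[i + 1][1] < ranges[i][0] for i in range(len(ranges) - 1))
    return asc or desc


def fit_ordinal_model(risks, responses3) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit of collapsed responses on risk.

    Requires all three categories present (callers with a missing
    category should use the dispatcher, which routes to the degenerate or
    binary rules).  Uses three jittered starts on non-convergence;
    ``separation`` is set when the categories are perfectly separated
    along risk or |beta| exceeds :data:`BETA_DIVERGENCE_BOUND`.
    """
    r = np.asarray(risks, dtype=float)
    y = _encode(list(responses3))
    if r.size != y.size:
        raise ValueError("risks and responses must have equal length")
    if r.size < 3:
        raise ValueError("need at least 3 observations")
    if not np.all(np.isfinite(r)):
        raise ValueError("risks must be finite")
    present = set(np.unique(y))
    if present != {0, 1, 2}:
        missing = [LEVELS3[i] for i in sorted({0, 1, 2} - present)]
        raise ValueError(
            f"category {missing} absent; route via estimate_threshold"
        )
    separated = is_separated(r, y)

    p_ge_u = float(np.mean(y >= 1))
    p_ge_y = float(np.mean(y >= 2))
    logit = lambda p: math.log(p / (1.0 - p))
    a_u0 = logit(p_ge_u)
    a_y0 = logit(p_ge_y)
    gamma0 = math.log(max(a_u0 - a_y0, 0.1))
    span = max(r.max() - r.min(), 1e-3)
    starts = [
        np.array([a_u0, gamma0, 0.0]),
        np.array([a_u0, gamma0, 4.0 / span]),
        np.array([a_u0, gamma0, -4.0 / span]),
    ]
    jitter_rng = np.random.default_rng(12345)

    best = None
    for k, x0 in enumerate(starts):
        res = minimize(
            _ordinal_nll_grad, x0, args=(r, y), jac=True,
            method="BFGS", options={"gtol": 1e-8, "maxiter": 500},
        )
        ok = res.success or float(np.linalg.norm(res.jac)) < 1e-6
        if best is None or (ok and res.fun < best[0].fun - 1e-12) or (
            ok and not best[1]
        ):
            best = (res, ok)
        if ok and k == 0:
            break
        if not ok:
            starts.append(x0 + jitter_rng.normal(scale=0.5, size=3))
            if len(starts) > 6:
                break

    res, converged = best
    a_u, gamma, b = res.x
    a_y = a_u - math.exp(gamma)
    theta = np.array([a_u, a_y, b])
    ses = _standard_errors(_ordinal_nll_grad_natural, theta, (r, y))
    if abs(b) > BETA_DIVERGENCE_BOUND:
        separated = True
    return OrdinalFit(
        alpha_U=float(a_u), alpha_Y=float(a_y), beta=float(b),
        se_alpha_U=float(ses[0]), se_alpha_Y=float(ses[1]), se_beta=float(ses[2]),
        loglik_full=-float(res.fun), loglik_null=_null_loglik(y),
        n=int(r.size), converged=bool(converged), separation=bool(separated),
    )


def category_probabilities(fit: OrdinalFit, risks) -> np.ndarray:
    """(n, 3) matrix of P(No), P(Unsure), P(Yes) under a fitted model."""
    r = np.atleast_1d(np.asarray(risks, dtype=float))
    s_u = expit(fit.alpha_U + fit.beta * r)
    s_y = expit(fit.alpha_Y + fit.beta * r)
    return np.column_stack([1.0 - s_u, s_u - s_y, s_y])


def threshold_from_fit(fit: OrdinalFit) -> float:
    """Closed-form threshold r* = -(alpha_U + alpha_Y) / (2 beta).

    This is the unique risk with P(No | r) = P(Yes | r) under the fitted
    model.  A non-positive beta still yields a balance point but inverts
    its interpretation; callers flag it.
    """
    if fit.beta == 0:
        raise ZeroDivisionError("beta is zero; no finite balance point")
    return -(fit.alpha_U + fit.alpha_Y) / (2.0 * fit.beta)


# ---------------------------------------------------------------------------
# binary special case


def _binary_nll_grad(params, r, y):
    a, b = params
    eta = a + b * r
    s = expit(eta)
    p = np.where(y == 1, s, 1.0 - s)
    nll = -float(np.sum(np.log(np.clip(p, _TINY, 1.0))))
    resid = y - s
    return nll, -np.array([float(np.sum(resid)), float(np.sum(resid * r))])


def fit_binary_logistic(risks, y01) -> BinaryFit:
    """logit P(Yes | r) = alpha + beta r, fitted by the same quasi-Newton."""
    r = np.asarray(risks, dtype=float)
    y = np.asarray(y01, dtype=int)
    separated = is_separated(r, y)
    p1 = float(np.mean(y))
    a0 = math.log(p1 / (1 - p1)) if 0 < p1 < 1 else 0.0
    res = minimize(
        _binary_nll_grad, np.array([a0, 0.0]), args=(r, y), jac=True,
        method="BFGS", options={"gtol": 1e-8, "maxiter": 500},
    )
    converged = res.success or float(np.linalg.norm(res.jac)) < 1e-6
    a, b = res.x
    ses = _standard_errors(lambda t, rr, yy: _binary_nll_grad(t, rr, yy), res.x, (r, y))
    n = r.size
    ll_null = (
        n * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1)) if 0 < p1 < 1 else 0.0
    )
    if abs(b) > BETA_DIVERGENCE_BOUND:
        separated = True
    return BinaryFit(
        alpha=float(a), beta=float(b), se_alpha=float(ses[0]), se_beta=float(ses[1]),
        loglik_full=-float(res.fun), loglik_null=ll_null,
        n=int(n), converged=bool(converged), separation=bool(separated),
    )


def _separation_midpoint(r: np.ndarray, y: np.ndarray) -> float:
    """Midpoint of the gap between the top sub-Yes risk and bottom Yes risk.

    Under complete separation every risk in the gap is a maximum-likelihood
    balance point; the midpoint is the symmetric representative.
    """
    yes_code = int(y.max())
    below = r[y < yes_code]
    above = r[y == yes_code]
    return float((below.max() + above.min()) / 2.0)


def fit_binary_threshold(risks, responses, physician_id: str = "") -> ThresholdEstimate:
    """Threshold for a physician who used only No and Yes.

    The P(Yes) = 0.5 point of a binary logistic fit, threshold = -alpha/beta;
    this coincides with the ordinal formula's limit when Unsure is empty.
    """
    r = np.asarray(risks, dtype=float)
    resp = list(responses)
    levels = set(resp)
    if not levels <= {"No", "Yes"}:
        raise ValueError(f"binary fit requires only No/Yes responses, got {sorted(levels)}")
    if levels != {"No", "Yes"}:
        raise ValueError("binary fit needs at least one of each of No and Yes")
    y = np.array([1 if x == "Yes" else 0 for x in resp])
    if is_separated(r, y):
        est = ThresholdEstimate(
            physician_id=physician_id,
            threshold=_separation_midpoint(r, y),
            method="separation_midpoint",
            concordance=concordance_index(r, resp),
            warnings=["complete separation: threshold is the empirical-gap midpoint"],
        )
        return est
    fit = fit_binary_logistic(r, y)
    warnings = []
    if fit.separation:
        return ThresholdEstimate(
            physician_id=physician_id,
            threshold=_separation_midpoint(r, y),
            method="separation_midpoint",
            concordance=concordance_index(r, resp),
            warnings=["optimizer divergence: threshold is the empirical-gap midpoint"],
        )
    if abs(fit.beta) < 1e-3:
        warnings.append("slope near zero: threshold unstable")
        threshold = float("nan") if fit.beta == 0 else -fit.alpha / fit.beta
    else:
        threshold = -fit.alpha / fit.beta
    if fit.beta < 0:
        warnings.append("negative slope: recommendations decrease with risk; interpretation inverted")
    if not fit.converged:
        warnings.append("optimizer did not converge")
    r2 = _nagelkerke(fit.loglik_full, fit.loglik_null, fit.n)
    return ThresholdEstimate(
        physician_id=physician_id, threshold=threshold, method="binary",
        r2_nagelkerke=r2, concordance=concordance_index(r, resp), warnings=warnings,
    )


# ---------------------------------------------------------------------------
# degenerate rules


def degenerate_threshold(responses3, risks, physician_id: str = "") -> ThresholdEstimate:
    """Assigned thresholds for physicians without both Yes and No responses.

    Never-treat (no Yes): midpoint of the highest observed case risk and
    100% — the threshold lies somewhere above every case shown.  The
    mirror-image always-treat rule (no No) assigns the midpoint of the
    lowest observed risk and 0%.  All-Unsure physicians carry no
    information about the balance point: method ``undefined``.
    """
    resp = list(responses3)
    if len(resp) == 0:
        raise ValueError("empty response vector")
    r = np.asarray(risks, dtype=float)
    levels = set(resp)
    unknown = levels - set(LEVELS3)
    if unknown:
        raise ValueError(f"unknown collapsed response level: {sorted(unknown)[0]!r}")
    has_yes = "Yes" in levels
    has_no = "No" in levels
    if has_yes and has_no:
        raise ValueError("both Yes and No present; not a degenerate pattern")
    if not has_yes and not has_no:
        return ThresholdEstimate(
            physician_id=physician_id, threshold=None, method="undefined",
            warnings=["all responses Unsure: threshold undefined"],
        )
    if not has_yes:
        return ThresholdEstimate(
            physician_id=physician_id,
            threshold=float((r.max() + 1.0) / 2.0),
            method="never_treat",
            warnings=["no Yes responses: threshold assigned above the observed risk range"],
        )
    return ThresholdEstimate(
        physician_id=physician_id,
        threshold=float(r.min() / 2.0),
        method="always_treat",
        warnings=["no No responses: threshold assigned below the observed risk range"],
    )


# ---------------------------------------------------------------------------
# diagnostics


def _nagelkerke(ll_full: float, ll_null: float, n: int) -> float:
    if n == 0:
        raise ValueError("n must be positive")
    r2_cs = 1.0 - math.exp((2.0 / n) * (ll_null - ll_full))
    denom = 1.0 - math.exp((2.0 / n) * ll_null)
    if denom <= 0:
        return 0.0
    return min(max(r2_cs / denom, 0.0), 1.0)


def nagelkerke_r2(fit) -> float:
    """Nagelkerke pseudo-R²: Cox–Snell rescaled to a [0, 1] maximum."""
    return _nagelkerke(fit.loglik_full, fit.loglik_null, fit.n)


def concordance_index(risks, responses3) -> float | None:
    """Fraction of discordant-category case pairs ranked correctly by risk.

    Over all pairs with different collapsed categories, counts the pairs
    in which the higher-category case has strictly higher risk; risk ties
    count 0.5.  Equals ROC AUC for two categories.  ``None`` when fewer
    than two categories are present.
    """
    r = np.asarray(risks, dtype=float)
    y = _encode(collapse_responses(list(responses3)))
    cats = np.unique(y)
    if cats.size < 2:
        return None
    num = 0.0
    den = 0
    for i in range(cats.size):
        for j in range(i + 1, cats.size):
            lo = r[y == cats[i]]
            hi = r[y == cats[j]]
            diff = hi[:, None] - lo[None, :]
            num += float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
            den += lo.size * hi.size
    return num / den


# ---------------------------------------------------------------------------
# dispatcher


def estimate_threshold(responses: pd.DataFrame, risks: pd.DataFrame) -> ThresholdEstimate:
    """Estimate one physician's treatment threshold from their records.

    ``responses`` holds one physician's rows (``physician_id, case_id,
    response`` on the 7-point or collapsed scale); ``risks`` maps
    ``case_id`` to ``risk``.  The 7-point scale is collapsed, then the
    estimate is routed: degenerate rules when Yes or No is absent, binary
    logistic when Unsure is absent, otherwise the ordinal fit; complete
    separation falls back to the empirical-gap midpoint.
    """
    if len(responses) == 0:
        raise ValueError("empty response table")
    pids = responses["physician_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected one physician, got {len(pids)}")
    physician_id = str(pids[0])
    risk_map = dict(zip(risks["case_id"], risks["risk"]))
    missing = [c for c in responses["case_id"] if c not in risk_map]
    if missing:
        raise ValueError(f"case_ids not present in risk table: {sorted(set(missing))}")
    r = np.array([risk_map[c] for c in responses["case_id"]], dtype=float)
    resp3 = collapse_responses(responses["response"].tolist())
    levels = set(resp3)

    if "Yes" not in levels or "No" not in levels:
        return degenerate_threshold(resp3, r, physician_id)
    if "Unsure" not in levels:
        return fit_binary_threshold(r, resp3, physician_id)

    y = _encode(resp3)
    if is_separated(r, y):
        return ThresholdEstimate(
            physician_id=physician_id,
            threshold=_separation_midpoint(r, y),
            method="separation_midpoint",
            concordance=concordance_index(r, resp3),
            warnings=["complete separation: threshold is the empirical-gap midpoint"],
        )
    fit = fit_ordinal_model(r, resp3)
    if fit.separation:
        return ThresholdEstimate(
            physician_id=physician_id,
            threshold=_separation_midpoint(r, y),
            method="separation_midpoint",
            concordance=concordance_index(r, resp3),
            warnings=["optimizer divergence: threshold is the empirical-gap midpoint"],
        )
    warnings = []
    if fit.beta <= 0:
        warnings.append("non-positive slope: recommendations decrease with risk; interpretation inverted")
    if not fit.converged:
        warnings.append("optimizer did not converge")
    return ThresholdEstimate(
        physician_id=physician_id,
        threshold=threshold_from_fit(fit),
        method="ordinal",
        r2_nagelkerke=nagelkerke_r2(fit),
        concordance=concordance_index(r, resp3),
        warnings=warnings,
    )
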