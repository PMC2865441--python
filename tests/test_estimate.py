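"""Threshold estimation: closed form, likelihood fits, routing, degenerate rules."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.special import expit

from ordthresh import (
    OrdinalFit,
    PhysicianParams,
    degenerate_threshold,
    estimate_threshold,
    fit_binary_threshold,
    fit_ordinal_model,
    simulate_responses,
    threshold_from_fit,
)
from ordthresh.estimate import category_probabilities, is_separated


def _make_fit(alpha_U, alpha_Y, beta, n=100):
    return OrdinalFit(
        alpha_U=alpha_U, alpha_Y=alpha_Y, beta=beta,
        se_alpha_U=np.nan, se_alpha_Y=np.nan, se_beta=np.nan,
        loglik_full=0.0, loglik_null=0.0, n=n, converged=True, separation=False,
    )


def _sample_3level(rng, risks, alpha_U, alpha_Y, beta):
    """Draw collapsed responses directly from the cumulative-logit model."""
    p_ge_u = expit(alpha_U + beta * risks)
    p_ge_y = expit(alpha_Y + beta * risks)
    u = rng.random(risks.size)
    y = (u <= p_ge_u).astype(int) + (u <= p_ge_y)
    return [("No", "Unsure", "Yes")[i] for i in y]


class TestClosedForm:
    def test_symmetric_intercepts_give_zero(self):
        assert threshold_from_fit(_make_fit(2.0, -2.0, 10.0)) == pytest.approx(0.0)

    def test_arithmetic_with_balance_verified(self):
        fit = _make_fit(-1.0, -6.0, 25.0)
        r_star = threshold_from_fit(fit)
        assert r_star == pytest.approx(0.14)
        p = category_probabilities(fit, r_star)[0]
        assert p[0] == pytest.approx(expit(-2.5))  # P(No)
        assert p[2] == pytest.approx(expit(-2.5))  # P(Yes)

    @pytest.mark.parametrize("coeffs", [(-0.5, -4.0, 20.0), (-1.0, -6.0, 25.0)])
    def test_matches_bisection_root(self, coeffs):
        fit = _make_fit(*coeffs)

        def imbalance(r):
            p = category_probabilities(fit, r)[0]
            return p[2] - p[0]

        r_star = threshold_from_fit(fit)
        root = brentq(imbalance, r_star - 1.0, r_star + 1.0, xtol=1e-12)
        assert abs(r_star - root) <= 1e-9

    def test_zero_slope_has_no_balance_point(self):
        with pytest.raises(ZeroDivisionError):
            threshold_from_fit(_make_fit(1.0, -1.0, 0.0))


class TestOrdinalFit:
    def test_generative_parameter_recovery(self):
        """Fitted coefficients land within 3 reported SEs of the truth."""
        rng = np.random.default_rng(42)
        risks = rng.uniform(0.01, 0.99, 2000)
        truth = (-1.0, -6.0, 25.0)
        resp = _sample_3level(rng, risks, *truth)
        fit = fit_ordinal_model(risks, resp)
        assert fit.converged and not fit.separation
        assert abs(fit.alpha_U - truth[0]) < 3 * fit.se_alpha_U
        assert abs(fit.alpha_Y - truth[1]) < 3 * fit.se_alpha_Y
        assert abs(fit.beta - truth[2]) < 3 * fit.se_beta

    def test_permuted_responses_fit_like_null(self):
        rng = np.random.default_rng(3)
        risks = rng.uniform(0.01, 0.99, 1000)
        resp = _sample_3level(rng, risks, -1.0, -6.0, 25.0)
        permuted = list(rng.permutation(resp))
        fit = fit_ordinal_model(risks, permuted)
        # likelihood-ratio statistic ~ chi2(1) under independence
        assert 2 * (fit.loglik_full - fit.loglik_null) < 11.0
        assert abs(fit.beta) < 3 * fit.se_beta

    def test_full_loglik_dominates_null(self):
        rng = np.random.default_rng(17)
        risks = rng.uniform(0.01, 0.99, 200)
        resp = _sample_3level(rng, risks, -0.5, -3.0, 12.0)
        fit = fit_ordinal_model(risks, resp)
        assert fit.loglik_full >= fit.loglik_null - 1e-8
        assert fit.alpha_U >= fit.alpha_Y

    def test_complete_separation_is_flagged(self):
        risks = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
        resp = ["No", "No", "Unsure", "Unsure", "Yes", "Yes"]
        fit = fit_ordinal_model(risks, resp)
        assert fit.separation

    def test_missing_category_routed_elsewhere(self):
        with pytest.raises(ValueError, match="absent"):
            fit_ordinal_model([0.1, 0.2, 0.3, 0.4], ["No", "No", "Yes", "Yes"])

    def test_sign_convention_matches_reference_fitter(self):
        """statsmodels' OrderedModel fits P(t <= j) = F(c_j - beta r); our
        P(t >= j) parameterization must satisfy alpha_j = -c_j with the
        same slope — the conversion the threshold formula depends on."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(10)
        risks = rng.uniform(0.01, 0.99, 1500)
        resp = _sample_3level(rng, risks, -1.0, -5.0, 18.0)
        fit = fit_ordinal_model(risks, resp)

        codes = pd.Series(
            pd.Categorical(resp, categories=["No", "Unsure", "Yes"], ordered=True)
        )
        sm_fit = OrderedModel(codes, risks[:, None], distr="logit").fit(
            method="bfgs", disp=False
        )
        beta_sm = float(np.asarray(sm_fit.params)[0])
        c = OrderedModel(codes, risks[:, None], distr="logit").transform_threshold_params(
            sm_fit.params
        )[1:-1]
        assert fit.beta == pytest.approx(beta_sm, abs=1e-2 * abs(beta_sm))
        assert fit.alpha_U == pytest.approx(-c[0], abs=1e-2 * abs(c[0]))
        assert fit.alpha_Y == pytest.approx(-c[1], abs=1e-2 * abs(c[1]))
        assert fit.loglik_full == pytest.approx(sm_fit.llf, abs=1e-4)


class TestBinaryFallback:
    def test_recovers_known_threshold(self):
        """logit P(Yes) = -3 + 30 r puts the balance point at 0.1."""
        rng = np.random.default_rng(23)
        risks = rng.uniform(0.001, 0.999, 2000)
        y = rng.random(2000) < expit(-3.0 + 30.0 * risks)
        resp = ["Yes" if v else "No" for v in y]
        est = fit_binary_threshold(risks, resp, "p1")
        assert est.method == "binary"
        assert est.threshold == pytest.approx(0.1, abs=0.01)
        assert est.r2_nagelkerke is not None and est.concordance is not None

    def test_uninformative_data_warns(self):
        # one Yes and one No at every risk level: the MLE slope is zero
        risks = np.repeat([0.1, 0.2, 0.3, 0.4], 2)
        resp = (["Yes", "No"] * 4)
        est = fit_binary_threshold(risks, resp, "p1")
        assert any("unstable" in w for w in est.warnings)

    def test_separation_falls_back_to_midpoint(self):
        risks = np.array([0.05, 0.1, 0.3, 0.4])
        est = fit_binary_threshold(risks, ["No", "No", "Yes", "Yes"], "p1")
        assert est.method == "separation_midpoint"
        assert est.threshold == pytest.approx(0.2)


class TestDegenerateRules:
    def test_never_treat_rule(self):
        est = degenerate_threshold(["No", "Unsure", "No"], [0.1, 0.42, 0.2], "p1")
        assert est.method == "never_treat"
        assert est.threshold == pytest.approx(0.71)

    def test_always_treat_rule(self):
        est = degenerate_threshold(["Yes", "Unsure", "Yes"], [0.02, 0.3, 0.4], "p1")
        assert est.method == "always_treat"
        assert est.threshold == pytest.approx(0.01)

    def test_all_unsure_is_undefined(self):
        est = degenerate_threshold(["Unsure"] * 3, [0.1, 0.2, 0.3], "p1")
        assert est.method == "undefined"
        assert est.threshold is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            degenerate_threshold([], [], "p1")


def _records(physician_id, case_ids, responses):
    return pd.DataFrame(
        {"physician_id": physician_id, "case_id": case_ids, "response": responses}
    )


class TestDispatcher:
    def _risk_df(self, risks):
        return pd.DataFrame(
            {"case_id": [f"c{i}" for i in range(len(risks))], "risk": risks}
        )

    def test_routes_mixed_responses_to_ordinal(self):
        rng = np.random.default_rng(1)
        risks = rng.uniform(0.01, 0.99, 300)
        resp = _sample_3level(rng, risks, -1.0, -5.0, 15.0)
        records = _records("p1", [f"c{i}" for i in range(300)], resp)
        est = estimate_threshold(records, self._risk_df(risks))
        assert est.method == "ordinal"
        assert est.r2_nagelkerke is not None

    def test_routes_two_extreme_levels_to_binary(self):
        rng = np.random.default_rng(2)
        risks = rng.uniform(0.01, 0.99, 400)
        resp = [
            "DefinitelyYes" if rng.random() < expit(-4 + 20 * r) else "DefinitelyNo"
            for r in risks
        ]
        records = _records("p1", [f"c{i}" for i in range(400)], resp)
        est = estimate_threshold(records, self._risk_df(risks))
        assert est.method == "binary"

    def test_unjoinable_case_ids_rejected(self):
        records = _records("p1", ["c0", "cX"], ["DefinitelyNo", "DefinitelyYes"])
        with pytest.raises(ValueError, match="cX"):
            estimate_threshold(records, self._risk_df([0.1, 0.2]))

    def test_generative_recovery_through_full_path(self):
        """7-point simulation, collapse, fit: recovered within +/-0.02."""
        p = PhysicianParams("p1", threshold=0.20, discrimination=40.0)
        rng = np.random.default_rng(31)
        risks = rng.uniform(0.01, 0.99, 500)
        resp = simulate_responses([p], risks, seed=77)
        risk_df = pd.DataFrame({"case_id": resp["case_id"].unique(), "risk": risks})
        est = estimate_threshold(resp, risk_df)
        assert est.method == "ordinal"
        assert est.threshold == pytest.approx(0.20, abs=0.02)

    def test_affine_equivariance(self):
        """Refit on r' = a r + b shifts the threshold to a r* + b."""
        rng = np.random.default_rng(8)
        risks = rng.uniform(0.01, 0.99, 800)
        resp = _sample_3level(rng, risks, -1.0, -6.0, 25.0)
        fit = fit_ordinal_model(risks, resp)
        a, b = 0.5, 0.2
        fit2 = fit_ordinal_model(a * risks + b, resp)
        assert threshold_from_fit(fit2) == pytest.approx(
            a * threshold_from_fit(fit) + b, abs=1e-6
        )

    def test_percent_scale_unit_invariance(self):
        """Fitting on risks x100 returns 100x the proportion threshold."""
        rng = np.random.default_rng(9)
        risks = rng.uniform(0.01, 0.99, 800)
        resp = _sample_3level(rng, risks, -1.0, -6.0, 25.0)
        t_prop = threshold_from_fit(fit_ordinal_model(risks, resp))
        t_pct = threshold_from_fit(fit_ordinal_model(100.0 * risks, resp))
        assert t_pct == pytest.approx(100.0 * t_prop, rel=1e-4)

    def test_binary_consistency_with_ordinal_limit(self):
        """With Unsure empty the binary threshold is the P=0.5 point, the
        limit of the ordinal balance definition."""
        rng = np.random.default_rng(12)
        risks = rng.uniform(0.001, 0.999, 1500)
        y = rng.random(1500) < expit(-5.0 + 25.0 * risks)
        resp = ["Yes" if v else "No" for v in y]
        est = fit_binary_threshold(risks, resp, "p1")
        # balance point of the fitted binary model, found independently
        from ordthresh.estimate import fit_binary_logistic

        fit = fit_binary_logistic(risks, np.array(y, dtype=int))
        root = brentq(lambda r: expit(fit.alpha + fit.beta * r) - 0.5, -2, 3, xtol=1e-12)
        assert est.threshold == pytest.approx(root, abs=1e-9)
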