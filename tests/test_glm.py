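"""Tests for design matrices and the three model-family fitters.

Fitters are checked against closed forms where they exist and against an
independent brute-force likelihood maximization (Nelder-Mead on the
log-likelihood written out directly) on small problems.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from rtelab.errors import ConfigError, EstimabilityError, FitError
from rtelab.glm import (
    DesignSpec,
    build_design_matrix,
    fit_binomial_logit,
    fit_gaussian_lm,
    fit_geometric,
    wald_test,
)

FACTORS = ("ecotype", "habitat", "provenance", "plantation", "status")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


class TestDesignMatrix:
    def test_two_level_sum_to_zero_is_plus_minus_one(self):
        df = pd.DataFrame({"ecotype": ["glo", "sp1", "glo"]})
        X, labels, spec = build_design_matrix(
            df, DesignSpec.from_strings(["ecotype"], FACTORS)
        )
        assert labels == ["(Intercept)", "ecotype[glo]"]
        assert X[:, 1].tolist() == [1.0, -1.0, 1.0]

    def test_treatment_coding(self):
        df = pd.DataFrame({"ecotype": ["glo", "sp1", "glo"]})
        X, labels, _ = build_design_matrix(
            df, DesignSpec.from_strings(["ecotype"], FACTORS, coding="treatment")
        )
        assert labels == ["(Intercept)", "ecotype[sp1]"]
        assert X[:, 1].tolist() == [0.0, 1.0, 0.0]

    def test_germination_term_structure_column_count(self):
        # intercept + e + o + e:o + t + t:e + t:o -> 7 columns for two
        # 2-level factors and one covariate
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "ecotype": rng.choice(["glo", "sp1"], 40),
                "provenance": rng.choice(["E", "W"], 40),
                "shadehouse_days": rng.integers(27, 316, 40),
            }
        )
        X, labels, _ = build_design_matrix(
            df,
            DesignSpec.from_strings(
                [
                    "ecotype",
                    "provenance",
                    "ecotype:provenance",
                    "shadehouse_days",
                    "shadehouse_days:ecotype",
                    "shadehouse_days:provenance",
                ],
                FACTORS,
            ),
        )
        assert X.shape[1] == len(labels) == 7

    def test_unobserved_cell_raises_estimability_error(self):
        # ecotype confounded with provenance: the e:o crossing is incomplete
        df = pd.DataFrame(
            {
                "ecotype": ["glo"] * 5 + ["sp1"] * 5,
                "provenance": ["E"] * 5 + ["W"] * 5,
            }
        )
        with pytest.raises(EstimabilityError, match="unobserved cells"):
            build_design_matrix(
                df,
                DesignSpec.from_strings(
                    ["ecotype", "provenance", "ecotype:provenance"], FACTORS
                ),
            )

    def test_row_matches_matrix(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "ecotype": rng.choice(["glo", "sp1"], 20),
                "habitat": rng.choice(["SF", "HT"], 20),
                "age": rng.integers(0, 6, 20),
            }
        )
        spec = DesignSpec.from_strings(
            ["ecotype", "habitat", "ecotype:habitat", "age", "age:ecotype"], FACTORS
        )
        X, _, resolved = build_design_matrix(df, spec)
        for i in range(len(df)):
            row = resolved.row(df.iloc[i].to_dict())
            np.testing.assert_allclose(row, X[i], atol=1e-12)

    def test_prediction_invariant_to_coding(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "ecotype": rng.choice(["glo", "sp1"], 60),
                "habitat": rng.choice(["SF", "HT"], 60),
            }
        )
        y = rng.normal(size=60)
        preds = {}
        for coding in ("sum_to_zero", "treatment"):
            X, labels, spec = build_design_matrix(
                df,
                DesignSpec.from_strings(
                    ["ecotype", "habitat", "ecotype:habitat"], FACTORS, coding=coding
                ),
            )
            fit = fit_gaussian_lm(y, X, labels=labels, spec=spec)
            preds[coding] = [
                fit.predict_eta({"ecotype": e, "habitat": h})
                for e in ("glo", "sp1")
                for h in ("SF", "HT")
            ]
        np.testing.assert_allclose(preds["sum_to_zero"], preds["treatment"], atol=1e-10)


# ---------------------------------------------------------------------------
# binomial logit
# ---------------------------------------------------------------------------


class TestBinomialLogit:
    def test_intercept_only_even_split(self):
        y = np.array([0, 1] * 10, dtype=float)
        fit = fit_binomial_logit(y, np.ones((20, 1)))
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_seven_of_ten(self):
        y = np.array([1] * 7 + [0] * 3, dtype=float)
        fit = fit_binomial_logit(y, np.ones((10, 1)))
        assert fit.params[0] == pytest.approx(math.log(7 / 3), abs=1e-8)
        # SE of logit(p-hat): sqrt(1/(n p (1-p)))
        assert fit.se[0] == pytest.approx(math.sqrt(1 / (10 * 0.7 * 0.3)), rel=1e-6)

    def test_parameter_recovery_three_se(self):
        rng = np.random.default_rng(7)
        n = 5000
        X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n), rng.uniform(0, 1, n)])
        beta = np.array([-0.5, 0.8, 1.2])
        y = (rng.random(n) < _expit(X @ beta)).astype(float)
        fit = fit_binomial_logit(y, X)
        assert np.all(np.abs(fit.params - beta) < 3 * fit.se)

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(11)
        n = 40
        X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n)])
        y = (rng.random(n) < _expit(X @ [0.3, -0.6])).astype(float)

        def negll(b):
            p = _expit(X @ b)
            return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        res = optimize.minimize(
            negll, np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000},
        )
        fit = fit_binomial_logit(y, X)
        np.testing.assert_allclose(fit.params, res.x, atol=1e-6)

    def test_fisher_information_matches_finite_difference_hessian(self):
        rng = np.random.default_rng(13)
        n = 200
        X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n)])
        y = (rng.random(n) < _expit(X @ [0.2, 0.5])).astype(float)
        fit = fit_binomial_logit(y, X)

        def ll(b):
            p = _expit(X @ b)
            return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        H = _fd_hessian(ll, fit.params)
        info = np.linalg.inv(fit.cov)
        np.testing.assert_allclose(info, -H, rtol=1e-4)

    def test_separation_flagged_and_penalized(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        X = np.column_stack([np.ones(20), np.repeat([-1.0, 1.0], 10)])
        fit = fit_binomial_logit(y, X)
        assert any("separation" in w for w in fit.warnings)
        assert np.all(np.isfinite(fit.params))

    def test_non_binary_response_rejected(self):
        with pytest.raises(ConfigError):
            fit_binomial_logit(np.array([0.0, 0.5, 1.0]), np.ones((3, 1)))


# ---------------------------------------------------------------------------
# geometric
# ---------------------------------------------------------------------------


class TestGeometric:
    def test_closed_form_uncensored(self):
        k = np.array([0.0, 1.0, 2.0])
        fit = fit_geometric(k, np.zeros(3, dtype=bool), np.ones((3, 1)))
        q = _expit(fit.params[0])
        assert q == pytest.approx(3 / 6, abs=1e-8)

    def test_closed_form_with_censoring(self):
        # lik: q^sum(k) (1-q)^n_uncens -> q = sum(k)/(sum(k)+n_uncens)
        k = np.array([1.0, 2.0, 4.0, 3.0])
        cens = np.array([False, False, True, True])
        fit = fit_geometric(k, cens, np.ones((4, 1)))
        assert _expit(fit.params[0]) == pytest.approx(10 / 12, abs=1e-8)

    def test_all_die_immediately_boundary(self):
        fit = fit_geometric(np.zeros(5), np.zeros(5, dtype=bool), np.ones((5, 1)))
        assert _expit(fit.params[0]) == 0.0
        assert fit.warnings

    def test_all_censored_not_identifiable(self):
        with pytest.raises(FitError, match="censored"):
            fit_geometric(np.array([2.0, 3.0]), np.array([True, True]), np.ones((2, 1)))

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(5)
        n = 50
        X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n)])
        q = _expit(X @ [1.0, 0.4])
        k = rng.geometric(1 - q) - 1  # failures before first death
        cens = k >= 6
        k = np.minimum(k, 6).astype(float)

        def negll(b):
            qq = _expit(X @ b)
            return -np.sum(k * np.log(qq) + (~cens) * np.log(1 - qq))

        res = optimize.minimize(
            negll, np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000},
        )
        fit = fit_geometric(k, cens, X)
        np.testing.assert_allclose(fit.params, res.x, atol=1e-6)

    def test_observed_information_matches_finite_difference(self):
        rng = np.random.default_rng(6)
        n = 150
        X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n)])
        q = _expit(X @ [1.2, 0.3])
        k = (rng.geometric(1 - q) - 1).astype(float)
        cens = np.zeros(n, dtype=bool)
        fit = fit_geometric(k, cens, X)

        def ll(b):
            qq = _expit(X @ b)
            return np.sum(k * np.log(qq) + np.log(1 - qq))

        H = _fd_hessian(ll, fit.params)
        np.testing.assert_allclose(np.linalg.inv(fit.cov), -H, rtol=1e-4)

    def test_recovery_calibrated_to_study_survival(self):
        # ~37% alive after 6 yearly trials -> q around 0.85
        rng = np.random.default_rng(17)
        n = 2000
        X = np.column_stack(
            [np.ones(n), rng.choice([-1.0, 1.0], n), rng.choice([-1.0, 1.0], n)]
        )
        beta = np.array([1.75, 0.3, -0.2])
        q = _expit(X @ beta)
        k = rng.geometric(1 - q) - 1
        cens = k >= 6
        k = np.minimum(k, 6).astype(float)
        assert 0.25 < cens.mean() < 0.5
        fit = fit_geometric(k, cens, X)
        assert np.all(np.abs(fit.params - beta) < 3 * fit.se)

    def test_log_on_mean_link_same_likelihood(self):
        k = np.array([2.0, 5.0, 1.0, 0.0, 3.0])
        cens = np.array([False, True, False, False, False])
        f1 = fit_geometric(k, cens, np.ones((5, 1)), link="logit_on_survival")
        f2 = fit_geometric(k, cens, np.ones((5, 1)), link="log_on_mean")
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-10)
        # log link: exp(eta) is the mean number of waiting periods q/(1-q)
        q = _expit(f2.params[0])
        assert math.exp(f2.params[0]) == pytest.approx(q / (1 - q), rel=1e-10)


# ---------------------------------------------------------------------------
# gaussian
# ---------------------------------------------------------------------------


class TestGaussianLM:
    def test_exact_fit_zero_sigma(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        beta = np.array([2.0, -1.5])
        fit = fit_gaussian_lm(X @ beta, X)
        np.testing.assert_allclose(fit.params, beta, atol=1e-12)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_hand_arithmetic_mean_model(self):
        fit = fit_gaussian_lm(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)))
        assert fit.params[0] == pytest.approx(2.0)
        assert fit.sigma2 == pytest.approx(1.0)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        n = 2000
        X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n), rng.uniform(0, 5, n)])
        beta = np.array([1.0, 0.25, -0.4])
        y = X @ beta + rng.normal(0, 0.7, n)
        fit = fit_gaussian_lm(y, X)
        assert np.all(np.abs(fit.params - beta) < 3 * fit.se)

    def test_underdetermined_rejected(self):
        with pytest.raises(FitError, match="underdetermined"):
            fit_gaussian_lm(np.array([1.0, 2.0]), np.eye(2))

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        fit = fit_gaussian_lm(y, X)
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.params, expected, atol=1e-10)


# ---------------------------------------------------------------------------
# wald test
# ---------------------------------------------------------------------------


class TestWald:
    def test_zero_contrast_row(self):
        fit = fit_gaussian_lm(np.arange(10.0), np.ones((10, 1)))
        stat, df, p = wald_test(fit, np.zeros((1, 1)))
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(21)
        n, reps = 510, 2000
        X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n)])
        L = np.array([[0.0, 1.0]])
        pvals = []
        for _ in range(reps):
            y = rng.normal(size=n)
            fit = fit_gaussian_lm(y, X)
            pvals.append(wald_test(fit, L)[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_power_against_four_se_effect(self):
        # effect sized at 4 SE of the slope estimator: empirical rejection
        # rate at p < 0.001 must match the analytic Wald power
        rng = np.random.default_rng(22)
        n, reps = 400, 1000
        X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n)])
        beta1 = 4.0 / math.sqrt(n)  # sigma=1 -> SE = 1/sqrt(n)
        L = np.array([[0.0, 1.0]])
        hits = 0
        for _ in range(reps):
            y = X @ [0.0, beta1] + rng.normal(size=n)
            if wald_test(fit_gaussian_lm(y, X), L)[2] < 0.001:
                hits += 1
        z = stats.norm.ppf(1 - 0.001 / 2)
        analytic = stats.norm.sf(z - 4.0) + stats.norm.cdf(-z - 4.0)
        assert hits / reps == pytest.approx(analytic, abs=0.05)

    def test_json_round_trip(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame({"ecotype": rng.choice(["glo", "sp1"], 30)})
        X, labels, spec = build_design_matrix(
            df, DesignSpec.from_strings(["ecotype"], FACTORS)
        )
        fit = fit_gaussian_lm(rng.normal(size=30), X, labels=labels, spec=spec)
        from rtelab.glm import ModelFit

        fit2 = ModelFit.from_json(fit.to_json())
        np.testing.assert_allclose(fit2.params, fit.params)
        np.testing.assert_allclose(fit2.cov, fit.cov)
        assert fit2.spec.levels == fit.spec.levels


def _fd_hessian(f, x, eps=1e-5):
    p = len(x)
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            xpp = x.copy(); xpp[[i, j]] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[[i, j]] -= eps
            if i == j:
                xpp = x.copy(); xpp[i] += 2 * eps
                xmm = x.copy(); xmm[i] -= 2 * eps
                H[i, j] = (f(xpp) - 2 * f(x) + f(xmm)) / (4 * eps**2)
            else:
                H[i, j] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return H
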