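"""Tests for adjusted means, pairwise comparisons, and the home/away contrast."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rtelab.adaptation import (
    ECOTYPE_HABITAT_AWAY,
    ECOTYPE_HABITAT_HOME,
    _adjust_p,
    germination_overall_lsmeans,
    germination_time_comparison,
    home_away_contrast,
    lsmean,
    star_code,
)
from rtelab.errors import EstimabilityError
from rtelab.glm import (
    DesignSpec,
    ModelFit,
    build_design_matrix,
    fit_binomial_logit,
    fit_gaussian_lm,
    fit_geometric,
)
from rtelab.models import FACTORS, fit_growth_from_frames
from rtelab.simulate import simulate_frames
from tests.conftest import null_growth_config


def _manual_fit(df, terms, cell_values, coding="sum_to_zero", family="binomial_logit"):
    """A fit whose predictions hit ``cell_values`` exactly: params solved
    from the cell design rows, identity covariance."""
    spec = DesignSpec.from_strings(terms, FACTORS, coding=coding).resolve(df)
    rows = np.array([spec.row(cell) for cell in cell_values])
    values = np.array([v for v in cell_values.values()])
    params = np.linalg.solve(rows, values)
    return ModelFit(
        family=family,
        params=params,
        cov=np.eye(len(params)),
        labels=[f"b{i}" for i in range(len(params))],
        loglik=0.0,
        deviance=0.0,
        n_obs=len(df),
        n_iter=1,
        converged=True,
        spec=spec,
        df_resid=max(len(df) - len(params), 1),
    )


class _FrozenDict(dict):
    def __hash__(self):
        return hash(tuple(sorted(self.items())))


def _cells_df():
    return pd.DataFrame(
        [
            {"ecotype": e, "provenance": o}
            for e in ("glo", "sp1")
            for o in ("E", "W")
        ]
    )


class TestLSMean:
    def test_saturated_two_by_two_average(self):
        # cell logits (glo,E)=0 (glo,W)=1 (sp1,E)=2 (sp1,W)=3; averaging the
        # glo row over provenance gives 0.5 on the logit scale
        cells = {
            _FrozenDict({"ecotype": "glo", "provenance": "E"}): 0.0,
            _FrozenDict({"ecotype": "glo", "provenance": "W"}): 1.0,
            _FrozenDict({"ecotype": "sp1", "provenance": "E"}): 2.0,
            _FrozenDict({"ecotype": "sp1", "provenance": "W"}): 3.0,
        }
        fit = _manual_fit(
            _cells_df(), ["ecotype", "provenance", "ecotype:provenance"], cells
        )
        m = lsmean(fit, {"ecotype": "glo"}, ["provenance"])
        assert m.estimate == pytest.approx(0.5, abs=1e-12)
        assert m.weights @ fit.params == pytest.approx(m.estimate)

    def test_zero_nuisance_effects_reduce_to_cell_prediction(self):
        cells = {
            _FrozenDict({"ecotype": "glo", "provenance": "E"}): 1.25,
            _FrozenDict({"ecotype": "glo", "provenance": "W"}): 1.25,
            _FrozenDict({"ecotype": "sp1", "provenance": "E"}): -0.75,
            _FrozenDict({"ecotype": "sp1", "provenance": "W"}): -0.75,
        }
        fit = _manual_fit(
            _cells_df(), ["ecotype", "provenance", "ecotype:provenance"], cells
        )
        m = lsmean(fit, {"ecotype": "glo"}, ["provenance"])
        assert m.estimate == pytest.approx(
            fit.predict_eta({"ecotype": "glo", "provenance": "E"}), abs=1e-12
        )

    @pytest.mark.parametrize("coding", ["sum_to_zero", "treatment"])
    def test_brute_force_oracle_small_n(self, coding):
        # every LS mean equals the enumerated average of cell predictions
        rng = np.random.default_rng(31)
        for rep in range(5):
            n = int(rng.integers(24, 51))
            df = pd.DataFrame(
                {
                    "ecotype": rng.choice(["glo", "sp1"], n),
                    "habitat": rng.choice(["SF", "HT"], n),
                    "status": rng.choice(["seed", "seedling"], n),
                    "age": rng.integers(0, 6, n).astype(float),
                }
            )
            y = rng.normal(size=n)
            try:
                X, labels, spec = build_design_matrix(
                    df,
                    DesignSpec.from_strings(
                        ["ecotype", "habitat", "ecotype:habitat", "status", "age"],
                        FACTORS,
                        coding=coding,
                    ),
                )
            except EstimabilityError:
                continue
            fit = fit_gaussian_lm(y, X, labels=labels, spec=spec)
            for e in ("glo", "sp1"):
                m = lsmean(fit, {"ecotype": e}, ["habitat", "status"], at={"age": 2})
                brute = np.mean(
                    [
                        fit.predict_eta(
                            {"ecotype": e, "habitat": h, "status": s, "age": 2}
                        )
                        for h in ("SF", "HT")
                        for s in ("seed", "seedling")
                    ]
                )
                assert abs(m.estimate - brute) <= 1e-10

    def test_missing_covariate_named(self):
        cells = {
            _FrozenDict({"ecotype": "glo", "provenance": "E"}): 0.0,
            _FrozenDict({"ecotype": "glo", "provenance": "W"}): 1.0,
            _FrozenDict({"ecotype": "sp1", "provenance": "E"}): 2.0,
            _FrozenDict({"ecotype": "sp1", "provenance": "W"}): 3.0,
        }
        fit = _manual_fit(
            _cells_df(), ["ecotype", "provenance", "ecotype:provenance"], cells
        )
        with pytest.raises(EstimabilityError, match="ecotype"):
            lsmean(fit, {}, ["provenance"])


class TestHomeAwayContrast:
    def _growth_fit(self, d, seed, coding="sum_to_zero"):
        ind, meas = simulate_frames(null_growth_config(d=d), seed)
        return fit_growth_from_frames(ind, meas, "height_cm", coding=coding)

    def test_symmetric_effects_give_zero_contrast(self):
        cells = {}
        for e, h in itertools.product(("glo", "sp1"), ("SF", "HT")):
            cells[_FrozenDict({"ecotype": e, "habitat": h})] = 0.7
        df = pd.DataFrame([dict(c) for c in cells])
        fit = _manual_fit(df, ["ecotype", "habitat", "ecotype:habitat"], cells)
        res = home_away_contrast(fit, ECOTYPE_HABITAT_HOME, ECOTYPE_HABITAT_AWAY, [])
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_planted_home_advantage_recovers_four_d(self):
        d = 0.25
        fit = self._growth_fit(d, seed=77)
        res = home_away_contrast(
            fit,
            ECOTYPE_HABITAT_HOME,
            ECOTYPE_HABITAT_AWAY,
            ["provenance", "plantation", "status"],
            at={"age": 0},
        )
        assert abs(res.estimate - 4 * d) < 4 * res.se
        assert res.p_value < 0.001
        assert res.stars == "***"

    def test_label_swap_flips_sign(self):
        fit = self._growth_fit(0.2, seed=78)
        args = (["provenance", "plantation", "status"],)
        res = home_away_contrast(
            fit, ECOTYPE_HABITAT_HOME, ECOTYPE_HABITAT_AWAY, *args, at={"age": 3}
        )
        swapped = home_away_contrast(
            fit, ECOTYPE_HABITAT_AWAY, ECOTYPE_HABITAT_HOME, *args, at={"age": 3}
        )
        assert swapped.estimate == pytest.approx(-res.estimate, abs=1e-12)
        assert abs(swapped.statistic) == pytest.approx(abs(res.statistic), abs=1e-12)

    def test_coding_invariance(self):
        res = {}
        for coding in ("sum_to_zero", "treatment"):
            fit = self._growth_fit(0.15, seed=79, coding=coding)
            res[coding] = home_away_contrast(
                fit,
                ECOTYPE_HABITAT_HOME,
                ECOTYPE_HABITAT_AWAY,
                ["provenance", "plantation", "status"],
                at={"age": 4},
            )
        assert res["sum_to_zero"].estimate == pytest.approx(
            res["treatment"].estimate, abs=1e-9
        )
        assert res["sum_to_zero"].se == pytest.approx(res["treatment"].se, abs=1e-9)

    def test_contrast_grows_with_age_under_diverging_interactions(self):
        # age interactions planted to diverge: C_a increases with age
        cfg = null_growth_config(d=0.0)
        growth = dict(cfg.growth)
        gc = growth["height_cm"]
        from dataclasses import replace

        growth["height_cm"] = replace(
            gc,
            age_ecotype_habitat={
                ("glo", "SF"): 0.05,
                ("sp1", "HT"): 0.05,
                ("glo", "HT"): -0.05,
                ("sp1", "SF"): -0.05,
            },
        )
        cfg = replace(cfg, growth=growth)
        ind, meas = simulate_frames(cfg, 80)
        fit = fit_growth_from_frames(ind, meas, "height_cm")
        estimates = [
            home_away_contrast(
                fit,
                ECOTYPE_HABITAT_HOME,
                ECOTYPE_HABITAT_AWAY,
                ["provenance", "plantation", "status"],
                at={"age": a},
            ).estimate
            for a in (0, 1, 2, 4, 5)
        ]
        assert estimates == sorted(estimates)
        assert estimates[-1] - estimates[0] > 0.5  # 4 * 0.05 * 5 = 1 planted


class TestStars:
    @pytest.mark.parametrize(
        "p,code",
        [(0.2, "NS"), (0.05, "*"), (0.01, "**"), (0.0009, "***"), (0.04, "*")],
    )
    def test_star_codes(self, p, code):
        assert star_code(p) == code


class TestPairwise:
    def test_adjustments(self):
        ps = [0.01, 0.04, 0.3]
        assert _adjust_p(ps, "none") == ps
        assert _adjust_p(ps, "bonferroni") == pytest.approx([0.03, 0.12, 0.9])
        assert _adjust_p(ps, "holm") == pytest.approx([0.03, 0.08, 0.3])

    def test_single_group_no_comparisons(self):
        rng = np.random.default_rng(41)
        df = pd.DataFrame({"ecotype": rng.choice(["glo", "sp1"], 40)})
        X, labels, spec = build_design_matrix(
            df, DesignSpec.from_strings(["ecotype"], FACTORS)
        )
        y = (rng.random(40) < 0.5).astype(float)
        fit = fit_binomial_logit(y, X, labels=labels, spec=spec)
        means, pairwise = germination_overall_lsmeans(fit, [], nuisance=["ecotype"])
        assert len(means) == 1
        assert pairwise.empty

    def test_null_family_wise_error_controlled(self):
        # balanced null: after Bonferroni the chance of any pairwise
        # rejection stays at or below the nominal level (within MC error)
        rng = np.random.default_rng(44)
        n, reps = 510, 200
        spec_terms = ["ecotype", "provenance", "ecotype:provenance"]
        fwe_hits = 0
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "ecotype": np.repeat(["glo", "sp1"], n // 2),
                    "provenance": np.tile(["E", "W"], n // 2),
                }
            )
            y = (rng.random(n) < 0.5).astype(float)
            X, labels, spec = build_design_matrix(
                df, DesignSpec.from_strings(spec_terms, FACTORS)
            )
            fit = fit_binomial_logit(y, X, labels=labels, spec=spec)
            _, pairwise = germination_overall_lsmeans(
                fit, ["ecotype", "provenance"], nuisance=[], adjust="bonferroni"
            )
            if (pairwise["p_adj"] < 0.05).any():
                fwe_hits += 1
        rate = fwe_hits / reps
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_planted_cell_separates(self):
        # one (e,o) cell with a +2 logit shift stands out at study scale
        rng = np.random.default_rng(42)
        n = 510
        df = pd.DataFrame(
            {
                "ecotype": rng.choice(["glo", "sp1"], n),
                "provenance": rng.choice(["E", "W"], n),
            }
        )
        eta = np.where((df["ecotype"] == "glo") & (df["provenance"] == "E"), 1.5, -0.5)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X, labels, spec = build_design_matrix(
            df,
            DesignSpec.from_strings(
                ["ecotype", "provenance", "ecotype:provenance"], FACTORS
            ),
        )
        fit = fit_binomial_logit(y, X, labels=labels, spec=spec)
        means, pairwise = germination_overall_lsmeans(
            fit, ["ecotype", "provenance"], nuisance=[]
        )
        hits = pairwise[
            (pairwise["cell_a"] == "glo/E") | (pairwise["cell_b"] == "glo/E")
        ]
        assert (hits["p_adj"] < 0.001).all()


class TestGerminationTiming:
    def _timing_fit(self, k, factors=None):
        n = len(k)
        if factors is None:
            X = np.ones((n, 1))
            return fit_geometric(
                np.asarray(k, float), np.zeros(n, bool), X, link="log_on_mean",
                labels=["(Intercept)"],
                spec=DesignSpec([], levels={}),
            )
        df = pd.DataFrame({"provenance": factors})
        X, labels, spec = build_design_matrix(
            df, DesignSpec.from_strings(["provenance"], FACTORS)
        )
        return fit_geometric(
            np.asarray(k, float), np.zeros(n, bool), X, link="log_on_mean",
            labels=labels, spec=spec,
        )

    def test_intercept_only_mean_three(self):
        fit = self._timing_fit([3, 3, 3])
        assert math.exp(fit.params[0]) == pytest.approx(3.0, abs=1e-8)

    def test_degenerate_identical_times_small_se(self):
        fit = self._timing_fit([3] * 300)
        df, _ = germination_time_comparison(fit, [], nuisance=[])
        assert df["expected_time"].iloc[0] == pytest.approx(3.0, abs=1e-6)
        assert df["se_time"].iloc[0] < 0.25

    def test_east_three_west_thirteen_ordering(self):
        rng = np.random.default_rng(43)
        n = 300
        k_e = rng.geometric(1 - 3 / 4, n) - 1  # mean waiting 3 months
        k_w = rng.geometric(1 - 13 / 14, n) - 1  # mean waiting 13 months
        fit = self._timing_fit(
            np.concatenate([k_e, k_w]), factors=["E"] * n + ["W"] * n
        )
        df, pairwise = germination_time_comparison(fit, ["provenance"])
        by = df.set_index("provenance")["expected_time"]
        assert by["W"] > by["E"]
        assert by["E"] == pytest.approx(3.0, rel=0.25)
        assert by["W"] == pytest.approx(13.0, rel=0.25)
        assert (pairwise["p_adj"] < 0.05).all()
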