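"""Adjusted ("least-squares") means and the combined home-vs-away contrast.

An adjusted mean for a focal design cell is the *unweighted* average of the
model's predicted linear predictors over all levels of the nuisance
factors, evaluated at any supplied covariate values (mean shadehouse time,
or a given age).  Because it is computed by prediction averaging, the
result is invariant to the factor coding used at fit time.

The headline local-adaptation test combines the classical "home vs. away"
and "local vs. foreigner" comparisons into a single contrast

    C = (m_11 + m_22) - (m_12 + m_21)

between the two sympatric (home) and the two allopatric (away) adjusted
means, with a delta-method standard error from the coefficient covariance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rtelab.errors import ConfigError, EstimabilityError
from rtelab.glm import ModelFit

#: Significance star codes, most stringent first.
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    for cut, stars in STAR_LEVELS:
        if p <= cut:
            return stars
    return "NS"


@dataclass(frozen=True)
class AdjustedMean:
    """A least-squares (adjusted) mean on the model's link scale."""

    focal: dict
    at: dict
    weights: np.ndarray
    estimate: float
    se: float


@dataclass(frozen=True)
class ContrastResult:
    """A linear contrast of adjusted means with Wald inference."""

    at: dict
    estimate: float
    se: float
    statistic: float
    p_value: float
    stars: str
    weights: np.ndarray = field(repr=False, default=None)


def _reference_p(fit: ModelFit, statistic: float) -> float:
    """Two-sided p for a scalar Wald statistic: t with residual df for
    gaussian fits, standard normal otherwise."""
    if fit.family == "gaussian":
        if fit.df_resid is None:
            raise ConfigError("gaussian fit lacks residual degrees of freedom")
        return float(2.0 * stats.t.sf(abs(statistic), fit.df_resid))
    return float(2.0 * stats.norm.sf(abs(statistic)))


def _mean_weights(
    fit: ModelFit,
    focal: Mapping[str, object],
    nuisance: Sequence[str],
    at: Mapping[str, object] | None,
) -> np.ndarray:
    if fit.spec is None:
        raise ConfigError("fit has no attached design spec; refit via build_design_matrix")
    spec = fit.spec
    at = dict(at or {})
    for f in nuisance:
        if f not in spec.levels:
            raise EstimabilityError(f"nuisance factor {f!r} is not part of the fitted design")
    cells = itertools.product(*[spec.levels[f] for f in nuisance])
    rows = [
        spec.row({**dict(focal), **dict(zip(nuisance, cell)), **at}) for cell in cells
    ]
    return np.mean(rows, axis=0)


def lsmean(
    fit: ModelFit,
    focal: Mapping[str, object],
    nuisance: Sequence[str],
    at: Mapping[str, object] | None = None,
) -> AdjustedMean:
    """Adjusted mean for ``focal`` averaging uniformly over ``nuisance``.

    ``at`` supplies covariate values (e.g. ``{"shadehouse_days": 89}`` or
    ``{"age": 5}``).  The estimate lives on the link scale of the fit and
    equals ``weights @ fit.params`` exactly.
    """
    w = _mean_weights(fit, focal, nuisance, at)
    est = float(w @ fit.params)
    se = math.sqrt(max(float(w @ fit.cov @ w), 0.0))
    return AdjustedMean(focal=dict(focal), at=dict(at or {}), weights=w, estimate=est, se=se)


def contrast_of_means(
    fit: ModelFit,
    plus: Sequence[AdjustedMean],
    minus: Sequence[AdjustedMean],
    at: Mapping[str, object] | None = None,
) -> ContrastResult:
    """Wald inference for ``sum(plus) - sum(minus)`` from one fit."""
    w = sum(m.weights for m in plus) - sum(m.weights for m in minus)
    est = float(w @ fit.params)
    var = float(w @ fit.cov @ w)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        statistic = 0.0 if est == 0.0 else math.inf
    else:
        statistic = est / se
    p = _reference_p(fit, statistic) if math.isfinite(statistic) else 0.0
    return ContrastResult(
        at=dict(at or {}),
        estimate=est,
        se=se,
        statistic=statistic,
        p_value=p,
        stars=star_code(p),
        weights=w,
    )


def home_away_contrast(
    fit: ModelFit,
    home: Sequence[Mapping[str, object]],
    away: Sequence[Mapping[str, object]],
    nuisance: Sequence[str],
    at: Mapping[str, object] | None = None,
) -> ContrastResult:
    """The combined sympatric-vs-allopatric contrast from a single fit.

    ``home`` and ``away`` each list the two focal cells (as factor-level
    mappings) whose adjusted means are summed on either side, e.g.::

        home=[{"ecotype": "glo", "habitat": "SF"}, {"ecotype": "sp1", "habitat": "HT"}]
        away=[{"ecotype": "glo", "habitat": "HT"}, {"ecotype": "sp1", "habitat": "SF"}]

    A positive estimate means "home" cells outperform "away" cells on the
    link scale at the supplied covariate values.
    """
    plus = [lsmean(fit, cell, nuisance, at) for cell in home]
    minus = [lsmean(fit, cell, nuisance, at) for cell in away]
    return contrast_of_means(fit, plus, minus, at=at)


# ---------------------------------------------------------------------------
# Standard focal pairings
# ---------------------------------------------------------------------------

#: Ecotype x habitat pairing: each ecotype's home habitat.
ECOTYPE_HABITAT_HOME = (
    {"ecotype": "glo", "habitat": "SF"},
    {"ecotype": "sp1", "habitat": "HT"},
)
ECOTYPE_HABITAT_AWAY = (
    {"ecotype": "glo", "habitat": "HT"},
    {"ecotype": "sp1", "habitat": "SF"},
)

#: Provenance x plantation pairing: planted back into the region of origin.
PROVENANCE_PLANTATION_HOME = (
    {"provenance": "E", "plantation": "E"},
    {"provenance": "W", "plantation": "W"},
)
PROVENANCE_PLANTATION_AWAY = (
    {"provenance": "E", "plantation": "W"},
    {"provenance": "W", "plantation": "E"},
)


# ---------------------------------------------------------------------------
# Overall germination: cell means and pairwise comparisons
# ---------------------------------------------------------------------------


def _adjust_p(pvals: Sequence[float], method: str) -> list[float]:
    m = len(pvals)
    if method == "none" or m == 0:
        return list(pvals)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if method == "holm":
        order = np.argsort(pvals)
        adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[idx]))
            adj[idx] = running
        return adj
    raise ConfigError(f"unknown multiplicity adjustment {method!r}")


def germination_overall_lsmeans(
    fit: ModelFit,
    focal_factors: Sequence[str],
    nuisance: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> tuple[list[AdjustedMean], pd.DataFrame]:
    """Adjusted means per focal margin of an overall-germination fit, with
    all pairwise Wald comparisons on the logit scale.

    ``nuisance`` defaults to every other factor in the fitted design.
    Pairwise p-values are multiplicity-adjusted per ``adjust``
    (``bonferroni``, ``holm`` or ``none``).
    """
    if fit.spec is None:
        raise ConfigError("fit has no attached design spec")
    focal_factors = list(focal_factors)
    for f in focal_factors:
        if f not in fit.spec.levels:
            raise EstimabilityError(f"factor {f!r} is not part of the fitted design")
    if nuisance is None:
        nuisance = [f for f in fit.spec.levels if f not in focal_factors]
    means = [
        lsmean(fit, dict(zip(focal_factors, cell)), nuisance)
        for cell in itertools.product(*[fit.spec.levels[f] for f in focal_factors])
    ]
    rows = []
    raw_p = []
    for a, b in itertools.combinations(means, 2):
        res = contrast_of_means(fit, [a], [b])
        rows.append(
            {
                "cell_a": "/".join(str(v) for v in a.focal.values()),
                "cell_b": "/".join(str(v) for v in b.focal.values()),
                "estimate": res.estimate,
                "se": res.se,
                "statistic": res.statistic,
                "p_raw": res.p_value,
            }
        )
        raw_p.append(res.p_value)
    table = pd.DataFrame(
        rows, columns=["cell_a", "cell_b", "estimate", "se", "statistic", "p_raw"]
    )
    table["p_adj"] = _adjust_p(raw_p, adjust)
    table["stars"] = [star_code(p) for p in table["p_adj"]]
    return means, table


# ---------------------------------------------------------------------------
# Germination timing: expected waiting time comparisons
# ---------------------------------------------------------------------------


def germination_time_comparison(
    fit: ModelFit,
    focal_factors: Sequence[str],
    nuisance: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected germination waiting times per focal margin.

    The fit must be a geometric timing model with the mean-waiting-time log
    link; adjusted means are back-transformed as ``m = exp(eta)`` with
    delta-method standard errors ``se_m = m * se_eta``.  Pairwise
    comparisons stay on the link scale.
    """
    if fit.family != "geometric" or fit.link != "log_on_mean":
        raise ConfigError("expected a geometric fit with the log_on_mean link")
    means, pairwise = germination_overall_lsmeans(
        fit, focal_factors, nuisance=nuisance, adjust=adjust
    )
    rows = []
    for m in means:
        mt = math.exp(m.estimate) if math.isfinite(m.estimate) else math.inf
        rows.append(
            {
                **{k: v for k, v in m.focal.items()},
                "eta": m.estimate,
                "se_eta": m.se,
                "expected_time": mt,
                "se_time": mt * m.se,
            }
        )
    return pd.DataFrame(rows), pairwise
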