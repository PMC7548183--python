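"""From-scratch fitters for the three model families used in the analysis.

* binomial-logit regression (germination probabilities), via IRLS;
* censored geometric time-to-event regression (yearly survival and
  germination timing), via Newton iterations with analytic gradient and
  observed information;
* Gaussian linear models with age interactions (log-scale growth traits),
  via least squares on an orthogonal decomposition.

Design matrices are built from factor terms with either sum-to-zero or
treatment coding; interactions are products of coded main-effect columns,
optionally multiplied by covariates (e.g. ``age:ecotype:habitat``).
Fitted coefficients and their covariance feed the adjusted-mean machinery
in :mod:`rtelab.adaptation`.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rtelab.errors import ConfigError, EstimabilityError, FitError

INTERCEPT_LABEL = "(Intercept)"

# ---------------------------------------------------------------------------
# Terms and design specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One model term: a product of zero or more factors and zero or more
    covariates, e.g. ``Term(("ecotype",))``, ``Term(("ecotype", "habitat"))``
    or ``Term(("ecotype",), ("age",))`` for an age-by-ecotype slope."""

    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return ":".join([*self.covariates, *self.factors]) or "1"

    @staticmethod
    def parse(expr: str, factor_names: Sequence[str]) -> "Term":
        """Parse ``"age:ecotype:habitat"`` style expressions; components
        found in ``factor_names`` are factors, the rest covariates."""
        facs, covs = [], []
        for part in expr.split(":"):
            part = part.strip()
            if not part:
                raise ConfigError(f"empty component in term {expr!r}")
            (facs if part in factor_names else covs).append(part)
        return Term(tuple(facs), tuple(covs))


def _contrast_matrix(m: int, coding: str) -> np.ndarray:
    """Rows = levels, columns = m-1 coded columns."""
    if coding == "sum_to_zero":
        return np.vstack([np.eye(m - 1), -np.ones((1, m - 1))])
    if coding == "treatment":
        return np.vstack([np.zeros((1, m - 1)), np.eye(m - 1)])
    raise ConfigError(f"unknown coding {coding!r}")


@dataclass
class DesignSpec:
    """Specification of a model design matrix.

    ``levels`` (factor name -> ordered level tuple) is resolved from the
    data on the first build and then pinned, so that prediction rows for
    arbitrary cells use the same coding as the fit.
    """

    terms: list[Term]
    coding: str = "sum_to_zero"
    intercept: bool = True
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def factor_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.terms:
            for f in t.factors:
                seen.setdefault(f)
        return tuple(seen)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.terms:
            for c in t.covariates:
                seen.setdefault(c)
        return tuple(seen)

    @classmethod
    def from_strings(
        cls,
        terms: Sequence[str],
        factor_names: Sequence[str],
        coding: str = "sum_to_zero",
        intercept: bool = True,
    ) -> "DesignSpec":
        return cls(
            [Term.parse(t, factor_names) for t in terms], coding=coding, intercept=intercept
        )

    # -- resolution and column building ------------------------------------

    def resolve(self, data: pd.DataFrame) -> "DesignSpec":
        """Pin factor levels from the data (sorted, deterministic)."""
        levels = dict(self.levels)
        for f in self.factor_names:
            if f not in data.columns:
                raise ConfigError(f"factor {f!r} not present in data")
            if f not in levels:
                obs = sorted(map(str, pd.unique(data[f])))
                if len(obs) < 2:
                    raise EstimabilityError(
                        f"factor {f!r} has fewer than two observed levels: {obs}"
                    )
                levels[f] = tuple(obs)
        return replace(self, levels=levels)

    def _term_blocks(self, term: Term, getcol) -> tuple[np.ndarray, list[str]]:
        """Column block and labels for one term.

        ``getcol(name, is_factor)`` returns a 1-D value array (covariate) or
        integer level-index array (factor)."""
        base = None
        labels = [""]
        for c in term.covariates:
            vals = np.asarray(getcol(c, False), dtype=float)
            base = vals if base is None else base * vals
        if base is None:
            block = None
        else:
            block = base[:, None]
        for f in term.factors:
            C = _contrast_matrix(len(self.levels[f]), self.coding)
            idx = np.asarray(getcol(f, True), dtype=int)
            coded = C[idx]  # (n, m-1)
            if self.coding == "treatment":
                sub = [f"{f}[{lv}]" for lv in self.levels[f][1:]]
            else:
                sub = [f"{f}[{lv}]" for lv in self.levels[f][:-1]]
            if block is None:
                block, labels = coded, sub
            else:
                # columnwise Kronecker (Khatri-Rao across rows)
                block = (block[:, :, None] * coded[:, None, :]).reshape(len(coded), -1)
                labels = [f"{a}:{b}" if a else b for a in labels for b in sub]
        if block is None:  # pure covariate term
            block = base[:, None]
            labels = [""]
        prefix = ":".join(term.covariates)
        out_labels = []
        for lab in labels:
            parts = [p for p in (prefix, lab) if p]
            out_labels.append(":".join(parts) or term.label)
        return block, out_labels

    def matrix(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Build the design matrix for a data frame; checks estimability."""
        if self.factor_names and not self.levels:
            raise ConfigError("spec not resolved; call resolve(data) first")
        n = len(data)
        level_index = {}

        def getcol(name, is_factor):
            if name not in data.columns:
                raise ConfigError(f"variable {name!r} not present in data")
            if is_factor:
                if name not in level_index:
                    lut = {lv: i for i, lv in enumerate(self.levels[name])}
                    vals = data[name].astype(str)
                    unknown = sorted(set(vals) - set(lut))
                    if unknown:
                        raise EstimabilityError(
                            f"factor {name!r} has unpinned levels {unknown}"
                        )
                    level_index[name] = vals.map(lut).to_numpy()
                return level_index[name]
            return data[name].to_numpy(dtype=float)

        blocks, labels = [], []
        if self.intercept:
            blocks.append(np.ones((n, 1)))
            labels.append(INTERCEPT_LABEL)
        for term in self.terms:
            self._check_cells_observed(term, data)
            b, labs = self._term_blocks(term, getcol)
            blocks.append(b)
            labels.extend(labs)
        X = np.hstack(blocks) if blocks else np.empty((n, 0))
        if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
            raise EstimabilityError(
                "design matrix is rank deficient; some term combination is "
                "not estimable from the observed design"
            )
        return X, labels

    def _check_cells_observed(self, term: Term, data: pd.DataFrame) -> None:
        if len(term.factors) < 2:
            return
        observed = set(
            map(tuple, data[list(term.factors)].astype(str).itertuples(index=False))
        )
        wanted = set(itertools.product(*[self.levels[f] for f in term.factors]))
        missing = sorted(wanted - observed)
        if missing:
            raise EstimabilityError(
                f"term {term.label!r} is not estimable: unobserved cells {missing}"
            )

    def row(self, values: Mapping[str, object]) -> np.ndarray:
        """Design row for a single (possibly counterfactual) cell."""
        if self.factor_names and not self.levels:
            raise ConfigError("spec not resolved; call resolve(data) first")

        def getcol(name, is_factor):
            if name not in values:
                raise EstimabilityError(f"no value supplied for {name!r}")
            if is_factor:
                lv = str(values[name])
                if lv not in self.levels[name]:
                    raise EstimabilityError(
                        f"level {lv!r} of factor {name!r} was not pinned at fit time"
                    )
                return np.array([self.levels[name].index(lv)])
            return np.array([float(values[name])])  # type: ignore[arg-type]

        blocks = []
        if self.intercept:
            blocks.append(np.ones((1, 1)))
        for term in self.terms:
            b, _ = self._term_blocks(term, getcol)
            blocks.append(b)
        return np.hstack(blocks)[0]

    def to_dict(self) -> dict:
        return {
            "terms": [{"factors": list(t.factors), "covariates": list(t.covariates)} for t in self.terms],
            "coding": self.coding,
            "intercept": self.intercept,
            "levels": {k: list(v) for k, v in self.levels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(
            [Term(tuple(t["factors"]), tuple(t["covariates"])) for t in d["terms"]],
            coding=d["coding"],
            intercept=d["intercept"],
            levels={k: tuple(v) for k, v in d["levels"].items()},
        )


def build_design_matrix(
    data: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, list[str], DesignSpec]:
    """Resolve ``spec`` against ``data`` and build the numeric matrix.

    Returns ``(X, labels, resolved_spec)``; the resolved spec carries the
    pinned factor levels needed to build prediction rows later.
    """
    resolved = spec.resolve(data)
    X, labels = resolved.matrix(data)
    return X, labels, resolved


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """A fitted model: coefficients, covariance, and fit diagnostics."""

    family: str
    params: np.ndarray
    cov: np.ndarray
    labels: list[str]
    loglik: float
    deviance: float
    n_obs: int
    n_iter: int
    converged: bool
    spec: DesignSpec | None = None
    sigma2: float | None = None
    df_resid: int | None = None
    link: str | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def predict_eta(self, values: Mapping[str, object]) -> float:
        """Linear predictor for one cell (requires an attached spec)."""
        if self.spec is None:
            raise ConfigError("fit has no attached design spec")
        return float(self.spec.row(values) @ self.params)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se}, index=self.labels
        )

    def to_json(self) -> str:
        d = {
            "family": self.family,
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "labels": self.labels,
            "loglik": self.loglik,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "sigma2": self.sigma2,
            "df_resid": self.df_resid,
            "link": self.link,
            "warnings": self.warnings,
            "spec": self.spec.to_dict() if self.spec is not None else None,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ModelFit":
        d = json.loads(s)
        spec = DesignSpec.from_dict(d["spec"]) if d.get("spec") else None
        return cls(
            family=d["family"],
            params=np.asarray(d["params"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            labels=list(d["labels"]),
            loglik=d["loglik"],
            deviance=d["deviance"],
            n_obs=d["n_obs"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            spec=spec,
            sigma2=d.get("sigma2"),
            df_resid=d.get("df_resid"),
            link=d.get("link"),
            warnings=list(d.get("warnings", [])),
        )


def _check_matrix(X: np.ndarray, y: np.ndarray) -> None:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ConfigError("X must be a 2-D matrix matching the response length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimabilityError("design matrix is rank deficient")


# ---------------------------------------------------------------------------
# Binomial logit (IRLS)
# ---------------------------------------------------------------------------


def fit_binomial_logit(
    y: np.ndarray,
    X: np.ndarray,
    labels: Sequence[str] | None = None,
    spec: DesignSpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    ridge: float = 1e-4,
) -> ModelFit:
    """Logistic regression for a 0/1 response by iteratively reweighted
    least squares; covariance is the inverse Fisher information.

    Complete or quasi-complete separation is detected from diverging linear
    predictors; the fit then falls back to a small L2 penalty (``ridge``)
    on non-intercept coefficients and is flagged in ``warnings``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ConfigError("binomial response must be coded 0/1")
    _check_matrix(X, y)
    labels = list(labels) if labels is not None else [f"b{i}" for i in range(X.shape[1])]

    def run(penalty: np.ndarray | None):
        beta = np.zeros(X.shape[1])
        dev_prev = np.inf
        trace = []
        for it in range(1, max_iter + 1):
            eta = X @ beta
            mu = _expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            z = eta + (y - mu) / w
            A = X.T @ (w[:, None] * X)
            b = X.T @ (w * z)
            if penalty is not None:
                A = A + np.diag(penalty)
            beta = np.linalg.solve(A, b)
            dev = _binomial_deviance(y, _expit(X @ beta))
            trace.append(dev)
            if np.isfinite(dev_prev) and abs(dev_prev - dev) <= tol * (abs(dev) + 0.1):
                info = X.T @ (np.clip(_expit(X @ beta) * (1 - _expit(X @ beta)), 1e-12, None)[:, None] * X)
                if penalty is not None:
                    info = info + np.diag(penalty)
                return beta, np.linalg.inv(info), dev, it, True, trace
            dev_prev = dev
            if penalty is None and np.max(np.abs(X @ beta)) > 30.0:
                return beta, None, dev, it, False, trace  # separation signal
        return beta, None, dev_prev, max_iter, False, trace

    beta, cov, dev, it, ok, trace = run(None)
    warns: list[str] = []
    # fitted probabilities indistinguishable from 0/1 mean the MLE is on
    # (or diverging towards) the boundary: quasi/complete separation
    if ok and np.max(np.abs(X @ beta)) > 15.0:
        ok = False
    if not ok:
        separated = np.max(np.abs(X @ beta)) > 15.0
        if separated:
            pen = np.full(X.shape[1], ridge)
            for j, lab in enumerate(labels):
                if lab == INTERCEPT_LABEL:
                    pen[j] = 0.0
            beta, cov, dev, it2, ok, trace2 = run(pen)
            it += it2
            warns.append(
                f"separation detected; returned L2-penalized fit (ridge={ridge})"
            )
            if not ok:
                raise FitError("penalized IRLS did not converge", trace=trace + trace2)
        else:
            raise FitError(
                f"IRLS did not converge in {max_iter} iterations", trace=trace
            )
    mu = _expit(X @ beta)
    ll = float(np.sum(y * _safe_log(mu) + (1 - y) * _safe_log(1 - mu)))
    return ModelFit(
        family="binomial_logit",
        params=beta,
        cov=cov,
        labels=labels,
        loglik=ll,
        deviance=float(dev),
        n_obs=len(y),
        n_iter=it,
        converged=ok,
        spec=spec,
        link="logit",
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# Censored geometric
# ---------------------------------------------------------------------------


def fit_geometric(
    final_age: np.ndarray,
    censored: np.ndarray,
    X: np.ndarray,
    link: str = "logit_on_survival",
    labels: Sequence[str] | None = None,
    spec: DesignSpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ModelFit:
    """Censored geometric time-to-event regression.

    Each observation waits ``k = final_age`` periods with per-period
    continuation probability ``q``; an uncensored observation contributes
    ``k ln q + ln(1 - q)`` to the log-likelihood and a right-censored one
    contributes ``k ln q``.  With ``link="logit_on_survival"``,
    ``q = expit(X b)``; ``link="log_on_mean"`` models the mean waiting time
    ``m = q/(1-q)`` with a log link, which induces exactly the same
    likelihood in ``X b`` (log m = logit q) and differs only in how
    downstream code back-transforms estimates.

    Newton iterations use the analytic gradient and the exact observed
    information ``X' diag((k + 1 - cens) q (1-q)) X``.
    """
    k = np.asarray(final_age, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    X = np.asarray(X, dtype=float)
    if (k < 0).any():
        raise ConfigError("final_age must be non-negative")
    if link not in ("logit_on_survival", "log_on_mean"):
        raise ConfigError(f"unknown geometric link {link!r}")
    _check_matrix(X, k)
    labels = list(labels) if labels is not None else [f"b{i}" for i in range(X.shape[1])]
    if cens.all():
        raise FitError("non-identifiable: all observations are censored")
    uncens = (~cens).astype(float)

    def loglik(beta):
        q = _expit(X @ beta)
        return float(np.sum(k * _safe_log(q) + uncens * _safe_log(1 - q)))

    if k.sum() == 0 and not cens.any():
        # boundary MLE q = 0 for every observation: all die immediately
        beta = np.zeros(X.shape[1])
        beta[_intercept_index(labels)] = -np.inf
        return ModelFit(
            family="geometric",
            params=beta,
            cov=np.zeros((X.shape[1], X.shape[1])),
            labels=labels,
            loglik=0.0,
            deviance=0.0,
            n_obs=len(k),
            n_iter=0,
            converged=True,
            spec=spec,
            link=link,
            warnings=["boundary MLE: continuation probability 0"],
        )

    beta = np.zeros(X.shape[1])
    ll = loglik(beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = _expit(X @ beta)
        u = k * (1.0 - q) - uncens * q  # d loglik / d eta
        w = np.clip((k + uncens) * q * (1.0 - q), 1e-12, None)
        grad = X.T @ u
        info = X.T @ (w[:, None] * X)
        step = np.linalg.solve(info, grad)
        # step halving to guarantee ascent
        lam, ll_new = 1.0, -np.inf
        for _ in range(30):
            ll_new = loglik(beta + lam * step)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        trace.append(ll_new)
        if np.max(np.abs(grad)) < tol * (abs(ll) + 1.0) or abs(ll_new - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        raise FitError(f"geometric Newton did not converge in {max_iter} iterations", trace=trace)
    q = _expit(X @ beta)
    info = X.T @ ((np.clip((k + uncens) * q * (1.0 - q), 1e-12, None))[:, None] * X)
    # saturated deviance reference: per-observation MLE of q
    dev = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        q_sat = np.where(uncens > 0, k / (k + 1.0), 1.0)
        ll_sat = float(np.sum(k * _safe_log(q_sat) + uncens * _safe_log(1 - q_sat)))
    dev = max(0.0, 2.0 * (ll_sat - ll))
    return ModelFit(
        family="geometric",
        params=beta,
        cov=np.linalg.inv(info),
        labels=labels,
        loglik=ll,
        deviance=dev,
        n_obs=len(k),
        n_iter=it,
        converged=True,
        spec=spec,
        link=link,
    )


def geometric_continuation_probability(fit: ModelFit, values: Mapping[str, object]) -> float:
    """Per-period continuation probability for one cell."""
    return float(_expit(fit.predict_eta(values)))


# ---------------------------------------------------------------------------
# Gaussian linear model
# ---------------------------------------------------------------------------


def fit_gaussian_lm(
    y: np.ndarray,
    X: np.ndarray,
    labels: Sequence[str] | None = None,
    spec: DesignSpec | None = None,
) -> ModelFit:
    """Ordinary least squares with ``sigma^2 = RSS / (n - p)`` and
    coefficient covariance ``sigma^2 (X'X)^{-1}``.

    The caller supplies the response on whatever scale it should be
    modelled on (growth traits are conventionally log-transformed first).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.isfinite(y).all():
        raise ConfigError("response contains non-finite values")
    _check_matrix(X, y)
    n, p = X.shape
    if n <= p:
        raise FitError(f"underdetermined: n={n} observations for p={p} coefficients")
    labels = list(labels) if labels is not None else [f"b{i}" for i in range(p)]
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    Rinv = np.linalg.solve(R, np.eye(p))
    cov = sigma2 * (Rinv @ Rinv.T)
    ll = -0.5 * n * (math.log(2 * math.pi * max(sigma2 * df / n, 1e-300)) + 1.0)
    return ModelFit(
        family="gaussian",
        params=beta,
        cov=cov,
        labels=labels,
        loglik=ll,
        deviance=rss,
        n_obs=n,
        n_iter=1,
        converged=True,
        spec=spec,
        sigma2=sigma2,
        df_resid=df,
        link="identity",
    )


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------


def wald_test(fit: ModelFit, L: np.ndarray) -> tuple[float, int, float]:
    """Wald test of ``L b = 0``.

    Returns ``(statistic, df, p)``.  Gaussian fits use an F reference with
    the residual degrees of freedom (statistic is then F); GLM fits use the
    chi-square reference.  An all-zero ``L`` gives statistic 0 and p = 1.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != len(fit.params):
        raise ConfigError(
            f"contrast has {L.shape[1]} columns for {len(fit.params)} coefficients"
        )
    df = int(np.linalg.matrix_rank(L))
    if df == 0:
        return 0.0, 0, 1.0
    est = L @ fit.params
    V = L @ fit.cov @ L.T
    if np.linalg.matrix_rank(V) < df:
        bad = int(np.argmin(np.diag(V)))
        raise EstimabilityError(f"contrast row {bad} is not estimable (singular variance)")
    stat = float(est @ np.linalg.solve(V, est))
    if fit.family == "gaussian":
        if fit.df_resid is None:
            raise ConfigError("gaussian fit lacks residual degrees of freedom")
        f = stat / df
        p = float(stats.f.sf(f, df, fit.df_resid))
        return f, df, p
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# numeric helpers
# ---------------------------------------------------------------------------


def _expit(x):
    with np.errstate(over="ignore", invalid="ignore"):
        return np.where(
            np.isneginf(x), 0.0, np.where(np.isposinf(x), 1.0, 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700))))
        )


def _safe_log(x):
    return np.log(np.clip(x, 1e-300, None))


def _binomial_deviance(y, mu) -> float:
    return float(-2.0 * np.sum(y * _safe_log(mu) + (1 - y) * _safe_log(1 - mu)))


def _intercept_index(labels: Sequence[str]) -> int:
    try:
        return list(labels).index(INTERCEPT_LABEL)
    except ValueError:
        return 0
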