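"""Standard analysis models: response-frame builders and term lists.

These wire the record tables to the generic fitters in :mod:`rtelab.glm`:

* shadehouse germination — binomial logit on ecotype, provenance, their
  interaction, and shadehouse-time slopes per ecotype/provenance;
* overall germination — binomial logit on genetic and environmental
  factors, no shadehouse-time term;
* germination timing — geometric model (log link on the mean waiting time
  in months) for germinated individuals;
* yearly survival — censored geometric model on the ecotype:habitat joint
  effect plus the provenance:plantation:status joint effect;
* growth traits — Gaussian linear model on the log scale with age slopes
  per joint effect; the ecotype:habitat by provenance:plantation:status
  cross interaction is deliberately excluded (not all of its cells are
  observable in this design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rtelab.errors import ConfigError, DataError
from rtelab.glm import DesignSpec, ModelFit, build_design_matrix, fit_binomial_logit, fit_gaussian_lm, fit_geometric
from rtelab.records import (
    GERM_AT_TRANSPLANT,
    GERM_NEVER,
    encode_survival_series,
    individuals_frame,
    measurements_frame,
)

FACTORS = ("ecotype", "habitat", "provenance", "plantation", "status")

#: Average days per month used to express germination waiting times.
DAYS_PER_MONTH = 30.44

SHADEHOUSE_GERMINATION_TERMS = (
    "ecotype",
    "provenance",
    "ecotype:provenance",
    "shadehouse_days",
    "shadehouse_days:ecotype",
    "shadehouse_days:provenance",
)

OVERALL_GERMINATION_TERMS = (
    "ecotype",
    "provenance",
    "ecotype:provenance",
    "habitat",
    "plantation",
    "habitat:plantation",
)

GERMINATION_TIMING_TERMS = ("ecotype", "provenance", "ecotype:provenance")

#: ecotype:habitat joint effect (4 cells) + provenance:plantation:status
#: joint effect (8 cells); no cross interaction between the two blocks.
SURVIVAL_TERMS = (
    "ecotype",
    "habitat",
    "ecotype:habitat",
    "provenance",
    "plantation",
    "status",
    "provenance:plantation",
    "provenance:status",
    "plantation:status",
    "provenance:plantation:status",
)

GROWTH_TERMS = SURVIVAL_TERMS + (
    "age",
    "age:ecotype",
    "age:habitat",
    "age:ecotype:habitat",
    "age:provenance",
    "age:plantation",
    "age:status",
    "age:provenance:plantation",
    "age:provenance:status",
    "age:plantation:status",
    "age:provenance:plantation:status",
)


def _spec(terms, coding: str) -> DesignSpec:
    return DesignSpec.from_strings(terms, FACTORS, coding=coding)


# ---------------------------------------------------------------------------
# Response frames
# ---------------------------------------------------------------------------


def shadehouse_germination_frame(individuals) -> pd.DataFrame:
    """One row per individual: 0/1 germinated in the shadehouse + factors."""
    df = individuals_frame(individuals)
    df["germinated"] = (df["germ_timing"] == GERM_AT_TRANSPLANT).astype(float)
    return df


def overall_germination_frame(individuals) -> pd.DataFrame:
    df = individuals_frame(individuals)
    df["germinated"] = (df["germ_timing"] != GERM_NEVER).astype(float)
    return df


def germination_timing_frame(individuals) -> pd.DataFrame:
    """Waiting time to germination, in whole months since sowing, for
    germinated individuals.

    Shadehouse germinations are recorded as the months spent in the
    shadehouse (germination was only scored at transplant); field
    germinations add 12 months per census year after transplant.
    """
    rows = []
    for r in individuals:
        g = r.germination_year()
        if g is None:
            continue
        months = int(round(r.shadehouse_days / DAYS_PER_MONTH)) + 12 * g
        rows.append(
            {
                "individual_id": r.individual_id,
                "ecotype": r.ecotype,
                "habitat": r.habitat,
                "provenance": r.provenance,
                "plantation": r.plantation,
                "status": r.status,
                "wait_months": months,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "ecotype",
            "habitat",
            "provenance",
            "plantation",
            "status",
            "wait_months",
        ],
    )


def survival_frame(individuals) -> pd.DataFrame:
    """Geometric survival responses (final age + censoring) for germinated
    individuals; never-germinated seeds are excluded."""
    rows = []
    for r in individuals:
        enc = encode_survival_series(r)
        if enc is None:
            continue
        k, cens = enc
        rows.append(
            {
                "individual_id": r.individual_id,
                "ecotype": r.ecotype,
                "habitat": r.habitat,
                "provenance": r.provenance,
                "plantation": r.plantation,
                "status": r.status,
                "final_age": k,
                "censored": cens,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "ecotype",
            "habitat",
            "provenance",
            "plantation",
            "status",
            "final_age",
            "censored",
        ],
    )


def growth_frame(individuals, measurements, trait: str) -> pd.DataFrame:
    """Log-scale trait values joined with the individuals' factors."""
    mdf = measurements_frame(measurements)
    mdf = mdf[mdf["trait"] == trait]
    if mdf.empty:
        raise DataError(f"no measurements for trait {trait!r}")
    if (mdf["value"] <= 0).any():
        raise DataError(f"trait {trait!r} has non-positive values; cannot log-transform")
    idf = individuals_frame(individuals)
    df = mdf.merge(idf, on="individual_id", how="left", validate="many_to_one")
    if df["ecotype"].isna().any():
        missing = sorted(df.loc[df["ecotype"].isna(), "individual_id"].unique())
        raise DataError(f"measurements reference unknown individuals: {missing[:5]}")
    df["log_value"] = np.log(df["value"].to_numpy(dtype=float))
    return df


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def fit_shadehouse_germination(individuals, coding: str = "sum_to_zero") -> ModelFit:
    df = shadehouse_germination_frame(individuals)
    X, labels, spec = build_design_matrix(df, _spec(SHADEHOUSE_GERMINATION_TERMS, coding))
    return fit_binomial_logit(df["germinated"].to_numpy(), X, labels=labels, spec=spec)


def fit_overall_germination(individuals, coding: str = "sum_to_zero") -> ModelFit:
    df = overall_germination_frame(individuals)
    X, labels, spec = build_design_matrix(df, _spec(OVERALL_GERMINATION_TERMS, coding))
    return fit_binomial_logit(df["germinated"].to_numpy(), X, labels=labels, spec=spec)


def fit_germination_timing(individuals, coding: str = "sum_to_zero") -> ModelFit:
    df = germination_timing_frame(individuals)
    if df.empty:
        raise DataError("no germinated individuals; timing model not fittable")
    X, labels, spec = build_design_matrix(df, _spec(GERMINATION_TIMING_TERMS, coding))
    return fit_geometric(
        df["wait_months"].to_numpy(),
        np.zeros(len(df), dtype=bool),
        X,
        link="log_on_mean",
        labels=labels,
        spec=spec,
    )


def fit_survival(individuals, coding: str = "sum_to_zero") -> ModelFit:
    df = survival_frame(individuals)
    if df.empty:
        raise DataError("no germinated individuals; survival model not fittable")
    X, labels, spec = build_design_matrix(df, _spec(SURVIVAL_TERMS, coding))
    return fit_geometric(
        df["final_age"].to_numpy(),
        df["censored"].to_numpy(dtype=bool),
        X,
        link="logit_on_survival",
        labels=labels,
        spec=spec,
    )


def fit_growth(individuals, measurements, trait: str, coding: str = "sum_to_zero") -> ModelFit:
    df = growth_frame(individuals, measurements, trait)
    X, labels, spec = build_design_matrix(df, _spec(GROWTH_TERMS, coding))
    return fit_gaussian_lm(df["log_value"].to_numpy(), X, labels=labels, spec=spec)


def fit_growth_from_frames(
    ind_df: pd.DataFrame, meas_df: pd.DataFrame, trait: str, coding: str = "sum_to_zero"
) -> ModelFit:
    """Growth fit straight from flat tables (fast path for simulation
    studies; equivalent to :func:`fit_growth` on the wrapped records)."""
    mdf = meas_df[meas_df["trait"] == trait]
    if mdf.empty:
        raise DataError(f"no measurements for trait {trait!r}")
    df = mdf.merge(
        ind_df[["individual_id", *FACTORS]], on="individual_id", how="left"
    )
    df["log_value"] = np.log(df["value"].to_numpy(dtype=float))
    X, labels, spec = build_design_matrix(df, _spec(GROWTH_TERMS, coding))
    return fit_gaussian_lm(df["log_value"].to_numpy(), X, labels=labels, spec=spec)


def mean_shadehouse_days(individuals) -> float:
    days = [r.shadehouse_days for r in individuals]
    if not days:
        raise ConfigError("no individuals")
    return float(np.mean(days))
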