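"""Synthetic reciprocal-transplant cohort generator.

Generates datasets with the statistical structure the downstream analysis
assumes, so every stage is testable without external data:

* a crossed design: mothers (fixing ecotype and provenance) contribute
  seeds split across gardens (fixing plantation region and habitat);
* Bernoulli shadehouse germination with a logit linear predictor including
  ecotype/provenance by shadehouse-time interactions, plus a constant
  yearly field-germination hazard for seeds that had not germinated by
  transplant (the source design gives no field-germination model; the
  constant hazard is a documented stand-in);
* geometric yearly survival whose logit depends on ecotype:habitat and
  provenance:plantation:status cells;
* Gaussian log-scale growth traits with age-slope interactions;
* five-class leaf herbivory drawn per (ecotype, habitat).

All randomness flows from one master seed; each stage draws from its own
child stream, so adding or re-running a stage never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rtelab.errors import ConfigError
from rtelab.records import (
    GERM_AT_TRANSPLANT,
    GERM_NEVER,
    HERBIVORY_CLASSES,
    HERBIVORY_MIDPOINTS,
    IndividualRecord,
    MeasurementRecord,
    N_YEARS,
    OBSERVED_AGES,
)

_STREAMS = ("design", "germination", "survival", "growth", "herbivory")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotherSpec:
    mother_id: str
    provenance: str
    ecotype: str
    n_seeds: int


@dataclass(frozen=True)
class GerminationCoefs:
    """Logit-scale coefficients of the shadehouse germination model:
    ``logit p = intercept + ecotype[e] + provenance[o] + interaction[e,o]
    + (slope + slope_ecotype[e] + slope_provenance[o]) * t`` with ``t``
    the days spent in the shadehouse."""

    intercept: float = 0.0
    ecotype: Mapping[str, float] = field(default_factory=dict)
    provenance: Mapping[str, float] = field(default_factory=dict)
    interaction: Mapping[tuple, float] = field(default_factory=dict)
    slope: float = 0.0
    slope_ecotype: Mapping[str, float] = field(default_factory=dict)
    slope_provenance: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SurvivalCoefs:
    """Logit-scale coefficients of the constant yearly survival
    probability: ``logit q = intercept + ecotype_habitat[e,h] + ors[o,r,s]
    + interaction[e,h,o,r,s]``."""

    intercept: float = 0.0
    ecotype_habitat: Mapping[tuple, float] = field(default_factory=dict)
    ors: Mapping[tuple, float] = field(default_factory=dict)
    interaction: Mapping[tuple, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GrowthCoefs:
    """Log-scale coefficients of one growth trait:
    ``ln Y = intercept + ecotype_habitat[e,h] + ors[o,r,s]
    + (age_slope + age_ecotype_habitat[e,h] + age_ors[o,r,s]) * age
    + Normal(0, sigma)``."""

    intercept: float = 0.0
    ecotype_habitat: Mapping[tuple, float] = field(default_factory=dict)
    ors: Mapping[tuple, float] = field(default_factory=dict)
    age_slope: float = 0.0
    age_ecotype_habitat: Mapping[tuple, float] = field(default_factory=dict)
    age_ors: Mapping[tuple, float] = field(default_factory=dict)
    sigma: float = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    mothers: tuple[MotherSpec, ...]
    gardens: tuple[tuple[str, str, str], ...]  # (garden_id, region, habitat)
    germination: GerminationCoefs = GerminationCoefs()
    survival: SurvivalCoefs = SurvivalCoefs()
    growth: Mapping[str, GrowthCoefs] = field(default_factory=dict)
    herbivory_probs: Mapping[tuple, tuple] | None = None
    field_hazard: Mapping[tuple, float] = field(default_factory=dict)
    field_hazard_default: float = 0.2
    shadehouse_days_range: tuple[int, int] = (27, 315)
    n_years: int = N_YEARS
    observed_ages: tuple[int, ...] = OBSERVED_AGES

    def validate(self) -> None:
        if not self.mothers:
            raise ConfigError("no mothers configured")
        if any(m.n_seeds <= 0 for m in self.mothers):
            raise ConfigError("every mother needs a positive number of seeds")
        regions = {g[1] for g in self.gardens}
        habitats = {g[2] for g in self.gardens}
        if regions != {"E", "W"} or habitats != {"SF", "HT"}:
            raise ConfigError(
                "garden list must cover both regions (E, W) and both habitats (SF, HT); "
                f"got regions={sorted(regions)}, habitats={sorted(habitats)}"
            )
        if len({g[0] for g in self.gardens}) != len(self.gardens):
            raise ConfigError("duplicate garden ids")
        lo, hi = self.shadehouse_days_range
        if not (0 <= lo <= hi):
            raise ConfigError(f"bad shadehouse_days_range {self.shadehouse_days_range}")
        for key, probs in (self.herbivory_probs or {}).items():
            p = np.asarray(probs, dtype=float)
            if len(p) != len(HERBIVORY_CLASSES) or (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ConfigError(f"herbivory class probabilities for {key} must be 5 non-negative values summing to 1")
        for trait, g in self.growth.items():
            if g.sigma < 0:
                raise ConfigError(f"growth sigma for {trait!r} must be >= 0")
        hazards = [self.field_hazard_default, *self.field_hazard.values()]
        if any(not (0.0 <= h <= 1.0) for h in hazards):
            raise ConfigError("field germination hazards must lie in [0, 1]")

    def hazard(self, o: str, r: str, h: str) -> float:
        return float(self.field_hazard.get((o, r, h), self.field_hazard_default))


#: Default Ni per mother reproducing the bundled study design (510 seeds
#: from 14 mothers: 5 eastern, 9 western).
_DEFAULT_MOTHERS = (
    ("E01", "E", "glo", 36),
    ("E02", "E", "glo", 37),
    ("E03", "E", "sp1", 36),
    ("E04", "E", "sp1", 38),
    ("E05", "E", "sp1", 39),
    ("W01", "W", "glo", 36),
    ("W02", "W", "glo", 36),
    ("W03", "W", "glo", 36),
    ("W04", "W", "glo", 35),
    ("W05", "W", "sp1", 36),
    ("W06", "W", "sp1", 36),
    ("W07", "W", "sp1", 36),
    ("W08", "W", "sp1", 36),
    ("W09", "W", "sp1", 37),
)

_DEFAULT_GARDENS = tuple(
    (f"G{i + 1:02d}", r, h)
    for i, (r, h) in enumerate(
        [("W", "HT")] * 3 + [("W", "SF")] * 3 + [("E", "SF")] * 3 + [("E", "HT")] * 3
    )
)


def _home_away(d: float) -> dict:
    """ecotype:habitat cell effects +d at home (glo/SF, sp1/HT), -d away."""
    return {
        ("glo", "SF"): +d,
        ("sp1", "HT"): +d,
        ("glo", "HT"): -d,
        ("sp1", "SF"): -d,
    }


def _ors_effects(region_match: float, status_seedling: float) -> dict:
    out = {}
    for o in ("E", "W"):
        for r in ("E", "W"):
            for s in ("seed", "seedling"):
                v = (region_match if o == r else -region_match) + (
                    status_seedling if s == "seedling" else -status_seedling
                )
                out[(o, r, s)] = v
    return out


def default_config() -> SimulationConfig:
    """A study-scale default: 510 seeds, 14 mothers, 12 gardens, aggregate
    germination/survival rates near the bundled count tables, and modest
    home-advantage effects on survival and growth."""
    return SimulationConfig(
        mothers=tuple(MotherSpec(*m) for m in _DEFAULT_MOTHERS),
        gardens=_DEFAULT_GARDENS,
        germination=GerminationCoefs(
            intercept=-1.0,
            ecotype={"glo": 0.2, "sp1": -0.2},
            provenance={"E": 1.2, "W": -1.2},
            slope=0.004,
            slope_provenance={"E": 0.002, "W": -0.002},
        ),
        survival=SurvivalCoefs(
            intercept=1.7,
            ecotype_habitat=_home_away(0.25),
            ors=_ors_effects(0.35, 0.1),
        ),
        growth={
            "height_cm": GrowthCoefs(
                intercept=math.log(12.0),
                ecotype_habitat=_home_away(0.08),
                ors=_ors_effects(0.05, 0.02),
                age_slope=0.30,
                age_ecotype_habitat=_home_away(0.04),
                sigma=0.35,
            ),
            "diameter_mm": GrowthCoefs(
                intercept=math.log(1.8),
                ecotype_habitat=_home_away(0.05),
                age_slope=0.18,
                age_ecotype_habitat=_home_away(0.02),
                sigma=0.30,
            ),
            "tnl": GrowthCoefs(
                intercept=math.log(4.0),
                ecotype_habitat=_home_away(0.06),
                age_slope=0.50,
                age_ecotype_habitat=_home_away(0.03),
                sigma=0.50,
            ),
        },
        herbivory_probs={
            ("glo", "SF"): (0.55, 0.25, 0.12, 0.05, 0.03),
            ("glo", "HT"): (0.45, 0.30, 0.15, 0.06, 0.04),
            ("sp1", "SF"): (0.85, 0.10, 0.03, 0.015, 0.005),
            ("sp1", "HT"): (0.70, 0.20, 0.06, 0.03, 0.01),
        },
        field_hazard={
            ("E", "E", "SF"): 0.30,
            ("E", "E", "HT"): 0.25,
            ("E", "W", "SF"): 0.12,
            ("E", "W", "HT"): 0.12,
            ("W", "E", "SF"): 0.10,
            ("W", "E", "HT"): 0.10,
            ("W", "W", "SF"): 0.05,
            ("W", "W", "HT"): 0.12,
        },
        field_hazard_default=0.1,
    )


# ---------------------------------------------------------------------------
# Stage simulators (frame-level, vectorized)
# ---------------------------------------------------------------------------


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def simulate_design(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign each mother's seeds across all gardens (as evenly as the seed
    count allows, remainders to random gardens) and draw one shadehouse
    duration per mother."""
    config.validate()
    n_gardens = len(config.gardens)
    garden_ids = [g[0] for g in config.gardens]
    garden_region = {g[0]: g[1] for g in config.gardens}
    garden_habitat = {g[0]: g[2] for g in config.gardens}
    lo, hi = config.shadehouse_days_range
    rows: dict[str, list] = {
        "individual_id": [],
        "mother_id": [],
        "garden_id": [],
        "ecotype": [],
        "habitat": [],
        "provenance": [],
        "plantation": [],
        "shadehouse_days": [],
    }
    for m in config.mothers:
        days = int(rng.integers(lo, hi + 1))
        base, extra = divmod(m.n_seeds, n_gardens)
        counts = np.full(n_gardens, base)
        if extra:
            counts[rng.choice(n_gardens, size=extra, replace=False)] += 1
        i = 0
        for gi, g in enumerate(garden_ids):
            for _ in range(int(counts[gi])):
                i += 1
                rows["individual_id"].append(f"{m.mother_id}-{i:03d}")
                rows["mother_id"].append(m.mother_id)
                rows["garden_id"].append(g)
                rows["ecotype"].append(m.ecotype)
                rows["habitat"].append(garden_habitat[g])
                rows["provenance"].append(m.provenance)
                rows["plantation"].append(garden_region[g])
                rows["shadehouse_days"].append(days)
    return pd.DataFrame(rows)


def _lookup(mapping: Mapping, keys, default: float = 0.0) -> np.ndarray:
    return np.array([float(mapping.get(k, default)) for k in keys])


def simulate_germination(
    design: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Add ``germ_year`` (0 = in the shadehouse, 1..n = field census year,
    -1 = never) and ``status`` columns."""
    g = config.germination
    e = design["ecotype"]
    o = design["provenance"]
    t = design["shadehouse_days"].to_numpy(dtype=float)
    eta = (
        g.intercept
        + _lookup(g.ecotype, e)
        + _lookup(g.provenance, o)
        + _lookup(g.interaction, zip(e, o))
        + (g.slope + _lookup(g.slope_ecotype, e) + _lookup(g.slope_provenance, o)) * t
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    n = len(design)
    germ_year = np.full(n, -1, dtype=int)
    germ_year[rng.random(n) < p] = 0
    hazards = np.array(
        [
            config.hazard(o_, r_, h_)
            for o_, r_, h_ in zip(design["provenance"], design["plantation"], design["habitat"])
        ]
    )
    u = rng.random((n, config.n_years))
    for y in range(1, config.n_years + 1):
        pending = germ_year < 0
        germ_year[pending & (u[:, y - 1] < hazards)] = y
    out = design.copy()
    out["germ_year"] = germ_year
    out["status"] = np.where(germ_year == 0, "seedling", "seed")
    return out


def simulate_survival_and_growth(
    design: pd.DataFrame,
    config: SimulationConfig,
    rng_survival: np.random.Generator,
    rng_growth: np.random.Generator,
    rng_herbivory: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw yearly survival fates and per-age trait measurements.

    Returns ``(individuals_frame, measurements_frame)`` where the first
    adds ``death_year`` (0 = alive at study end) and ``fate_y*`` columns
    and the second is a long measurement table.
    """
    s = config.survival
    eh = list(zip(design["ecotype"], design["habitat"]))
    ors = list(zip(design["provenance"], design["plantation"], design["status"]))
    ehors = [k1 + k2 for k1, k2 in zip(eh, ors)]
    eta = (
        s.intercept
        + _lookup(s.ecotype_habitat, eh)
        + _lookup(s.ors, ors)
        + _lookup(s.interaction, ehors)
    )
    q = 1.0 / (1.0 + np.exp(-eta))
    n = len(design)
    germ_year = design["germ_year"].to_numpy()
    death_year = np.zeros(n, dtype=int)
    u = rng_survival.random((n, config.n_years))
    for y in range(1, config.n_years + 1):
        at_risk = (germ_year >= 0) & (germ_year < y) & (death_year == 0)
        death_year[at_risk & (u[:, y - 1] >= q)] = y

    out = design.copy()
    out["death_year"] = death_year
    for y in range(1, config.n_years + 1):
        fate = np.where(
            (germ_year < 0) | (germ_year > y),
            "pre_germination",
            np.where((death_year > 0) & (death_year <= y), "dead", "alive"),
        )
        out[f"fate_y{y}"] = fate

    # measurements for alive (individual, age) pairs
    meas: dict[str, list] = {"individual_id": [], "age": [], "trait": [], "value": []}
    ids = design["individual_id"].to_numpy()
    for a in config.observed_ages:
        alive = (germ_year >= 0) & (germ_year <= a) & ((death_year == 0) | (a < death_year))
        idx = np.nonzero(alive)[0]
        if len(idx) == 0:
            continue
        for trait, gc in config.growth.items():
            mu = (
                gc.intercept
                + _lookup(gc.ecotype_habitat, (eh[i] for i in idx))
                + _lookup(gc.ors, (ors[i] for i in idx))
                + (
                    gc.age_slope
                    + _lookup(gc.age_ecotype_habitat, (eh[i] for i in idx))
                    + _lookup(gc.age_ors, (ors[i] for i in idx))
                )
                * a
            )
            ln_y = mu + gc.sigma * rng_growth.standard_normal(len(idx))
            vals = np.exp(ln_y)
            if trait == "tnl":
                vals = np.maximum(1.0, np.round(vals))
            meas["individual_id"].extend(ids[idx])
            meas["age"].extend([a] * len(idx))
            meas["trait"].extend([trait] * len(idx))
            meas["value"].extend(vals.tolist())
        if config.herbivory_probs is not None:
            n_leaves = 1 + rng_herbivory.poisson(4.0, size=len(idx))
            scores = np.empty(len(idx))
            eh_arr = np.array([f"{e}|{h}" for e, h in (eh[i] for i in idx)])
            midpoints = np.array([HERBIVORY_MIDPOINTS[c] for c in HERBIVORY_CLASSES])
            for key, probs in config.herbivory_probs.items():
                mask = eh_arr == f"{key[0]}|{key[1]}"
                if not mask.any():
                    continue
                counts = rng_herbivory.multinomial(n_leaves[mask], np.asarray(probs, dtype=float))
                scores[mask] = counts @ midpoints / n_leaves[mask]
            meas["individual_id"].extend(ids[idx])
            meas["age"].extend([a] * len(idx))
            meas["trait"].extend(["herbivory_pct"] * len(idx))
            meas["value"].extend(scores.tolist())
    return out, pd.DataFrame(meas)


def simulate_frames(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all stages and return the two flat tables (fast path used by
    simulation-heavy tests; :func:`simulate_dataset` wraps them in record
    objects)."""
    rng = _streams(seed)
    design = simulate_design(config, rng["design"])
    design = simulate_germination(design, config, rng["germination"])
    ind, meas = simulate_survival_and_growth(
        design, config, rng["survival"], rng["growth"], rng["herbivory"]
    )
    timing = np.where(
        ind["germ_year"] < 0,
        GERM_NEVER,
        np.where(ind["germ_year"] == 0, GERM_AT_TRANSPLANT, ""),
    ).astype(object)
    field_years = ind["germ_year"].to_numpy()
    for i in np.nonzero(field_years > 0)[0]:
        timing[i] = f"year{field_years[i]}"
    ind = ind.copy()
    ind["germ_timing"] = timing
    return ind, meas


def simulate_dataset(
    config: SimulationConfig, seed: int
) -> tuple[list[IndividualRecord], list[MeasurementRecord], dict]:
    """Generate a full synthetic dataset.

    Returns validated individual and measurement records plus a provenance
    dictionary echoing the seed and true generative parameters.
    """
    ind, meas = simulate_frames(config, seed)
    fate_cols = [f"fate_y{y}" for y in range(1, config.n_years + 1)]
    individuals = [
        IndividualRecord(
            individual_id=row.individual_id,
            mother_id=row.mother_id,
            garden_id=row.garden_id,
            ecotype=row.ecotype,
            habitat=row.habitat,
            provenance=row.provenance,
            plantation=row.plantation,
            status=row.status,
            shadehouse_days=int(row.shadehouse_days),
            germ_timing=row.germ_timing,
            fate_by_year=tuple(getattr(row, c) for c in fate_cols),
        )
        for row in ind.itertuples(index=False)
    ]
    measurements = [
        MeasurementRecord(
            individual_id=row.individual_id,
            age=int(row.age),
            trait=row.trait,
            value=float(row.value),
        )
        for row in meas.itertuples(index=False)
    ]
    truth = {"seed": seed, "config": config_to_dict(config)}
    return individuals, measurements, truth


# ---------------------------------------------------------------------------
# Config (de)serialization — tuple keys become ":"-joined strings
# ---------------------------------------------------------------------------


def _enc_map(m: Mapping) -> dict:
    return {
        (":".join(k) if isinstance(k, tuple) else str(k)): (
            list(v) if isinstance(v, (tuple, list)) else float(v)
        )
        for k, v in m.items()
    }


def _dec_map(d: Mapping | None, tuple_keys: bool) -> dict:
    if not d:
        return {}
    out = {}
    for k, v in d.items():
        key = tuple(k.split(":")) if tuple_keys and ":" in str(k) else k
        out[key] = tuple(v) if isinstance(v, list) else float(v)
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    g, s = config.germination, config.survival
    return {
        "mothers": [[m.mother_id, m.provenance, m.ecotype, m.n_seeds] for m in config.mothers],
        "gardens": [list(x) for x in config.gardens],
        "shadehouse_days_range": list(config.shadehouse_days_range),
        "n_years": config.n_years,
        "observed_ages": list(config.observed_ages),
        "field_hazard_default": config.field_hazard_default,
        "field_hazard": _enc_map(config.field_hazard),
        "germination": {
            "intercept": g.intercept,
            "ecotype": _enc_map(g.ecotype),
            "provenance": _enc_map(g.provenance),
            "interaction": _enc_map(g.interaction),
            "slope": g.slope,
            "slope_ecotype": _enc_map(g.slope_ecotype),
            "slope_provenance": _enc_map(g.slope_provenance),
        },
        "survival": {
            "intercept": s.intercept,
            "ecotype_habitat": _enc_map(s.ecotype_habitat),
            "ors": _enc_map(s.ors),
            "interaction": _enc_map(s.interaction),
        },
        "growth": {
            trait: {
                "intercept": gc.intercept,
                "ecotype_habitat": _enc_map(gc.ecotype_habitat),
                "ors": _enc_map(gc.ors),
                "age_slope": gc.age_slope,
                "age_ecotype_habitat": _enc_map(gc.age_ecotype_habitat),
                "age_ors": _enc_map(gc.age_ors),
                "sigma": gc.sigma,
            }
            for trait, gc in config.growth.items()
        },
        "herbivory_probs": _enc_map(config.herbivory_probs) if config.herbivory_probs else None,
    }


def config_from_dict(d: Mapping) -> SimulationConfig:
    g = d.get("germination", {})
    s = d.get("survival", {})
    return SimulationConfig(
        mothers=tuple(MotherSpec(m[0], m[1], m[2], int(m[3])) for m in d["mothers"]),
        gardens=tuple(tuple(x) for x in d["gardens"]),
        shadehouse_days_range=tuple(d.get("shadehouse_days_range", (27, 315))),
        n_years=int(d.get("n_years", N_YEARS)),
        observed_ages=tuple(d.get("observed_ages", OBSERVED_AGES)),
        field_hazard_default=float(d.get("field_hazard_default", 0.2)),
        field_hazard=_dec_map(d.get("field_hazard"), True),
        germination=GerminationCoefs(
            intercept=float(g.get("intercept", 0.0)),
            ecotype=_dec_map(g.get("ecotype"), False),
            provenance=_dec_map(g.get("provenance"), False),
            interaction=_dec_map(g.get("interaction"), True),
            slope=float(g.get("slope", 0.0)),
            slope_ecotype=_dec_map(g.get("slope_ecotype"), False),
            slope_provenance=_dec_map(g.get("slope_provenance"), False),
        ),
        survival=SurvivalCoefs(
            intercept=float(s.get("intercept", 0.0)),
            ecotype_habitat=_dec_map(s.get("ecotype_habitat"), True),
            ors=_dec_map(s.get("ors"), True),
            interaction=_dec_map(s.get("interaction"), True),
        ),
        growth={
            trait: GrowthCoefs(
                intercept=float(gc.get("intercept", 0.0)),
                ecotype_habitat=_dec_map(gc.get("ecotype_habitat"), True),
                ors=_dec_map(gc.get("ors"), True),
                age_slope=float(gc.get("age_slope", 0.0)),
                age_ecotype_habitat=_dec_map(gc.get("age_ecotype_habitat"), True),
                age_ors=_dec_map(gc.get("age_ors"), True),
                sigma=float(gc.get("sigma", 0.1)),
            )
            for trait, gc in d.get("growth", {}).items()
        },
        herbivory_probs=(
            {k: tuple(v) for k, v in _dec_map(d["herbivory_probs"], True).items()}
            if d.get("herbivory_probs")
            else None
        ),
    )
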