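"""Shared fixtures and dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rtelab.records import IndividualRecord
from rtelab.simulate import (
    GerminationCoefs,
    GrowthCoefs,
    SimulationConfig,
    SurvivalCoefs,
    default_config,
)


def make_individual(**overrides) -> IndividualRecord:
    """A valid seedling record with sensible defaults, overridable per test."""
    base = dict(
        individual_id="I001",
        mother_id="M01",
        garden_id="G01",
        ecotype="glo",
        habitat="SF",
        provenance="E",
        plantation="E",
        status="seedling",
        shadehouse_days=89,
        germ_timing="at_transplant",
        fate_by_year=("alive",) * 5,
    )
    base.update(overrides)
    return IndividualRecord(**base)


def null_growth_config(sigma: float = 0.35, d: float = 0.0) -> SimulationConfig:
    """Study-scale config whose height trait carries *no* home/away effect
    beyond an optional planted cell shift ``d`` (+d home, -d away), with
    nonzero nuisance effects so the adjustment matters."""
    cfg = default_config()
    home_away = {
        ("glo", "SF"): +d,
        ("sp1", "HT"): +d,
        ("glo", "HT"): -d,
        ("sp1", "SF"): -d,
    }
    ors = {
        (o, r, s): (0.1 if o == r else -0.1) + (0.05 if s == "seedling" else -0.05)
        for o in "EW"
        for r in "EW"
        for s in ("seed", "seedling")
    }
    growth = {
        "height_cm": GrowthCoefs(
            intercept=np.log(12.0),
            ecotype_habitat=home_away,
            ors=ors,
            age_slope=0.3,
            age_ors={k: v / 5 for k, v in ors.items()},
            sigma=sigma,
        )
    }
    return SimulationConfig(
        mothers=cfg.mothers,
        gardens=cfg.gardens,
        germination=GerminationCoefs(intercept=0.3),
        survival=SurvivalCoefs(intercept=2.0),
        growth=growth,
        herbivory_probs=None,
        field_hazard={},
        field_hazard_default=0.4,
        shadehouse_days_range=cfg.shadehouse_days_range,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset shared across tests (seed 1234)."""
    from rtelab.simulate import simulate_dataset

    individuals, measurements, truth = simulate_dataset(default_config(), 1234)
    return individuals, measurements


@pytest.fixture
def rng():
    return np.random.default_rng(99)
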