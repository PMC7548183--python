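"""Experiment data model, CSV I/O, validation, and derived per-individual traits.

The unit of observation is an *individual*: a seed sown into a shadehouse,
transplanted into one of the field gardens, which may germinate (in the
shadehouse or later in the field), survive for some number of years, and be
measured yearly for growth-associated traits.

Two long-format tables describe a dataset:

``individuals.csv``
    one row per individual with its design-factor levels, shadehouse time,
    germination timing, and yearly fate codes;
``measurements.csv``
    one row per (individual, age, trait) with the measured value.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from rtelab.errors import (
    ConfigError,
    DataError,
    UndefinedRGRError,
    UndefinedScoreError,
)

# ---------------------------------------------------------------------------
# Factor levels and constants
# ---------------------------------------------------------------------------

ECOTYPES = ("glo", "sp1")
HABITATS = ("SF", "HT")
REGIONS = ("E", "W")
STATUSES = ("seed", "seedling")
FATES = ("pre_germination", "alive", "dead")
TRAITS = ("height_cm", "diameter_mm", "tnl", "herbivory_pct")

#: Leaf damage classes (percent damaged area) and their representative
#: midpoint values used to score a seedling's herbivory level.
HERBIVORY_CLASSES = ("c0_20", "c20_40", "c40_60", "c60_80", "c80_100")
HERBIVORY_MIDPOINTS = {
    "c0_20": 10.0,
    "c20_40": 30.0,
    "c40_60": 50.0,
    "c60_80": 70.0,
    "c80_100": 90.0,
}

#: Default number of yearly follow-up censuses after transplant.
N_YEARS = 5

#: Ages (years since transplant) at which measurements were taken; one
#: mid-study year was skipped, so age 3 is absent by default.
OBSERVED_AGES = (0, 1, 2, 4, 5)

#: Design-factor columns usable as grouping keys in count tables.
FACTOR_KEYS = ("mother_id", "garden_id", "ecotype", "habitat", "provenance", "plantation")

GERM_NEVER = "never"
GERM_AT_TRANSPLANT = "at_transplant"


def germ_timing_levels(n_years: int = N_YEARS) -> tuple[str, ...]:
    """Valid ``germ_timing`` codes for a study with ``n_years`` censuses."""
    return (GERM_AT_TRANSPLANT, *(f"year{y}" for y in range(1, n_years + 1)), GERM_NEVER)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndividualRecord:
    """One seed/seedling with its design-factor levels and yearly fate.

    ``fate_by_year`` holds one fate code per follow-up census (year 1 .. n),
    each one of ``pre_germination``, ``alive`` or ``dead``.
    """

    individual_id: str
    mother_id: str
    garden_id: str
    ecotype: str
    habitat: str
    provenance: str
    plantation: str
    status: str
    shadehouse_days: int
    germ_timing: str
    fate_by_year: tuple[str, ...]

    @property
    def n_years(self) -> int:
        return len(self.fate_by_year)

    def germination_year(self) -> int | None:
        """Census year at which the individual was first recorded as a
        seedling (0 = at transplant), or None if it never germinated."""
        if self.germ_timing == GERM_NEVER:
            return None
        if self.germ_timing == GERM_AT_TRANSPLANT:
            return 0
        return int(self.germ_timing.removeprefix("year"))

    def death_year(self) -> int | None:
        """First census year with fate ``dead``, or None."""
        for y, f in enumerate(self.fate_by_year, start=1):
            if f == "dead":
                return y
        return None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        for name, value, levels in (
            ("ecotype", self.ecotype, ECOTYPES),
            ("habitat", self.habitat, HABITATS),
            ("provenance", self.provenance, REGIONS),
            ("plantation", self.plantation, REGIONS),
            ("status", self.status, STATUSES),
        ):
            if value not in levels:
                problems.append(f"unknown {name} level {value!r}")
        if self.germ_timing not in germ_timing_levels(self.n_years):
            problems.append(f"unknown germ_timing {self.germ_timing!r}")
        if not (isinstance(self.shadehouse_days, int) and self.shadehouse_days >= 0):
            problems.append(f"shadehouse_days must be a non-negative integer, got {self.shadehouse_days!r}")
        for f in self.fate_by_year:
            if f not in FATES:
                problems.append(f"unknown fate code {f!r}")
                return problems
        # status <-> timing equivalence
        if (self.status == "seedling") != (self.germ_timing == GERM_AT_TRANSPLANT):
            problems.append(
                f"status {self.status!r} inconsistent with germ_timing {self.germ_timing!r}"
            )
        # fate series must be pre_germination* alive* dead* with the alive
        # phase starting exactly at the germination year
        g = self.germination_year() if self.germ_timing in germ_timing_levels(self.n_years) else None
        phase = 0  # 0 = pre, 1 = alive, 2 = dead
        for y, f in enumerate(self.fate_by_year, start=1):
            idx = FATES.index(f)
            if idx < phase:
                problems.append(f"fate regresses at year {y} ({f!r})")
                break
            phase = idx
            if f == "pre_germination" and g is not None and y >= g:
                problems.append(f"pre_germination at year {y} but germinated at year {g}")
                break
            if f != "pre_germination" and (g is None or y < g):
                problems.append(f"fate {f!r} at year {y} but germination year is {g}")
                break
        return problems


@dataclass(frozen=True)
class MeasurementRecord:
    """One trait value for one individual at one age (years since transplant)."""

    individual_id: str
    age: int
    trait: str
    value: float

    def validate(self, observed_ages: Sequence[int] = OBSERVED_AGES) -> list[str]:
        problems: list[str] = []
        if self.trait not in TRAITS:
            problems.append(f"unknown trait {self.trait!r}")
            return problems
        if self.age not in observed_ages:
            problems.append(f"age {self.age} outside observed ages {tuple(observed_ages)}")
        v = self.value
        if not math.isfinite(v):
            problems.append(f"non-finite value {v!r}")
        elif self.trait in ("height_cm", "diameter_mm") and v <= 0:
            problems.append(f"{self.trait} must be > 0, got {v}")
        elif self.trait == "tnl" and v < 1:
            problems.append(f"tnl must be >= 1, got {v}")
        elif self.trait == "herbivory_pct" and not (10.0 <= v <= 90.0):
            problems.append(f"herbivory_pct must lie in [10, 90], got {v}")
        return problems


# ---------------------------------------------------------------------------
# Derived traits
# ---------------------------------------------------------------------------


def herbivory_score(leaf_classes: Sequence[str]) -> float:
    """Seedling herbivory level: mean of per-leaf damage-class midpoints.

    Each leaf carries one of five damage classes covering 0-100% of leaf
    area in 20%-wide bands; the class is scored by its midpoint
    (10/30/50/70/90) and the seedling score is the arithmetic mean over all
    its leaves, hence always within [10, 90].
    """
    if len(leaf_classes) == 0:
        raise UndefinedScoreError("herbivory score undefined for an individual with no leaves")
    total = 0.0
    for c in leaf_classes:
        try:
            total += HERBIVORY_MIDPOINTS[c]
        except KeyError:
            raise DataError(f"unknown herbivory class {c!r}") from None
    return total / len(leaf_classes)


def relative_growth_rate(values: Sequence[tuple[float, float]]) -> float:
    """Average yearly relative growth rate over consecutive measurements.

    ``values`` is a sequence of ``(age, value)`` pairs; the rate is the mean
    over consecutive (age-sorted) pairs of ``(ln y2 - ln y1) / (a2 - a1)``,
    so a missing census year simply contributes one longer interval.
    """
    pts = sorted(values, key=lambda p: p[0])
    ages = [a for a, _ in pts]
    if len(set(ages)) != len(ages):
        raise DataError("duplicate ages in RGR input")
    for _, y in pts:
        if y <= 0:
            raise DataError(f"RGR requires strictly positive values, got {y}")
    if len(pts) < 2:
        raise UndefinedRGRError("RGR requires at least two measurements")
    rates = [
        (math.log(y2) - math.log(y1)) / (a2 - a1)
        for (a1, y1), (a2, y2) in zip(pts, pts[1:])
    ]
    return sum(rates) / len(rates)


def encode_survival_series(record: IndividualRecord) -> tuple[int, bool] | None:
    """Survival coding for the geometric lifetime model.

    Returns ``(final_age, censored)`` where ``final_age`` counts whole years
    from the germination census to the death census (uncensored) or to the
    last census (right-censored, still alive at study end).  Returns None
    for individuals that never germinated; they do not enter survival fits.
    """
    g = record.germination_year()
    if g is None:
        return None
    d = record.death_year()
    if d is not None:
        return d - g, False
    return record.n_years - g, True


def fate_code(record: IndividualRecord) -> str:
    """Seven-level fate code: ``U`` (never germinated), ``D1``..``Dn``
    (year of death), or ``A`` (alive at the final census)."""
    if record.germination_year() is None:
        return "U"
    d = record.death_year()
    if d is not None:
        return f"D{d}"
    return "A"


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def tabulate_counts(
    records: Iterable[IndividualRecord],
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Count table per group: seeds planted (Ni), germinated at transplant
    (Gt), germinated overall (Go), and alive at the final census (AliveY6).

    ``group_by`` may be any subset of mother/garden identifiers and design
    factors; an empty list yields the single grand-total row.
    """
    group_by = list(group_by)
    for key in group_by:
        if key not in FACTOR_KEYS:
            raise ConfigError(f"unknown grouping key {key!r}; valid keys: {FACTOR_KEYS}")
    rows = []
    for r in records:
        rows.append(
            {
                **{k: getattr(r, k) for k in group_by},
                "Ni": 1,
                "Gt": int(r.germ_timing == GERM_AT_TRANSPLANT),
                "Go": int(r.germ_timing != GERM_NEVER),
                "AliveY6": int(len(r.fate_by_year) > 0 and r.fate_by_year[-1] == "alive"),
            }
        )
    df = pd.DataFrame(rows, columns=[*group_by, "Ni", "Gt", "Go", "AliveY6"])
    count_cols = ["Ni", "Gt", "Go", "AliveY6"]
    df[count_cols] = df[count_cols].astype(int)
    if group_by:
        out = df.groupby(group_by, sort=True, as_index=False).sum()
    else:
        out = df[["Ni", "Gt", "Go", "AliveY6"]].sum().to_frame().T
    return out


# ---------------------------------------------------------------------------
# CSV layout and I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnLayout:
    """Mapping from canonical column names to the columns of a user file.

    ``columns`` maps canonical names (e.g. ``ecotype``) to file column
    names; unmapped canonical names are looked up verbatim.  ``levels``
    optionally recodes factor values per canonical field, e.g.
    ``{"habitat": {"flooded": "SF", "hilltop": "HT"}}``.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    levels: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def col(self, name: str) -> str:
        return self.columns.get(name, name)

    def decode(self, fieldname: str, value: str) -> str:
        return self.levels.get(fieldname, {}).get(value, value)


INDIVIDUAL_COLUMNS = (
    "individual_id",
    "mother_id",
    "garden_id",
    "ecotype",
    "habitat",
    "provenance",
    "plantation",
    "status",
    "shadehouse_days",
    "germ_timing",
)
MEASUREMENT_COLUMNS = ("individual_id", "age", "trait", "value")


def _fate_columns(n_years: int) -> list[str]:
    return [f"fate_y{y}" for y in range(1, n_years + 1)]


def load_records(
    individuals_path: str | Path,
    measurements_path: str | Path | None = None,
    layout: ColumnLayout | None = None,
    n_years: int = N_YEARS,
    observed_ages: Sequence[int] = OBSERVED_AGES,
) -> tuple[list[IndividualRecord], list[MeasurementRecord]]:
    """Read and validate an individuals table and (optionally) a
    measurements table.

    Raises :class:`ConfigError` when a mapped column is missing and
    :class:`DataError` (with row-addressed diagnostics collected across the
    whole file) when any row violates a record invariant.
    """
    layout = layout or ColumnLayout()
    ind_rows = _read_csv_rows(individuals_path)
    required = [layout.col(c) for c in INDIVIDUAL_COLUMNS] + [
        layout.col(c) for c in _fate_columns(n_years)
    ]
    _check_columns(individuals_path, ind_rows.columns, required)

    individuals: list[IndividualRecord] = []
    problems: list[str] = []
    bad_rows: list[int] = []
    for i, row in ind_rows.iterrows():
        rownum = i + 2  # 1-based with header
        try:
            days = int(row[layout.col("shadehouse_days")])
        except (TypeError, ValueError):
            problems.append(
                f"row {rownum}: shadehouse_days {row[layout.col('shadehouse_days')]!r} is not an integer"
            )
            bad_rows.append(rownum)
            continue
        rec = IndividualRecord(
            individual_id=str(row[layout.col("individual_id")]),
            mother_id=str(row[layout.col("mother_id")]),
            garden_id=str(row[layout.col("garden_id")]),
            ecotype=layout.decode("ecotype", str(row[layout.col("ecotype")])),
            habitat=layout.decode("habitat", str(row[layout.col("habitat")])),
            provenance=layout.decode("provenance", str(row[layout.col("provenance")])),
            plantation=layout.decode("plantation", str(row[layout.col("plantation")])),
            status=layout.decode("status", str(row[layout.col("status")])),
            shadehouse_days=days,
            germ_timing=layout.decode("germ_timing", str(row[layout.col("germ_timing")])),
            fate_by_year=tuple(
                layout.decode("fate", str(row[layout.col(c)])) for c in _fate_columns(n_years)
            ),
        )
        errs = rec.validate()
        if errs:
            problems.extend(f"row {rownum} ({rec.individual_id}): {e}" for e in errs)
            bad_rows.append(rownum)
        individuals.append(rec)

    _check_unique(
        (r.individual_id for r in individuals), "individual_id", problems, bad_rows
    )
    _check_garden_consistency(individuals, problems)

    measurements: list[MeasurementRecord] = []
    if measurements_path is not None:
        mrows = _read_csv_rows(measurements_path)
        _check_columns(
            measurements_path, mrows.columns, [layout.col(c) for c in MEASUREMENT_COLUMNS]
        )
        known_ids = {r.individual_id for r in individuals}
        seen: set[tuple[str, int, str]] = set()
        for i, row in mrows.iterrows():
            rownum = i + 2
            try:
                age = int(row[layout.col("age")])
                value = float(row[layout.col("value")])
            except (TypeError, ValueError):
                problems.append(f"row {rownum}: non-numeric age or value")
                bad_rows.append(rownum)
                continue
            m = MeasurementRecord(
                individual_id=str(row[layout.col("individual_id")]),
                age=age,
                trait=layout.decode("trait", str(row[layout.col("trait")])),
                value=value,
            )
            errs = m.validate(observed_ages)
            if m.individual_id not in known_ids:
                errs.append(f"unknown individual_id {m.individual_id!r}")
            key = (m.individual_id, m.age, m.trait)
            if key in seen:
                errs.append(f"duplicate measurement {key}")
            seen.add(key)
            if errs:
                problems.extend(f"row {rownum}: {e}" for e in errs)
                bad_rows.append(rownum)
            measurements.append(m)

    if problems:
        raise DataError(
            "invalid records:\n" + "\n".join(problems), rows=sorted(set(bad_rows))
        )
    return individuals, measurements


def write_records(
    individuals: Iterable[IndividualRecord],
    measurements: Iterable[MeasurementRecord],
    individuals_path: str | Path,
    measurements_path: str | Path,
    n_years: int = N_YEARS,
) -> None:
    """Write the two CSV tables; inverse of :func:`load_records`."""
    individuals = list(individuals)
    with open(individuals_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([*INDIVIDUAL_COLUMNS, *_fate_columns(n_years)])
        for r in individuals:
            w.writerow(
                [
                    r.individual_id,
                    r.mother_id,
                    r.garden_id,
                    r.ecotype,
                    r.habitat,
                    r.provenance,
                    r.plantation,
                    r.status,
                    r.shadehouse_days,
                    r.germ_timing,
                    *r.fate_by_year,
                ]
            )
    with open(measurements_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(MEASUREMENT_COLUMNS)
        for m in measurements:
            w.writerow([m.individual_id, m.age, m.trait, repr(m.value)])


def validation_report(
    individuals: Sequence[IndividualRecord],
    measurements: Sequence[MeasurementRecord],
) -> dict:
    """Machine-readable summary of a validated dataset."""
    germinated = [r for r in individuals if r.germ_timing != GERM_NEVER]
    return {
        "n_individuals": len(individuals),
        "n_measurements": len(measurements),
        "n_mothers": len({r.mother_id for r in individuals}),
        "n_gardens": len({r.garden_id for r in individuals}),
        "n_germinated_at_transplant": sum(
            r.germ_timing == GERM_AT_TRANSPLANT for r in individuals
        ),
        "n_germinated_overall": len(germinated),
        "n_alive_final": sum(
            r.fate_by_year[-1] == "alive" for r in individuals if r.fate_by_year
        ),
        "fate_codes": dict(sorted(Counter(fate_code(r) for r in individuals).items())),
    }


# ---------------------------------------------------------------------------
# Frame conversion helpers (used by the model-fitting stages)
# ---------------------------------------------------------------------------


def individuals_frame(individuals: Sequence[IndividualRecord]) -> pd.DataFrame:
    """Individuals as a DataFrame (factors + shadehouse days + timings)."""
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in individuals],
            "mother_id": [r.mother_id for r in individuals],
            "garden_id": [r.garden_id for r in individuals],
            "ecotype": [r.ecotype for r in individuals],
            "habitat": [r.habitat for r in individuals],
            "provenance": [r.provenance for r in individuals],
            "plantation": [r.plantation for r in individuals],
            "status": [r.status for r in individuals],
            "shadehouse_days": [r.shadehouse_days for r in individuals],
            "germ_timing": [r.germ_timing for r in individuals],
            "fate": [fate_code(r) for r in individuals],
        }
    )


def measurements_frame(measurements: Sequence[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [m.individual_id for m in measurements],
            "age": [m.age for m in measurements],
            "trait": [m.trait for m in measurements],
            "value": [m.value for m in measurements],
        }
    )


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _read_csv_rows(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _check_columns(path, present, required) -> None:
    missing = [c for c in required if c not in set(present)]
    if missing:
        raise ConfigError(f"{path}: missing required columns {missing}")


def _check_unique(ids, what, problems, bad_rows) -> None:
    counts = Counter(ids)
    for value, n in counts.items():
        if n > 1:
            problems.append(f"duplicate {what} {value!r} ({n} rows)")


def _check_garden_consistency(individuals, problems) -> None:
    # garden_id must determine (plantation, habitat) uniquely
    seen: dict[str, tuple[str, str]] = {}
    for r in individuals:
        key = (r.plantation, r.habitat)
        if r.garden_id in seen and seen[r.garden_id] != key:
            problems.append(
                f"garden {r.garden_id!r} maps to both {seen[r.garden_id]} and {key}"
            )
        seen.setdefault(r.garden_id, key)
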