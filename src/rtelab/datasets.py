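"""Bundled reference count tables for a 510-seed reciprocal transplant cohort.

The published study this package is modelled on followed 510 individuals
from 14 mother trees planted across 12 gardens (2 regions x 2 habitats x 3
replicates).  Its printed per-mother and per-garden count summaries are
bundled here so that count tabulation can be exercised and cross-checked
without downloading the deposited raw data.  Each row carries: seeds
planted (Ni), germinated at transplant (Gt), germinated overall (Go), and
alive at the final census (AliveY6).
"""

from __future__ import annotations

from rtelab.records import GERM_AT_TRANSPLANT, GERM_NEVER, IndividualRecord, N_YEARS

#: (mother_id, provenance, ecotype, Ni, Gt, Go, AliveY6)
MOTHER_COUNTS = (
    ("W426", "E", "glo", 36, 27, 31, 18),
    ("W503", "E", "glo", 37, 21, 29, 12),
    ("M837", "E", "sp1", 36, 25, 30, 14),
    ("W424", "E", "sp1", 38, 38, 38, 17),
    ("W425", "E", "sp1", 39, 31, 37, 15),
    ("W463", "W", "glo", 36, 16, 18, 9),
    ("W466", "W", "glo", 36, 2, 13, 12),
    ("W497", "W", "glo", 36, 7, 23, 17),
    ("W498", "W", "glo", 35, 1, 10, 10),
    ("W465", "W", "sp1", 36, 0, 8, 7),
    ("W474", "W", "sp1", 36, 0, 18, 14),
    ("W475", "W", "sp1", 36, 4, 20, 16),
    ("W476", "W", "sp1", 36, 0, 16, 15),
    ("W477", "W", "sp1", 37, 12, 21, 14),
)

#: (garden_id, plantation, habitat, Ni, Gt, Go, AliveY6)
GARDEN_COUNTS = (
    ("G01", "W", "HT", 42, 13, 31, 20),
    ("G02", "W", "HT", 44, 16, 28, 15),
    ("G03", "W", "HT", 43, 11, 26, 15),
    ("G04", "W", "SF", 42, 12, 17, 3),
    ("G05", "W", "SF", 42, 9, 18, 11),
    ("G06", "W", "SF", 44, 11, 20, 7),
    ("G07", "E", "SF", 42, 22, 34, 22),
    ("G08", "E", "SF", 41, 19, 23, 15),
    ("G09", "E", "SF", 42, 19, 31, 26),
    ("G10", "E", "HT", 42, 22, 31, 23),
    ("G11", "E", "HT", 43, 18, 29, 16),
    ("G12", "E", "HT", 43, 12, 24, 17),
)

#: The 12 standard gardens as (garden_id, plantation region, habitat).
STANDARD_GARDENS = tuple((g, r, h) for g, r, h, *_ in GARDEN_COUNTS)


def _build_individuals(groups, n_years: int) -> list[IndividualRecord]:
    """Construct minimal valid records matching per-group count rows.

    ``groups`` yields dicts with the factor levels shared by a group plus
    its Ni/Gt/Go/AliveY6 counts.  Within a group, the Gt transplant
    germinations come first, then the field germinations (recorded at the
    first census), then the never-germinated seeds; survivors are taken
    from the head of the germinated block.  The exact attribution within a
    group is unconstrained by count data and irrelevant to any tabulation
    over these factors.
    """
    out: list[IndividualRecord] = []
    for grp in groups:
        ni, gt, go, alive = grp["Ni"], grp["Gt"], grp["Go"], grp["AliveY6"]
        if not (0 <= gt <= go <= ni and 0 <= alive <= go):
            raise ValueError(f"inconsistent counts in group {grp}")
        for i in range(ni):
            if i < gt:
                timing, status = GERM_AT_TRANSPLANT, "seedling"
            elif i < go:
                timing, status = "year1", "seed"
            else:
                timing, status = GERM_NEVER, "seed"
            if timing == GERM_NEVER:
                fates = ("pre_germination",) * n_years
            elif i < alive:
                fates = ("alive",) * n_years
            elif timing == GERM_AT_TRANSPLANT:
                fates = ("dead",) * n_years
            else:  # field-germinated, died later
                fates = ("alive",) + ("dead",) * (n_years - 1)
            out.append(
                IndividualRecord(
                    individual_id=f"{grp['prefix']}-{i + 1:03d}",
                    mother_id=grp["mother_id"],
                    garden_id=grp["garden_id"],
                    ecotype=grp["ecotype"],
                    habitat=grp["habitat"],
                    provenance=grp["provenance"],
                    plantation=grp["plantation"],
                    status=status,
                    shadehouse_days=grp.get("shadehouse_days", 89),
                    germ_timing=timing,
                    fate_by_year=fates,
                )
            )
    return out


def records_from_mother_counts(
    rows=MOTHER_COUNTS, n_years: int = N_YEARS
) -> list[IndividualRecord]:
    """Individual records consistent with the per-mother count rows.

    Gardens are assigned round-robin over the 12 standard gardens; garden
    assignment does not affect any per-mother or grand-total tabulation.
    """
    groups = []
    for idx, (mother, prov, eco, ni, gt, go, alive) in enumerate(rows):
        g, r, h = STANDARD_GARDENS[idx % len(STANDARD_GARDENS)]
        groups.append(
            {
                "prefix": mother,
                "mother_id": mother,
                "garden_id": g,
                "ecotype": eco,
                "habitat": h,
                "provenance": prov,
                "plantation": r,
                "Ni": ni,
                "Gt": gt,
                "Go": go,
                "AliveY6": alive,
            }
        )
    return _build_individuals(groups, n_years)


def records_from_garden_counts(
    rows=GARDEN_COUNTS, n_years: int = N_YEARS
) -> list[IndividualRecord]:
    """Individual records consistent with the per-garden count rows.

    Mother identity, ecotype and provenance are not constrained by the
    garden table; placeholder levels are assigned round-robin.
    """
    groups = []
    for idx, (garden, plantation, habitat, ni, gt, go, alive) in enumerate(rows):
        groups.append(
            {
                "prefix": garden,
                "mother_id": f"M{idx % 14:02d}",
                "garden_id": garden,
                "ecotype": ("glo", "sp1")[idx % 2],
                "habitat": habitat,
                "provenance": ("E", "W")[idx % 2],
                "plantation": plantation,
                "Ni": ni,
                "Gt": gt,
                "Go": go,
                "AliveY6": alive,
            }
        )
    return _build_individuals(groups, n_years)
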