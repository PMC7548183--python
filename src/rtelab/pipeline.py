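"""End-to-end analysis pipeline: validate -> counts -> GLM/LS-means ->
home-vs-away contrasts -> trees/forest -> report bundle.

Every stage writes plain CSV/JSON/DOT artifacts into the output directory
and appends to a run manifest (config hash, seeds, package version, stage
log), so each reported number is traceable to a stage output file.
Re-running with the same inputs, config and seed reproduces all outputs
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

import rtelab
from rtelab import models
from rtelab.adaptation import (
    ECOTYPE_HABITAT_AWAY,
    ECOTYPE_HABITAT_HOME,
    PROVENANCE_PLANTATION_AWAY,
    PROVENANCE_PLANTATION_HOME,
    germination_overall_lsmeans,
    germination_time_comparison,
    home_away_contrast,
    lsmean,
)
from rtelab.ctree import forest_importance, grow_tree, tree_to_dot, tree_to_json, tree_to_text
from rtelab.errors import ConfigError, DataError, EstimabilityError, FitError, RTEError
from rtelab.records import (
    OBSERVED_AGES,
    TRAITS,
    individuals_frame,
    load_records,
    relative_growth_rate,
    tabulate_counts,
    validation_report,
    write_records,
)
from rtelab.simulate import SimulationConfig, config_from_dict, config_to_dict, simulate_dataset

TREE_COVARIATES = ("provenance", "plantation", "habitat", "ecotype", "status")


class PipelineError(RTEError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run.

    Either ``individuals_path`` (+ optional ``measurements_path``) or
    ``simulation`` must be provided.
    """

    individuals_path: str | None = None
    measurements_path: str | None = None
    simulation: SimulationConfig | None = None
    traits: tuple[str, ...] = TRAITS
    observed_ages: tuple[int, ...] = OBSERVED_AGES
    alpha: float = 0.05
    adjust: str = "bonferroni"
    n_perm: int = 999
    forest_trees: int = 50
    seed: int = 0
    coding: str = "sum_to_zero"
    include_trees: bool = True
    include_forest: bool = True

    def validate(self) -> None:
        if self.individuals_path is None and self.simulation is None:
            raise ConfigError("config needs either input paths or a simulation block")
        unknown = [t for t in self.traits if t not in TRAITS]
        if unknown:
            raise ConfigError(f"unknown trait(s) {unknown}; valid traits: {TRAITS}")
        if self.adjust not in ("none", "bonferroni", "holm"):
            raise ConfigError(f"unknown multiplicity adjustment {self.adjust!r}")

    def to_dict(self) -> dict:
        return {
            "individuals_path": self.individuals_path,
            "measurements_path": self.measurements_path,
            "simulation": config_to_dict(self.simulation) if self.simulation else None,
            "traits": list(self.traits),
            "observed_ages": list(self.observed_ages),
            "alpha": self.alpha,
            "adjust": self.adjust,
            "n_perm": self.n_perm,
            "forest_trees": self.forest_trees,
            "seed": self.seed,
            "coding": self.coding,
            "include_trees": self.include_trees,
            "include_forest": self.include_forest,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        sim = d.get("simulation")
        return cls(
            individuals_path=d.get("individuals_path"),
            measurements_path=d.get("measurements_path"),
            simulation=config_from_dict(sim) if sim else None,
            traits=tuple(d.get("traits", TRAITS)),
            observed_ages=tuple(d.get("observed_ages", OBSERVED_AGES)),
            alpha=float(d.get("alpha", 0.05)),
            adjust=d.get("adjust", "bonferroni"),
            n_perm=int(d.get("n_perm", 999)),
            forest_trees=int(d.get("forest_trees", 50)),
            seed=int(d.get("seed", 0)),
            coding=d.get("coding", "sum_to_zero"),
            include_trees=bool(d.get("include_trees", True)),
            include_forest=bool(d.get("include_forest", True)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: AnalysisConfig, outdir: str | Path, verbose: bool = False) -> dict:
    """Execute all stages and return the run manifest.

    A stage that cannot run because the data lack what it needs (no
    measurements, a single factor level, ...) is skipped with a notice;
    any other failure aborts with the stage name after writing a partial
    manifest to ``manifest.json``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": rtelab.__version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": [],
        "outputs": [],
        "notices": [],
    }

    def log(stage: str, **info):
        entry = {"stage": stage, **info}
        manifest["stages"].append(entry)
        if verbose:
            print(f"[{stage}] " + " ".join(f"{k}={v}" for k, v in info.items()))

    def emit(name: str):
        manifest["outputs"].append(name)

    def abort(stage: str, exc: Exception):
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _write_json(manifest, outdir / "manifest.json")
        raise PipelineError(stage, exc) from exc

    # ---- stage: data -----------------------------------------------------
    stage = "data"
    try:
        if config.simulation is not None:
            individuals, measurements, truth = simulate_dataset(config.simulation, config.seed)
            write_records(
                individuals,
                measurements,
                outdir / "individuals.csv",
                outdir / "measurements.csv",
                n_years=config.simulation.n_years,
            )
            _write_json(truth, outdir / "simulation_truth.json")
            emit("individuals.csv")
            emit("measurements.csv")
            emit("simulation_truth.json")
        else:
            individuals, measurements = load_records(
                config.individuals_path,
                config.measurements_path,
                observed_ages=config.observed_ages,
            )
        log(stage, n_individuals=len(individuals), n_measurements=len(measurements))
    except RTEError as exc:
        abort(stage, exc)

    # ---- stage: validate -------------------------------------------------
    stage = "validate"
    try:
        report = validation_report(individuals, measurements)
        _write_json(report, outdir / "validation.json")
        emit("validation.json")
        log(stage, **{k: v for k, v in report.items() if isinstance(v, int)})
    except Exception as exc:
        abort(stage, exc)

    # ---- stage: counts ---------------------------------------------------
    stage = "counts"
    try:
        for name, keys in (
            ("counts_total", ()),
            ("counts_by_mother", ("mother_id",)),
            ("counts_by_garden", ("garden_id",)),
            ("counts_by_cell", ("ecotype", "provenance", "plantation", "habitat")),
        ):
            _write_csv(tabulate_counts(individuals, keys), outdir / f"{name}.csv")
            emit(f"{name}.csv")
        log(stage, tables=4)
    except Exception as exc:
        abort(stage, exc)

    def model_stage(stage_name: str, fn):
        try:
            fn()
        except (DataError, EstimabilityError, FitError) as exc:
            manifest["notices"].append(f"{stage_name} skipped: {exc}")
            log(stage_name, skipped=True)
        except Exception as exc:
            abort(stage_name, exc)

    # ---- stage: germination ----------------------------------------------
    def germination():
        tbar = models.mean_shadehouse_days(individuals)
        fit_sh = models.fit_shadehouse_germination(individuals, coding=config.coding)
        rows = []
        for e in fit_sh.spec.levels["ecotype"]:
            for o in fit_sh.spec.levels["provenance"]:
                m = lsmean(
                    fit_sh,
                    {"ecotype": e, "provenance": o},
                    [],
                    at={"shadehouse_days": tbar},
                )
                rows.append(
                    {"ecotype": e, "provenance": o, "logit": m.estimate, "se": m.se}
                )
        for e in fit_sh.spec.levels["ecotype"]:
            m = lsmean(fit_sh, {"ecotype": e}, ["provenance"], at={"shadehouse_days": tbar})
            rows.append({"ecotype": e, "provenance": "", "logit": m.estimate, "se": m.se})
        df = pd.DataFrame(rows)
        df["t_bar_days"] = tbar
        _write_csv(df, outdir / "germination_shadehouse_lsmeans.csv")
        emit("germination_shadehouse_lsmeans.csv")

        fit_ov = models.fit_overall_germination(individuals, coding=config.coding)
        means, pairwise = germination_overall_lsmeans(
            fit_ov, ["ecotype", "provenance"], adjust=config.adjust
        )
        _write_csv(
            pd.DataFrame(
                [
                    {**m.focal, "logit": m.estimate, "se": m.se}
                    for m in means
                ]
            ),
            outdir / "germination_overall_lsmeans.csv",
        )
        _write_csv(pairwise, outdir / "germination_overall_pairwise.csv")
        emit("germination_overall_lsmeans.csv")
        emit("germination_overall_pairwise.csv")

        fit_t = models.fit_germination_timing(individuals, coding=config.coding)
        times, tpairs = germination_time_comparison(
            fit_t, ["provenance"], adjust=config.adjust
        )
        _write_csv(times, outdir / "germination_timing_lsmeans.csv")
        _write_csv(tpairs, outdir / "germination_timing_pairwise.csv")
        emit("germination_timing_lsmeans.csv")
        emit("germination_timing_pairwise.csv")
        log("germination", t_bar=round(tbar, 2))

    model_stage("germination", germination)

    # ---- stage: survival -------------------------------------------------
    def survival():
        fit = models.fit_survival(individuals, coding=config.coding)
        rows = []
        for e, h in ((e, h) for e in fit.spec.levels["ecotype"] for h in fit.spec.levels["habitat"]):
            m = lsmean(
                fit,
                {"ecotype": e, "habitat": h},
                ["provenance", "plantation", "status"],
            )
            rows.append({"ecotype": e, "habitat": h, "logit_q": m.estimate, "se": m.se})
        _write_csv(pd.DataFrame(rows), outdir / "survival_lsmeans.csv")
        emit("survival_lsmeans.csv")
        contrasts = []
        res = home_away_contrast(
            fit,
            ECOTYPE_HABITAT_HOME,
            ECOTYPE_HABITAT_AWAY,
            nuisance=["provenance", "plantation", "status"],
        )
        contrasts.append({"pairing": "ecotype_habitat", **_contrast_row(res)})
        res = home_away_contrast(
            fit,
            PROVENANCE_PLANTATION_HOME,
            PROVENANCE_PLANTATION_AWAY,
            nuisance=["ecotype", "habitat", "status"],
        )
        contrasts.append({"pairing": "provenance_plantation", **_contrast_row(res)})
        _write_csv(pd.DataFrame(contrasts), outdir / "survival_contrasts.csv")
        emit("survival_contrasts.csv")
        log("survival", n=fit.n_obs)

    model_stage("survival", survival)

    # ---- stage: growth ---------------------------------------------------
    def growth():
        if not measurements:
            raise DataError("no measurements available")
        lsmean_rows, contrast_rows = [], []
        fitted = 0
        for trait in config.traits:
            try:
                fit = models.fit_growth(individuals, measurements, trait, coding=config.coding)
            except (DataError, EstimabilityError) as exc:
                manifest["notices"].append(f"growth[{trait}] skipped: {exc}")
                continue
            fitted += 1
            for age in config.observed_ages:
                for pairing, home, away, nuisance in (
                    (
                        "ecotype_habitat",
                        ECOTYPE_HABITAT_HOME,
                        ECOTYPE_HABITAT_AWAY,
                        ["provenance", "plantation", "status"],
                    ),
                    (
                        "provenance_plantation",
                        PROVENANCE_PLANTATION_HOME,
                        PROVENANCE_PLANTATION_AWAY,
                        ["ecotype", "habitat", "status"],
                    ),
                ):
                    for cell in (*home, *away):
                        m = lsmean(fit, cell, nuisance, at={"age": age})
                        lsmean_rows.append(
                            {
                                "trait": trait,
                                "pairing": pairing,
                                **cell,
                                "age": age,
                                "estimate": m.estimate,
                                "se": m.se,
                            }
                        )
                    res = home_away_contrast(fit, home, away, nuisance, at={"age": age})
                    contrast_rows.append(
                        {"trait": trait, "pairing": pairing, "age": age, **_contrast_row(res)}
                    )
        if not fitted:
            raise DataError("no growth trait could be fitted")
        _write_csv(pd.DataFrame(lsmean_rows), outdir / "lsmeans.csv")
        _write_csv(pd.DataFrame(contrast_rows), outdir / "contrasts.csv")
        emit("lsmeans.csv")
        emit("contrasts.csv")
        log("growth", traits=fitted, rows=len(contrast_rows))

    model_stage("growth", growth)

    # ---- stage: trees ----------------------------------------------------
    def trees():
        idf = individuals_frame(individuals)
        seed_seq = np.random.SeedSequence(config.seed).spawn(2)
        tree = grow_tree(
            idf,
            list(TREE_COVARIATES),
            "fate",
            alpha=config.alpha,
            min_obs=2,
            n_perm=config.n_perm,
            rng=np.random.default_rng(seed_seq[0]),
        )
        (outdir / "tree_fate.txt").write_text(tree_to_text(tree) + "\n", encoding="utf-8")
        (outdir / "tree_fate.dot").write_text(tree_to_dot(tree, "fate") + "\n", encoding="utf-8")
        (outdir / "tree_fate.json").write_text(tree_to_json(tree) + "\n", encoding="utf-8")
        emit("tree_fate.txt")
        emit("tree_fate.dot")
        emit("tree_fate.json")
        n_trait_trees = 0
        trait_data = trait_tree_frames(individuals, measurements, config.observed_ages)
        rng = np.random.default_rng(seed_seq[1])
        for name, frame in trait_data.items():
            if len(frame) < 4:
                manifest["notices"].append(f"tree[{name}] skipped: too few rows")
                continue
            t = grow_tree(
                frame,
                list(TREE_COVARIATES),
                "response",
                alpha=config.alpha,
                min_obs=2,
                n_perm=config.n_perm,
                rng=rng,
            )
            (outdir / f"tree_{name}.txt").write_text(tree_to_text(t) + "\n", encoding="utf-8")
            (outdir / f"tree_{name}.dot").write_text(tree_to_dot(t, name) + "\n", encoding="utf-8")
            (outdir / f"tree_{name}.json").write_text(tree_to_json(t) + "\n", encoding="utf-8")
            emit(f"tree_{name}.txt")
            emit(f"tree_{name}.dot")
            emit(f"tree_{name}.json")
            n_trait_trees += 1
        log("trees", fate_nodes=tree.node_count(), trait_trees=n_trait_trees)

    if config.include_trees:
        model_stage("trees", trees)

    # ---- stage: forest ---------------------------------------------------
    def forest():
        idf = individuals_frame(individuals)
        imp = forest_importance(
            idf,
            list(TREE_COVARIATES),
            "fate",
            n_trees=config.forest_trees,
            seed=config.seed,
            alpha=config.alpha,
            n_perm=min(config.n_perm, 499),
        )
        _write_json(
            {
                "importances": imp.importances,
                "n_trees": imp.n_trees,
                "mean_oob_accuracy": float(np.nanmean(imp.per_tree_accuracy)),
            },
            outdir / "forest_importance.json",
        )
        emit("forest_importance.json")
        log("forest", n_trees=imp.n_trees)

    if config.include_forest:
        model_stage("forest", forest)

    manifest["completed"] = True
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _contrast_row(res) -> dict:
    return {
        "estimate": res.estimate,
        "se": res.se,
        "statistic": res.statistic,
        "p": res.p_value,
        "stars": res.stars,
    }


def trait_tree_frames(
    individuals, measurements, observed_ages: Sequence[int] = OBSERVED_AGES
) -> dict[str, pd.DataFrame]:
    """Per-response data frames for the trait trees.

    ``<trait>_final``: the value at the last observed age, for individuals
    germinated at transplant and alive at study end; ``<trait>_rgr``: the
    average yearly relative growth rate over all available measurements
    (needs at least two); ``herbivory_ave``: the mean herbivory score over
    the individual's measured ages.
    """
    idf = individuals_frame(individuals).set_index("individual_id")
    by_ind: dict[str, dict[str, list[tuple[int, float]]]] = {}
    for m in measurements:
        by_ind.setdefault(m.individual_id, {}).setdefault(m.trait, []).append(
            (m.age, m.value)
        )
    final_age = max(observed_ages)
    frames: dict[str, list[dict]] = {}

    def push(name: str, ind_id: str, value: float):
        row = idf.loc[ind_id]
        frames.setdefault(name, []).append(
            {
                **{c: row[c] for c in TREE_COVARIATES},
                "response": float(value),
            }
        )

    for ind_id, traits in by_ind.items():
        row = idf.loc[ind_id]
        germinated_at_start = row["germ_timing"] == "at_transplant"
        alive_final = row["fate"] == "A"
        for trait, pts in traits.items():
            if trait == "herbivory_pct":
                push("herbivory_ave", ind_id, float(np.mean([v for _, v in pts])))
                continue
            if germinated_at_start and alive_final:
                at_final = [v for a, v in pts if a == final_age]
                if at_final:
                    push(f"{trait}_final", ind_id, at_final[0])
            if len(pts) >= 2 and all(v > 0 for _, v in pts):
                push(f"{trait}_rgr", ind_id, relative_growth_rate(pts))
    return {name: pd.DataFrame(rows) for name, rows in frames.items()}
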