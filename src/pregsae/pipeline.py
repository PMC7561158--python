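"""End-to-end pipeline: validate, simulate, fit, estimate, map, report.

``run_all`` executes the full methodology on one config and writes every
artifact under a deterministic run directory.  Each CSV artifact carries
the config hash, seed and the verbatim canonical config in ``#`` header
lines; a MANIFEST lists artifacts with SHA-256 hashes; the run log counts
every excluded-record class.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import density as density_mod
from . import estimation, models, schema, synthetic
from .config import PipelineConfig
from .errors import SchemaError
from .geo import polygon_areas, read_polygons, total_bounds, write_polygons, polygons_to_geojson
from .truth import GroundTruth

# ---------------------------------------------------------------------------
# table io with config headers


def write_table(frame: pd.DataFrame, path, config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash: {config.hash()}\n")
            fh.write(f"# seed: {config.seed}\n")
            fh.write(f"# config: {config.canonical_json()}\n")
        frame.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# schema validation


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_on_violations(self) -> None:
        if self.violations:
            raise SchemaError(self.violations)


def _check_columns(frame: pd.DataFrame, required, table_name: str, report: ValidationReport):
    for col in required:
        if col not in frame.columns:
            report.violations.append(f"{table_name}: missing required column {col!r}")


def validate_schemas(tables: dict, polygons=None) -> ValidationReport:
    """Column-by-column check of every table against its documented dictionary.

    ``tables`` maps table names ("survey", "births", "pregnancies",
    "population") to DataFrames.  All violations are collected and reported
    at once.  With polygons supplied, birth coordinates falling outside the
    polygon bounding box are counted as warnings.
    """
    report = ValidationReport()
    dictionaries = {
        "survey": schema.SURVEY_COLUMNS,
        "births": schema.BIRTH_COLUMNS,
        "pregnancies": schema.PREGNANCY_COLUMNS,
        "population": schema.POPULATION_COLUMNS,
    }
    for name, required in dictionaries.items():
        if name in tables:
            _check_columns(tables[name], required, name, report)
    if polygons and "births" in tables:
        births = tables["births"]
        if {"longitude", "latitude"} <= set(births.columns):
            minx, miny, maxx, maxy = total_bounds(polygons)
            lon = births["longitude"].to_numpy(dtype=float)
            lat = births["latitude"].to_numpy(dtype=float)
            usable = ~(np.isnan(lon) | np.isnan(lat))
            outside = usable & ((lon < minx) | (lon > maxx) | (lat < miny) | (lat > maxy))
            n_out = int(outside.sum())
            if n_out:
                report.warnings.append(
                    f"births: {n_out} records with coordinates outside the polygon bounds"
                )
    return report


# ---------------------------------------------------------------------------
# run-all


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        sim = dict(config.simulate)
        truth_kwargs = {k: v for k, v in sim.items()
                        if k in GroundTruth.__dataclass_fields__ and k != "seed"}
        if "women_per_area" in truth_kwargs and isinstance(truth_kwargs["women_per_area"], list):
            truth_kwargs["women_per_area"] = tuple(truth_kwargs["women_per_area"])
        truth = GroundTruth(seed=config.seed, **truth_kwargs)
        bundle = synthetic.generate_bundle(
            truth,
            sampling_rate=sim.get("sampling_rate", 0.05),
            weight_dispersion=sim.get("weight_dispersion", 0.3),
            n_women=sim.get("n_women", 8000),
            age_bins=config.age_bins_tuples(),
        )
        synthetic.write_bundle(bundle, outdir / "inputs")
        return (bundle.survey_table, bundle.birth_table, bundle.pregnancy_table,
                bundle.population_table, bundle.polygons)
    paths = config.inputs
    return (
        read_table(paths["survey"]),
        read_table(paths["births"]),
        read_table(paths["pregnancies"]),
        read_table(paths["population"]),
        read_polygons(paths["polygons"]),
    )


def _density_outputs(name, estimates, weight_col, polygons, config, outdir, log):
    total_area = config.density.get("total_area") or sum(polygon_areas(polygons).values())
    annual_events = float(estimates[weight_col].sum()) / config.years_span
    radius = density_mod.search_radius(total_area, annual_events)
    cell = config.density.get("cell_size") or radius / 20.0
    # merge coordinates back in
    spec = density_mod.GridSpec.for_bounds(total_bounds(polygons), cell)
    pts = estimates[["longitude", "latitude", weight_col]].to_numpy(dtype=float)
    grid = density_mod.kernel_density(pts, radius, spec, years_span=config.years_span)
    density_mod.write_ascii_grid(grid, outdir / f"{name}_density.asc")
    density_mod.write_png(grid, outdir / f"{name}_density.png", title=name.replace("_", " "))
    log[f"{name}_search_radius_miles"] = round(radius, 1)
    log[f"{name}_annual_events"] = annual_events
    return grid


def run_all(config: PipelineConfig) -> Path:
    """Execute simulate -> fit f -> fit g -> estimate -> density -> report.

    Returns the run directory.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    outdir = config.run_dir()
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    run_log: dict = {"config_hash": config.hash(), "seed": config.seed}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
        return _Ctx()

    with stage("load-inputs"):
        survey, births, pregnancies, population, polygons = _load_inputs(config, outdir)
        report = validate_schemas(
            {"survey": survey, "births": births, "pregnancies": pregnancies,
             "population": population},
            polygons,
        )
        report.raise_on_violations()
        run_log["schema_warnings"] = report.warnings

    with stage("fit-intendedness"):
        model_f = models.fit_intendedness_model(
            survey, coding_scheme=config.coding_scheme, k_folds=config.k_folds,
            seed=config.seed, candidate_grid=config.candidate_grid,
        )
        write_table(model_f.cv_table, outdir / "cv_results_intendedness.csv", config)
        run_log["model_f_family"] = model_f.family
        run_log["model_f_cv_cstat"] = round(float(model_f.cv_cstat), 2)
        try:
            imp = models.importance_report(model_f, top_k=5)
            write_table(
                pd.DataFrame(imp["ranked"], columns=["feature", "gini_share"]),
                outdir / "importance_intendedness.csv", config,
            )
            run_log["model_f_top5_importance_share"] = round(imp["top_k_share"], 3)
        except models.UnsupportedOperationError:
            run_log["model_f_top5_importance_share"] = None

    with stage("fit-livebirth"):
        model_g = models.fit_livebirth_model(
            pregnancies, k_folds=config.k_folds, seed=config.seed,
            candidate_grid=config.candidate_grid,
        )
        write_table(model_g.cv_table, outdir / "cv_results_livebirth.csv", config)
        run_log["model_g_family"] = model_g.family
        run_log["model_g_cv_cstat"] = round(float(model_g.cv_cstat), 2)

    with stage("estimate"):
        birth_estimates, est_log = estimation.build_birth_estimates(
            model_f, model_g, births, polygons,
            g_floor=config.g_floor, age_bins=config.age_bins_tuples(),
        )
        area_estimates = estimation.aggregate(
            birth_estimates, population, years_span=config.years_span,
            age_bins=config.age_bins_tuples(), log=est_log,
        )
        summary = estimation.statewide_report(area_estimates, est_log)
        write_table(birth_estimates, outdir / "birth_estimates.csv", config)
        write_table(area_estimates, outdir / "area_estimates.csv", config)
        write_table(pd.DataFrame([summary]), outdir / "statewide_summary.csv", config)
        run_log.update({k: v for k, v in summary.items()})

        # choropleth-ready polygons: all-ages estimates on polygon properties
        all_rows = area_estimates[
            (area_estimates["age_group"] == estimation.ALL_AGES)
            & (area_estimates["area_id"] != estimation.STATEWIDE_ID)
        ]
        props = {
            str(r["area_id"]): {c: (None if pd.isna(r[c]) else float(r[c]))
                                for c in estimation.OUTCOME_COLUMNS}
            for _, r in all_rows.iterrows()
        }
        with open(outdir / "area_estimates.geojson", "w") as fh:
            json.dump(polygons_to_geojson(polygons, props), fh, indent=1)

    with stage("density"):
        coords = births.set_index("birth_id")[["longitude", "latitude"]]
        est_with_xy = birth_estimates.join(coords, on="birth_id")
        _density_outputs("unintended_births", est_with_xy, "y_hat",
                         polygons, config, outdir, run_log)
        _density_outputs("unintended_pregnancies", est_with_xy, "u_hat",
                         polygons, config, outdir, run_log)

    with stage("report"):
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(run_log, fh, sort_keys=True)
        manifest_lines = []
        for path in sorted(outdir.rglob("*")):
            if path.is_file() and path.name != "MANIFEST.txt":
                digest = hashlib.sha256(path.read_bytes()).hexdigest()
                manifest_lines.append(f"{digest}  {path.relative_to(outdir)}")
        (outdir / "MANIFEST.txt").write_text("\n".join(manifest_lines) + "\n")

    return outdir


def coding_sensitivity(config: PipelineConfig) -> pd.DataFrame:
    """Re-run the pipeline under the three codings of the "unsure" response.

    Returns one row per coding scheme with the statewide percentage of
    births (and pregnancies) estimated unintended — the coding-sensitivity
    analysis of how much the headline share depends on where "unsure"
    responders are placed.
    """
    rows = []
    for scheme in schema.CODING_SCHEMES:
        cfg = PipelineConfig.from_dict({**config.to_dict(), "coding_scheme": scheme})
        outdir = run_all(cfg)
        summary = read_table(outdir / "statewide_summary.csv").iloc[0]
        rows.append({
            "coding_scheme": scheme,
            "pct_births_unintended": float(summary["pct_births_unintended"]),
            "pct_pregnancies_unintended": float(summary["pct_pregnancies_unintended"]),
        })
    return pd.DataFrame(rows)
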