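"""Applying the fitted models to birth records and aggregating by area.

For each birth b with covariates X_b, Z_b the pipeline computes

* y_hat = f(X_b), the probability the birth came from an unintended
  pregnancy;
* u_hat = y_hat / g(Z_b, 1), the expected number of unintended pregnancies
  the birth represents (an inverse-probability multiplier: if only a
  fraction g of unintended pregnancies reach a live birth, each observed
  unintended birth stands for 1/g unintended pregnancies);
* p_hat = y_hat / g(Z_b, 1) + (1 - y_hat) / g(Z_b, 0), the expected total
  pregnancies represented.

Births are assigned to areas by point-in-polygon on their coordinates, and
the per-birth quantities are aggregated into per-area (x age-group) counts
per year, percentages, and incidence per 1,000 resident women.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from . import schema
from .errors import InvalidArgumentError, SchemaError
from .geo import Polygons

DEFAULT_G_FLOOR = 0.05


# ---------------------------------------------------------------------------
# prediction on the birth file


@dataclass
class BirthPredictions:
    """Retained births with predictions, plus exclusion bookkeeping."""

    frame: pd.DataFrame
    n_excluded_coordinates: int = 0


def predict_births(model_f, birth_table: pd.DataFrame) -> BirthPredictions:
    """Apply the intendedness model to every usable birth record.

    Records whose coordinates are missing cannot be placed in an area and
    are excluded up front; their count is reported alongside the
    predictions, mirroring how vital-records analyses account for
    ungeocodable addresses.
    """
    needed = set(getattr(model_f, "feature_names", []) or [])
    base_needed = {c[:-3] if c.endswith("_mi") else c for c in needed}
    missing_cols = sorted(c for c in base_needed if c not in birth_table.columns)
    if missing_cols:
        raise SchemaError([f"birth table missing feature column: {c}" for c in missing_cols])

    usable = birth_table["longitude"].notna() & birth_table["latitude"].notna()
    n_excluded = int((~usable).sum())
    frame = birth_table.loc[usable].copy().reset_index(drop=True)
    y_hat = np.asarray(model_f.predict(frame), dtype=float)
    if len(y_hat) and (y_hat.min() < 0 or y_hat.max() > 1):
        raise InvalidArgumentError("model produced probabilities outside [0, 1]")
    frame["y_hat"] = y_hat
    return BirthPredictions(frame=frame, n_excluded_coordinates=n_excluded)


def predict_livebirth_probabilities(model_g, birth_table: pd.DataFrame):
    """g(Z, 1) and g(Z, 0) for every birth record: the live-birth probability
    with intendedness forced to unintended and to not-unintended."""
    forced = birth_table.copy()
    forced["unintended"] = 1.0
    g1 = np.asarray(model_g.predict(forced), dtype=float)
    forced["unintended"] = 0.0
    g0 = np.asarray(model_g.predict(forced), dtype=float)
    return g1, g0


def pregnancy_multipliers(y_hat, g1, g0, g_floor: float = DEFAULT_G_FLOOR):
    """Per-birth expected unintended (u_hat) and total (p_hat) pregnancies.

    The live-birth probabilities are floored at ``g_floor`` before division
    so near-zero predictions cannot explode the inverse weights.
    """
    if g_floor <= 0:
        raise InvalidArgumentError("g_floor must be > 0")
    y = np.asarray(y_hat, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise InvalidArgumentError("y_hat must lie in [0, 1]")
    g1f = np.maximum(np.asarray(g1, dtype=float), g_floor)
    g0f = np.maximum(np.asarray(g0, dtype=float), g_floor)
    u_hat = y / g1f
    p_hat = y / g1f + (1.0 - y) / g0f
    return u_hat, p_hat


# ---------------------------------------------------------------------------
# area assignment


def assign_area(latitude, longitude, polygons: Polygons):
    """Containing area id for each point, or None when no polygon contains it.

    Boundary points (shared edges of a tiling) resolve to the polygon whose
    id sorts first, so assignment is deterministic.  Accepts scalars or
    arrays; scalar input returns a scalar.
    """
    if not polygons:
        raise InvalidArgumentError("polygon set is empty")
    scalar = np.isscalar(latitude) and np.isscalar(longitude)
    lat = np.atleast_1d(np.asarray(latitude, dtype=float))
    lon = np.atleast_1d(np.asarray(longitude, dtype=float))
    if lat.shape != lon.shape:
        raise InvalidArgumentError("latitude and longitude must have equal length")

    ids = sorted(polygons)
    tree = STRtree([polygons[a] for a in ids])
    points = shapely.points(lon, lat)
    pt_idx, poly_idx = tree.query(points, predicate="intersects")

    assigned = np.full(len(lat), None, dtype=object)
    # min() over matching ids implements the lexicographic boundary tie-break
    order = np.argsort(poly_idx, kind="mergesort")
    for pi, gi in zip(pt_idx[order], poly_idx[order]):
        if assigned[pi] is None:
            assigned[pi] = ids[gi]
    if scalar:
        return assigned[0]
    return assigned


# ---------------------------------------------------------------------------
# building the per-birth estimates table


@dataclass
class EstimationLog:
    """Counts of every excluded-record class, carried into the report."""

    n_excluded_coordinates: int = 0
    n_unassigned_area: int = 0
    n_undefined_incidence_cells: int = 0
    notes: list = field(default_factory=list)


def build_birth_estimates(
    model_f,
    model_g,
    birth_table: pd.DataFrame,
    polygons: Polygons,
    g_floor: float = DEFAULT_G_FLOOR,
    age_bins=None,
) -> tuple[pd.DataFrame, EstimationLog]:
    """Assemble the per-birth estimates table: y_hat, u_hat, p_hat, area, age group.

    Passing ``model_g=None`` applies the no-loss limit g = 1 everywhere, in
    which case each birth represents exactly one pregnancy.
    """
    age_bins = schema.DEFAULT_AGE_BINS if age_bins is None else age_bins
    schema.validate_age_bins(age_bins)
    log = EstimationLog()

    preds = predict_births(model_f, birth_table)
    log.n_excluded_coordinates = preds.n_excluded_coordinates
    frame = preds.frame

    area = assign_area(frame["latitude"].to_numpy(), frame["longitude"].to_numpy(), polygons)
    keep = np.array([a is not None for a in area])
    log.n_unassigned_area = int((~keep).sum())
    frame = frame.loc[keep].reset_index(drop=True)
    frame["area_id"] = np.asarray(area, dtype=object)[keep]

    if model_g is None:
        g1 = np.ones(len(frame))
        g0 = np.ones(len(frame))
    else:
        g1, g0 = predict_livebirth_probabilities(model_g, frame)
    u_hat, p_hat = pregnancy_multipliers(frame["y_hat"].to_numpy(), g1, g0, g_floor)
    frame["u_hat"] = u_hat
    frame["p_hat"] = p_hat

    edges = [b[0] for b in age_bins] + [age_bins[-1][1] + 1]
    labels = [schema.age_bin_label(b) for b in age_bins]
    ages = frame["mother_age"].to_numpy(dtype=float)
    idx = np.clip(np.digitize(ages, edges) - 1, 0, len(labels) - 1)
    frame["age_group"] = np.array(labels, dtype=object)[idx]

    cols = ["birth_id", "area_id", "age_group", "mother_age", "y_hat", "u_hat", "p_hat"]
    return frame[cols], log


# ---------------------------------------------------------------------------
# aggregation

STATEWIDE_ID = "statewide"
ALL_AGES = "all"

OUTCOME_COLUMNS = [
    "births_per_year",
    "unintended_births_per_year",
    "pct_births_unintended",
    "incidence_births_per_1000",
    "pregnancies_per_year",
    "unintended_pregnancies_per_year",
    "pct_pregnancies_unintended",
    "incidence_pregnancies_per_1000",
    "women_count",
]


def _cell(sub: pd.DataFrame, women: float, years_span: float) -> dict:
    n_births = len(sub)
    sum_y = float(sub["y_hat"].sum())
    sum_u = float(sub["u_hat"].sum())
    sum_p = float(sub["p_hat"].sum())
    unintended_per_year = sum_y / years_span
    unintended_preg_per_year = sum_u / years_span
    return {
        "births_per_year": n_births / years_span,
        "unintended_births_per_year": unintended_per_year,
        "pct_births_unintended": 100.0 * sum_y / n_births if n_births else np.nan,
        "incidence_births_per_1000": 1000.0 * unintended_per_year / women if women > 0 else np.nan,
        "pregnancies_per_year": sum_p / years_span,
        "unintended_pregnancies_per_year": unintended_preg_per_year,
        "pct_pregnancies_unintended": 100.0 * sum_u / sum_p if sum_p > 0 else np.nan,
        "incidence_pregnancies_per_1000": 1000.0 * unintended_preg_per_year / women if women > 0 else np.nan,
        "women_count": women,
    }


def aggregate(
    birth_estimates: pd.DataFrame,
    population_table: pd.DataFrame,
    years_span: float = 3.0,
    age_bins=None,
    log: EstimationLog | None = None,
) -> pd.DataFrame:
    """Area-level (x age-group) outcomes, plus "all"-ages and statewide rows.

    Per-year counts divide the summed per-birth quantities by the span of
    the birth window; percentages are ratios of those sums; incidence is
    per 1,000 resident women from the population table.  Cells with births
    but no resident women get undefined (NaN) incidence and are counted in
    the log.
    """
    if years_span <= 0:
        raise InvalidArgumentError("years_span must be > 0")
    age_bins = schema.DEFAULT_AGE_BINS if age_bins is None else age_bins
    schema.validate_age_bins(age_bins)
    if birth_estimates["area_id"].isna().any():
        raise InvalidArgumentError("every birth estimate must carry an area id")
    labels = [schema.age_bin_label(b) for b in age_bins]

    pop = population_table.groupby(["area_id", "age_group"])["women"].sum()
    pop_area = population_table.groupby("area_id")["women"].sum()
    pop_state_age = population_table.groupby("age_group")["women"].sum()
    pop_state = float(population_table["women"].sum())

    rows = []
    area_ids = sorted(
        set(pop_area.index.astype(str)) | set(map(str, birth_estimates["area_id"].unique()))
    )
    for aid in area_ids:
        sub_a = birth_estimates[birth_estimates["area_id"] == aid]
        for lab in labels:
            women = float(pop.get((aid, lab), 0.0))
            rows.append({"area_id": aid, "age_group": lab,
                         **_cell(sub_a[sub_a["age_group"] == lab], women, years_span)})
        rows.append({"area_id": aid, "age_group": ALL_AGES,
                     **_cell(sub_a, float(pop_area.get(aid, 0.0)), years_span)})
    for lab in labels:
        rows.append({"area_id": STATEWIDE_ID, "age_group": lab,
                     **_cell(birth_estimates[birth_estimates["age_group"] == lab],
                             float(pop_state_age.get(lab, 0.0)), years_span)})
    rows.append({"area_id": STATEWIDE_ID, "age_group": ALL_AGES,
                 **_cell(birth_estimates, pop_state, years_span)})

    table = pd.DataFrame(rows, columns=["area_id", "age_group"] + OUTCOME_COLUMNS)
    if log is not None:
        has_births = table["births_per_year"] > 0
        log.n_undefined_incidence_cells = int(
            (has_births & table["incidence_births_per_1000"].isna()).sum()
        )
    return table


def statewide_report(area_estimates: pd.DataFrame, log: EstimationLog | None = None) -> dict:
    """One-row statewide summary at the reporting grain of the study:
    counts to the nearest 100, percentages to 0.1, incidence to the nearest
    integer per 1,000 women."""
    row = area_estimates[
        (area_estimates["area_id"] == STATEWIDE_ID) & (area_estimates["age_group"] == ALL_AGES)
    ]
    if row.empty:
        raise InvalidArgumentError("area_estimates has no statewide row; run aggregate first")
    r = row.iloc[0]
    report = {
        "births_per_year": round(float(r["births_per_year"]) / 100.0) * 100,
        "unintended_births_per_year": round(float(r["unintended_births_per_year"]) / 100.0) * 100,
        "pct_births_unintended": round(float(r["pct_births_unintended"]), 1),
        "incidence_births_per_1000": round(float(r["incidence_births_per_1000"])),
        "pregnancies_per_year": round(float(r["pregnancies_per_year"]) / 100.0) * 100,
        "unintended_pregnancies_per_year": round(float(r["unintended_pregnancies_per_year"]) / 100.0) * 100,
        "pct_pregnancies_unintended": round(float(r["pct_pregnancies_unintended"]), 1),
        "incidence_pregnancies_per_1000": round(float(r["incidence_pregnancies_per_1000"])),
        "women_count": int(r["women_count"]),
    }
    if log is not None:
        report["n_excluded_coordinates"] = log.n_excluded_coordinates
        report["n_unassigned_area"] = log.n_unassigned_area
        report["n_undefined_incidence_cells"] = log.n_undefined_incidence_cells
    return report
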