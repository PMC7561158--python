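"""Synthetic vital-records simulator.

Generates the four input tables of the small-area estimation pipeline — a
birth-record file, a maternal survey of recent births with an intendedness
response (PRAMS-like), a pregnancy-history survey with live-birth outcomes
(NSFG-like), and an area population table (ACS-like) — plus the area
polygons, all from a :class:`~pregsae.truth.GroundTruth` whose seed fully
determines the output.

The generator exists so that every downstream stage can be tested against
known truth: the latent per-birth intendedness and its generating
probability are kept on the birth table in ``true_``-prefixed columns that
no estimation stage reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from shapely.geometry import Polygon

from . import schema
from .errors import InvalidArgumentError
from .geo import Polygons, write_polygons
from .truth import GroundTruth

# Seed-stream offsets: each stage draws from an independent child stream of
# the truth seed so that regenerating one table never perturbs another.
_STREAM_POLYGONS = 0
_STREAM_BIRTHS = 1
_STREAM_SURVEY = 2
_STREAM_PREGNANCIES = 3
_STREAM_POPULATION = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# calibration helpers


def calibrate_intercept(linear_predictor: np.ndarray, target_share: float) -> float:
    """Intercept alpha such that mean(expit(alpha + lp)) == target_share.

    The simulator states its baselines as marginal shares; solving for the
    intercept on the realized covariates makes those shares hold exactly in
    expectation regardless of the coefficient values.
    """
    if target_share >= 1.0:
        return np.inf
    lp = np.asarray(linear_predictor, dtype=float)

    def deficit(alpha):
        return float(np.mean(expit(alpha + lp))) - target_share

    return float(brentq(deficit, -40.0, 40.0, xtol=1e-12))


def linear_predictor(frame: pd.DataFrame, coefficients: dict) -> np.ndarray:
    """Apply logit-scale coefficients on the documented covariate scales.

    Continuous features are standardized by ``schema.CONTINUOUS_SCALE``
    (coefficients are per nominal SD); binary features enter raw.
    """
    lp = np.zeros(len(frame), dtype=float)
    for feat, coef in coefficients.items():
        if coef == 0.0:
            continue
        x = frame[feat].to_numpy(dtype=float)
        if feat in schema.CONTINUOUS_SCALE:
            center, scale_ = schema.CONTINUOUS_SCALE[feat]
            x = (x - center) / scale_
        lp += coef * x
    return lp


# ---------------------------------------------------------------------------
# polygons


def generate_polygons(
    area_count: int,
    seed: int = 0,
    width: float = schema.FRAME_WIDTH_MI,
    height: float = schema.FRAME_HEIGHT_MI,
) -> Polygons:
    """Tile the study bounding box with ``area_count`` disjoint rectangles.

    Rows of the box are split into randomly-proportioned bands and each band
    into randomly-proportioned columns, so the rectangles tile the box
    exactly (shared boundaries, areas summing to width*height).  Area ids
    are zero-padded ("A01", ...) so lexicographic order is stable.
    """
    if area_count < 1:
        raise InvalidArgumentError("area_count must be >= 1")
    rng = _rng(seed, _STREAM_POLYGONS)
    n_rows = max(1, int(np.floor(np.sqrt(area_count))))
    cols_per_row = np.full(n_rows, area_count // n_rows)
    cols_per_row[: area_count % n_rows] += 1

    row_fracs = rng.dirichlet(np.full(n_rows, 8.0))
    y_edges = np.concatenate([[0.0], np.cumsum(row_fracs)]) * height
    y_edges[-1] = height

    pad = len(str(area_count))
    polygons: Polygons = {}
    k = 0
    for r in range(n_rows):
        ncol = int(cols_per_row[r])
        col_fracs = rng.dirichlet(np.full(ncol, 8.0))
        x_edges = np.concatenate([[0.0], np.cumsum(col_fracs)]) * width
        x_edges[-1] = width
        for c in range(ncol):
            k += 1
            aid = f"A{k:0{pad}d}"
            polygons[aid] = Polygon(
                [
                    (x_edges[c], y_edges[r]),
                    (x_edges[c + 1], y_edges[r]),
                    (x_edges[c + 1], y_edges[r + 1]),
                    (x_edges[c], y_edges[r + 1]),
                ]
            )
    return polygons


# ---------------------------------------------------------------------------
# birth records


def _area_profiles(truth: GroundTruth, area_ids, rng) -> dict:
    """Per-area covariate composition: marriage/insurance rates, age shift."""
    base_married = schema.COVARIATE_MARGINALS["married"]
    base_ins = schema.COVARIATE_MARGINALS["private_insurance"]
    profiles = {}
    for aid in area_ids:
        delta = rng.normal(0.0, truth.area_covariate_sd, size=2)
        shift = rng.normal(0.0, 1.5 * truth.area_covariate_sd)
        profiles[aid] = {
            "married_rate": float(expit(logit(base_married) + delta[0])),
            "private_insurance_rate": float(expit(logit(base_ins) + delta[1])),
            "age_shift": float(shift),
        }
    if truth.area_profiles:
        for aid, override in truth.area_profiles.items():
            profiles.setdefault(aid, {})
            profiles[aid].update(override)
    return profiles


def _draw_covariates(n: int, rng, age_mean_shift: float = 0.0,
                     married_rate: Optional[float] = None,
                     insurance_rate: Optional[float] = None) -> pd.DataFrame:
    m = schema.COVARIATE_MARGINALS
    ages = np.clip(
        rng.normal(m["mother_age"]["mean"] + age_mean_shift, m["mother_age"]["sd"], n),
        m["mother_age"]["lo"], m["mother_age"]["hi"],
    )
    edu = np.clip(rng.normal(m["education_years"]["mean"], m["education_years"]["sd"], n),
                  m["education_years"]["lo"], m["education_years"]["hi"])
    bmi = np.clip(rng.normal(m["prepregnancy_bmi"]["mean"], m["prepregnancy_bmi"]["sd"], n),
                  m["prepregnancy_bmi"]["lo"], m["prepregnancy_bmi"]["hi"])
    bw = np.clip(rng.normal(m["birth_weight_grams"]["mean"], m["birth_weight_grams"]["sd"], n),
                 m["birth_weight_grams"]["lo"], m["birth_weight_grams"]["hi"])
    parity = rng.poisson(m["parity"]["poisson_mean"], n).astype(float)
    visits = rng.poisson(m["prenatal_visits"]["poisson_mean"], n).astype(float)
    pcm = np.minimum(
        m["prenatal_care_month"]["offset"] + rng.poisson(m["prenatal_care_month"]["poisson_mean"], n),
        m["prenatal_care_month"]["hi"],
    ).astype(float)
    u = rng.random(n)
    plurality = np.where(u < m["plurality"]["p_triplet"], 3.0,
                         np.where(u < m["plurality"]["p_triplet"] + m["plurality"]["p_twin"], 2.0, 1.0))
    race = rng.choice(
        ["white", "black", "hispanic", "other"],
        size=n,
        p=[m["race"][k] for k in ("white", "black", "hispanic", "other")],
    )
    frame = pd.DataFrame(
        {
            "mother_age": ages,
            "education_years": edu,
            "parity": parity,
            "plurality": plurality,
            "prenatal_care_month": pcm,
            "prenatal_visits": visits,
            "prepregnancy_bmi": bmi,
            "birth_weight_grams": bw,
            "married": (rng.random(n) < (m["married"] if married_rate is None else married_rate)).astype(float),
            "private_insurance": (rng.random(n) < (m["private_insurance"] if insurance_rate is None else insurance_rate)).astype(float),
            "race_black": (race == "black").astype(float),
            "race_hispanic": (race == "hispanic").astype(float),
            "race_other": (race == "other").astype(float),
        }
    )
    for feat in ("infertility_treatment", "smoked_before_pregnancy", "pregnancy_risk_any",
                 "previous_adverse_outcome", "gestation_lt39", "breastfeeding",
                 "infant_male", "father_college", "foreign_born"):
        frame[feat] = (rng.random(n) < m[feat]).astype(float)
    return frame


def _uniform_points_in_polygon(poly: Polygon, n: int, rng) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(16, int(1.5 * (n - filled)))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        import shapely

        keep = shapely.contains_xy(poly, xs, ys)
        take = min(int(keep.sum()), n - filled)
        out[filled : filled + take, 0] = xs[keep][:take]
        out[filled : filled + take, 1] = ys[keep][:take]
        filled += take
    return out


def generate_birth_table(
    truth: GroundTruth,
    polygons: Polygons,
    n_total: Optional[int] = None,
    seed: Optional[int] = None,
    years: tuple[int, ...] = (2014, 2015, 2016),
) -> pd.DataFrame:
    """Simulate the birth-record file.

    Each record carries the intendedness-model covariates, the live-birth
    model covariates, planar coordinates uniform within its area, a year,
    and the latent truth columns ``true_unintended`` / ``true_p_unintended``.
    Item missingness is injected last, per ``truth.missingness_rates``.
    """
    truth.validate()
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, _STREAM_BIRTHS)
    area_ids = sorted(polygons)
    if n_total is None:
        n_total = truth.births_per_area * len(area_ids)

    # urban/rural skew in where births occur
    size_w = rng.lognormal(0.0, truth.area_size_sd, len(area_ids))
    counts = rng.multinomial(n_total, size_w / size_w.sum())

    profiles = _area_profiles(truth, area_ids, rng)
    parts = []
    for aid, n_a in zip(area_ids, counts):
        if n_a == 0:
            continue
        prof = profiles[aid]
        frame = _draw_covariates(
            int(n_a), rng,
            age_mean_shift=prof["age_shift"],
            married_rate=prof["married_rate"],
            insurance_rate=prof["private_insurance_rate"],
        )
        pts = _uniform_points_in_polygon(polygons[aid], int(n_a), rng)
        frame["longitude"] = pts[:, 0]
        frame["latitude"] = pts[:, 1]
        parts.append(frame)
    births = pd.concat(parts, ignore_index=True)
    births["year"] = rng.choice(list(years), size=len(births))

    lp = linear_predictor(births, truth.intendedness_coefficients)
    alpha = calibrate_intercept(lp, truth.baseline_unintended_share)
    p = expit(alpha + lp) if np.isfinite(alpha) else np.ones(len(births))
    births["true_p_unintended"] = p
    births["true_unintended"] = (rng.random(len(births)) < p).astype(int)

    # item missingness (after the latent draw: truth depends on the real values)
    for feat, rate in truth.missingness_rates.items():
        if rate <= 0:
            continue
        mask = rng.random(len(births)) < rate
        if feat == "coordinates":
            births.loc[mask, ["longitude", "latitude"]] = np.nan
        elif feat in births.columns:
            births.loc[mask, feat] = np.nan

    births.insert(0, "birth_id", [f"B{i:07d}" for i in range(len(births))])
    cols = schema.BIRTH_COLUMNS + ["true_p_unintended", "true_unintended"]
    return births[cols]


# ---------------------------------------------------------------------------
# maternal survey


def generate_survey_table(
    birth_table: pd.DataFrame,
    sampling_rate: float,
    weight_dispersion: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Subsample births into a maternal survey with the five-category response.

    The response is drawn from fixed conditional splits given the latent
    binary intendedness (unintended -> "later"/"never"; otherwise
    "sooner"/"then"/"unsure"), so the default binary coding reproduces the
    latent truth exactly.  Survey weights have mean 1/sampling_rate with a
    gamma-shaped dispersion around it; dispersion 0 gives equal weights.
    """
    if len(birth_table) == 0:
        raise InvalidArgumentError("birth_table is empty")
    if not (0.0 < sampling_rate <= 1.0):
        raise InvalidArgumentError("sampling_rate must be in (0, 1]")
    if weight_dispersion < 0:
        raise InvalidArgumentError("weight_dispersion must be >= 0")
    rng = _rng(seed, _STREAM_SURVEY)

    take = rng.random(len(birth_table)) < sampling_rate if sampling_rate < 1.0 else np.ones(len(birth_table), bool)
    survey = birth_table.loc[take].copy().reset_index(drop=True)
    n = len(survey)

    responses = np.empty(n, dtype=object)
    u = rng.random(n)
    latent = survey["true_unintended"].to_numpy()
    for value, splits in schema.RESPONSE_SPLITS.items():
        idx = np.flatnonzero(latent == value)
        edges = np.cumsum(list(splits.values()))
        cats = [schema.SHORT_RESPONSES[k] for k in splits]
        responses[idx] = np.array(cats, dtype=object)[np.searchsorted(edges, u[idx] * edges[-1])]
    survey["intendedness_response"] = responses

    base = 1.0 / sampling_rate
    if weight_dispersion == 0:
        weights = np.full(n, base)
    else:
        shape_ = 1.0 / weight_dispersion**2
        weights = base * rng.gamma(shape_, 1.0 / shape_, n)
    survey["survey_weight"] = weights

    cols = schema.SURVEY_COLUMNS + ["true_unintended"]
    return survey[cols]


# ---------------------------------------------------------------------------
# pregnancy histories


def generate_pregnancy_table(
    truth: GroundTruth,
    n_women: int,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate per-pregnancy histories with intendedness and live-birth outcome.

    Women carry the live-birth-model covariates; each has one or more
    pregnancies whose intendedness follows f* restricted to those covariates
    (calibrated to ``pregnancy_unintended_share``) and whose live-birth
    indicator follows g* (calibrated to ``baseline_livebirth_share``).
    """
    if n_women < 1:
        raise InvalidArgumentError("n_women must be >= 1")
    truth.validate()
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, _STREAM_PREGNANCIES)

    n_preg_per_woman = 1 + rng.poisson(1.2, n_women)
    woman_id = np.repeat(np.arange(n_women), n_preg_per_woman)
    n = int(n_preg_per_woman.sum())

    m = schema.COVARIATE_MARGINALS
    base_age = np.clip(rng.normal(29.0, 7.0, n_women), 16.0, 45.0)
    race = rng.choice(["white", "black", "hispanic", "other"], size=n_women,
                      p=[m["race"][k] for k in ("white", "black", "hispanic", "other")])
    married_w = (rng.random(n_women) < m["married"]).astype(float)
    foreign_w = (rng.random(n_women) < m["foreign_born"]).astype(float)

    order = np.concatenate([np.arange(k) for k in n_preg_per_woman]).astype(float)
    frame = pd.DataFrame(
        {
            "woman_id": [f"W{i:06d}" for i in woman_id],
            "mother_age": np.clip(base_age[woman_id] - rng.uniform(0.0, 8.0, n), 15.0, 45.0),
            "parity": order,
            "married": married_w[woman_id],
            "foreign_born": foreign_w[woman_id],
            "race_black": (race[woman_id] == "black").astype(float),
            "race_hispanic": (race[woman_id] == "hispanic").astype(float),
            "race_other": (race[woman_id] == "other").astype(float),
        }
    )
    frame["pregnancy_id"] = [f"P{i:07d}" for i in range(n)]

    coefs_y = {k: v for k, v in truth.intendedness_coefficients.items() if k in frame.columns}
    lp_y = linear_predictor(frame, coefs_y)
    alpha_y = calibrate_intercept(lp_y, truth.pregnancy_unintended_share)
    p_y = expit(alpha_y + lp_y) if np.isfinite(alpha_y) else np.ones(n)
    frame["unintended"] = (rng.random(n) < p_y).astype(int)

    coefs_l = dict(truth.livebirth_coefficients)
    lp_l = linear_predictor(frame, {k: v for k, v in coefs_l.items() if k != "unintended"})
    lp_l = lp_l + coefs_l.get("unintended", 0.0) * frame["unintended"].to_numpy()
    alpha_l = calibrate_intercept(lp_l, truth.baseline_livebirth_share)
    p_l = expit(alpha_l + lp_l) if np.isfinite(alpha_l) else np.ones(n)
    frame["live_birth"] = (rng.random(n) < p_l).astype(int)

    shape_ = 1.0 / 0.3**2
    frame["survey_weight"] = rng.gamma(shape_, 1.0 / shape_, n)
    return frame[schema.PREGNANCY_COLUMNS]


# ---------------------------------------------------------------------------
# population table


def generate_population_table(
    polygons: Polygons,
    women_per_area,
    age_bins=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Women aged 15-45 per area and age bin (integer counts).

    ``women_per_area`` is either an exact integer per area or an (lo, hi)
    range sampled per area.  Bin allocation follows bin width with a mild
    Dirichlet jitter, rounded by largest remainder so bins sum exactly to
    the per-area total.
    """
    age_bins = schema.DEFAULT_AGE_BINS if age_bins is None else age_bins
    schema.validate_age_bins(age_bins)
    rng = _rng(seed, _STREAM_POPULATION)
    widths = np.array([b - a + 1 for a, b in age_bins], dtype=float)
    rows = []
    for aid in sorted(polygons):
        if isinstance(women_per_area, (tuple, list)):
            total = int(rng.integers(int(women_per_area[0]), int(women_per_area[1]) + 1))
        else:
            total = int(women_per_area)
        props = rng.dirichlet(widths * 20.0)
        raw = props * total
        counts = np.floor(raw).astype(int)
        rem = total - counts.sum()
        counts[np.argsort(-(raw - counts))[:rem]] += 1
        for (a, b), c in zip(age_bins, counts):
            rows.append({"area_id": aid, "age_group": schema.age_bin_label((a, b)), "women": int(c)})
    return pd.DataFrame(rows, columns=schema.POPULATION_COLUMNS)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SyntheticBundle:
    """All generated inputs plus the truth that produced them."""

    survey_table: pd.DataFrame
    pregnancy_table: pd.DataFrame
    birth_table: pd.DataFrame
    population_table: pd.DataFrame
    polygons: Polygons
    truth: GroundTruth


def generate_bundle(
    truth: GroundTruth,
    sampling_rate: float = 0.05,
    weight_dispersion: float = 0.3,
    n_women: int = 8_000,
    age_bins=None,
) -> SyntheticBundle:
    """Generate the full input set from one ground truth."""
    polygons = generate_polygons(truth.area_count, seed=truth.seed)
    births = generate_birth_table(truth, polygons)
    survey = generate_survey_table(births, sampling_rate, weight_dispersion, seed=truth.seed)
    pregnancies = generate_pregnancy_table(truth, n_women)
    population = generate_population_table(polygons, truth.women_per_area, age_bins, seed=truth.seed)
    return SyntheticBundle(survey, pregnancies, births, population, polygons, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write the bundle as CSVs + GeoJSON + a ground-truth YAML sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": outdir / "survey.csv",
        "pregnancies": outdir / "pregnancies.csv",
        "births": outdir / "births.csv",
        "population": outdir / "population.csv",
        "polygons": outdir / "areas.geojson",
        "truth": outdir / "ground_truth.yaml",
    }
    bundle.survey_table.to_csv(paths["survey"], index=False)
    bundle.pregnancy_table.to_csv(paths["pregnancies"], index=False)
    bundle.birth_table.to_csv(paths["births"], index=False)
    bundle.population_table.to_csv(paths["population"], index=False)
    write_polygons(bundle.polygons, paths["polygons"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(bundle.truth.to_dict(), fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
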