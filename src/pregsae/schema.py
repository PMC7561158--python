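"""Column dictionaries and documented covariate marginals.

All feature lists, response wordings, age bins and the synthetic generator's
marginal distributions live here so that recovery tests and the schema
validator reference a single set of constants.

Coordinates throughout the package are planar, in miles, on a study frame
whose bounding box matches a Missouri-sized state (69,707 square miles).
The ``longitude`` column is the x coordinate and ``latitude`` the y
coordinate of that frame.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Study frame: 300 mi x 232.3566... mi = 69,707 sq mi.
STUDY_AREA_SQMI = 69_707.0
FRAME_WIDTH_MI = 300.0
FRAME_HEIGHT_MI = STUDY_AREA_SQMI / FRAME_WIDTH_MI

# ---------------------------------------------------------------------------
# Intendedness question: the five response categories and their short codes.
RESPONSE_LATER = "I wanted to be pregnant later"
RESPONSE_SOONER = "I wanted to be pregnant sooner"
RESPONSE_THEN = "I wanted to be pregnant then"
RESPONSE_NEVER = "I didn't want to be pregnant then or at any time in the future"
RESPONSE_UNSURE = "I wasn't sure what I wanted"

RESPONSES = (RESPONSE_LATER, RESPONSE_SOONER, RESPONSE_THEN, RESPONSE_NEVER, RESPONSE_UNSURE)

SHORT_RESPONSES = {
    "later": RESPONSE_LATER,
    "sooner": RESPONSE_SOONER,
    "then": RESPONSE_THEN,
    "never": RESPONSE_NEVER,
    "unsure": RESPONSE_UNSURE,
}

CODING_SCHEMES = ("unsure_as_not_unintended", "unsure_as_unintended", "drop_unsure")
DEFAULT_CODING_SCHEME = "unsure_as_not_unintended"

# ---------------------------------------------------------------------------
# Features of the intendedness model f (available on both the maternal survey
# and the birth-record file).
CONTINUOUS_F = [
    "mother_age",
    "education_years",
    "parity",
    "plurality",
    "prenatal_care_month",
    "prenatal_visits",
    "prepregnancy_bmi",
    "birth_weight_grams",
]
BINARY_F = [
    "married",
    "private_insurance",
    "infertility_treatment",
    "smoked_before_pregnancy",
    "pregnancy_risk_any",
    "previous_adverse_outcome",
    "gestation_lt39",
    "breastfeeding",
    "infant_male",
    "father_college",
    "race_black",
    "race_hispanic",
    "race_other",
]
FEATURES_F = CONTINUOUS_F + BINARY_F

# Features of the live-birth model g (shared between the pregnancy-history
# survey and the birth-record file), plus intendedness itself.
CONTINUOUS_G = ["mother_age", "parity"]
BINARY_G = ["married", "foreign_born", "race_black", "race_hispanic", "race_other"]
FEATURES_G = CONTINUOUS_G + BINARY_G + ["unintended"]

# ---------------------------------------------------------------------------
# Table column dictionaries (the external CSV contracts).
BIRTH_COLUMNS = ["birth_id", "year", "longitude", "latitude", "foreign_born"] + FEATURES_F
SURVEY_COLUMNS = ["birth_id", "intendedness_response", "survey_weight"] + FEATURES_F
PREGNANCY_COLUMNS = (
    ["woman_id", "pregnancy_id", "unintended", "live_birth", "survey_weight"]
    + CONTINUOUS_G
    + BINARY_G
)
POPULATION_COLUMNS = ["area_id", "age_group", "women"]

# ---------------------------------------------------------------------------
# Age bins: closed integer bins partitioning ages 15..45.
DEFAULT_AGE_BINS = [(15, 17), (18, 20), (21, 24), (25, 29), (30, 34), (35, 45)]


def age_bin_label(bin_: tuple[int, int]) -> str:
    return f"{bin_[0]}-{bin_[1]}"


def validate_age_bins(age_bins) -> None:
    """Age bins must be a contiguous integer partition of [15, 45]."""
    from .errors import InvalidArgumentError

    if not age_bins:
        raise InvalidArgumentError("age_bins must be non-empty")
    lo, hi = age_bins[0][0], age_bins[-1][1]
    if lo != 15 or hi != 45:
        raise InvalidArgumentError(f"age_bins must span [15, 45], got [{lo}, {hi}]")
    for (a, b), (c, _d) in zip(age_bins, age_bins[1:]):
        if b < a or c != b + 1:
            raise InvalidArgumentError(f"age_bins not a partition at ({a},{b}) -> ({c},...)")


# ---------------------------------------------------------------------------
# Documented covariate marginals for the synthetic generator.  The 41%
# married rate mirrors the observation that 59% of mothers on the birth file
# are unmarried; other values are field-plausible national magnitudes.
COVARIATE_MARGINALS = {
    "mother_age": {"mean": 27.5, "sd": 5.8, "lo": 15.0, "hi": 45.0},
    "education_years": {"mean": 13.5, "sd": 2.2, "lo": 8.0, "hi": 20.0},
    "prepregnancy_bmi": {"mean": 26.5, "sd": 6.0, "lo": 15.0, "hi": 55.0},
    "birth_weight_grams": {"mean": 3300.0, "sd": 550.0, "lo": 300.0, "hi": 6000.0},
    "parity": {"poisson_mean": 1.1},
    "prenatal_visits": {"poisson_mean": 11.0},
    "prenatal_care_month": {"poisson_mean": 1.6, "offset": 1, "hi": 10},
    "plurality": {"p_twin": 0.032, "p_triplet": 0.002},
    "married": 0.41,
    "private_insurance": 0.48,
    "infertility_treatment": 0.02,
    "smoked_before_pregnancy": 0.17,
    "pregnancy_risk_any": 0.12,
    "previous_adverse_outcome": 0.08,
    "gestation_lt39": 0.42,
    "breastfeeding": 0.80,
    "infant_male": 0.512,
    "father_college": 0.30,
    "foreign_born": 0.06,
    "race": {"white": 0.72, "black": 0.18, "hispanic": 0.06, "other": 0.04},
}

# Centers/scales used when applying ground-truth coefficients to continuous
# covariates (coefficients are per standard deviation of these nominal
# scales; binary coefficients are on the raw 0/1 value).
CONTINUOUS_SCALE = {
    "mother_age": (27.5, 5.8),
    "education_years": (13.5, 2.2),
    "parity": (1.1, 1.05),
    "plurality": (1.03, 0.2),
    "prenatal_care_month": (2.6, 1.3),
    "prenatal_visits": (11.0, 3.3),
    "prepregnancy_bmi": (26.5, 6.0),
    "birth_weight_grams": (3300.0, 550.0),
}

# Conditional splits of the five-category response given the latent binary
# intendedness.  The binary coding of the generated response under the
# default scheme reproduces the latent truth exactly.
RESPONSE_SPLITS = {
    1: {"later": 0.70, "never": 0.30},
    0: {"sooner": 0.25, "then": 0.60, "unsure": 0.15},
}
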