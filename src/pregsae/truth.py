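"""Ground-truth specification for the synthetic vital-records simulator.

A :class:`GroundTruth` holds the true intendedness model f* and live-birth
model g* (both logistic on the documented covariate scales), the marginal
shares the simulator calibrates to, and the geography/missingness knobs.
Given its seed it fully determines every generated table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

from .errors import InvalidArgumentError

# Default f*: the dominant predictors are marital status, insurance, age,
# parity and the month prenatal care began, matching the relative strengths
# the intendedness literature reports.  Continuous coefficients are per
# standard deviation of schema.CONTINUOUS_SCALE; binary per 0/1.
DEFAULT_INTENDEDNESS_COEFFICIENTS = {
    "married": -0.90,
    "private_insurance": -0.70,
    "mother_age": -0.35,
    "parity": 0.30,
    "prenatal_care_month": 0.20,
    "race_black": 0.25,
    "education_years": -0.15,
    "smoked_before_pregnancy": 0.25,
}

# Default g*: unintended pregnancies are less likely to end in a live birth.
DEFAULT_LIVEBIRTH_COEFFICIENTS = {
    "unintended": -0.80,
    "married": 0.45,
    "mother_age": -0.15,
    "parity": 0.10,
    "foreign_born": 0.20,
}

DEFAULT_MISSINGNESS_RATES = {
    "prenatal_care_month": 0.03,
    "prenatal_visits": 0.03,
    "prepregnancy_bmi": 0.05,
    "education_years": 0.04,
    "private_insurance": 0.02,
    "father_college": 0.15,
    # fraction of birth records with ungeocodable addresses (both
    # coordinates missing), mirroring the real file's tiny exclusion rate
    "coordinates": 0.0006,
}


@dataclass
class GroundTruth:
    """True generating models and simulator configuration.

    Parameters
    ----------
    intendedness_coefficients
        Logit-scale coefficients of f*, keyed by feature name.
    livebirth_coefficients
        Logit-scale coefficients of g*, keyed by feature name; must include
        an ``unintended`` term (possibly zero).
    baseline_unintended_share
        Calibrated marginal share of births from unintended pregnancies.
    baseline_livebirth_share
        Calibrated marginal share of pregnancies ending in a live birth.
    pregnancy_unintended_share
        Marginal unintended share among generated pregnancies.
    area_count, women_per_area, births_per_area
        Geography: number of areas, women aged 15-45 per area (int for an
        exact count or an (lo, hi) range), and the mean births per area
        over the whole window.
    missingness_rates
        Per-feature missingness fractions; the special key ``coordinates``
        drops both geographic coordinates jointly.
    area_covariate_sd
        Logit-scale spread of per-area covariate composition (marriage and
        insurance rates, age shift); 0 makes areas homogeneous.
    area_profiles
        Optional explicit per-area composition overrides:
        area_id -> {"married_rate", "private_insurance_rate", "age_shift"}.
    area_size_sd
        Log-scale spread of relative area birth counts (urban/rural skew).
    """

    intendedness_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENDEDNESS_COEFFICIENTS)
    )
    livebirth_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_LIVEBIRTH_COEFFICIENTS)
    )
    baseline_unintended_share: float = 0.34
    baseline_livebirth_share: float = 0.71
    pregnancy_unintended_share: float = 0.40
    area_count: int = 10
    women_per_area: object = (15_000, 36_000)
    births_per_area: int = 1_000
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS_RATES))
    seed: int = 0
    area_covariate_sd: float = 0.5
    area_profiles: Optional[dict] = None
    area_size_sd: float = 0.6

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, share in [
            ("baseline_unintended_share", self.baseline_unintended_share),
            ("baseline_livebirth_share", self.baseline_livebirth_share),
            ("pregnancy_unintended_share", self.pregnancy_unintended_share),
        ]:
            if not (0.0 < share <= 1.0):
                raise InvalidArgumentError(f"{name} must be in (0, 1], got {share}")
        if self.area_count < 1:
            raise InvalidArgumentError("area_count must be >= 1")
        if self.births_per_area < 1:
            raise InvalidArgumentError("births_per_area must be >= 1")
        for feat, rate in self.missingness_rates.items():
            if not (0.0 <= rate < 1.0):
                raise InvalidArgumentError(f"missingness rate for {feat} must be in [0,1)")
        if self.area_covariate_sd < 0 or self.area_size_sd < 0:
            raise InvalidArgumentError("area spread parameters must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["women_per_area"], tuple):
            d["women_per_area"] = list(d["women_per_area"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        if isinstance(d.get("women_per_area"), list):
            d["women_per_area"] = tuple(d["women_per_area"])
        return cls(**d)
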