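"""Pipeline configuration: a fully serializable run description.

A config captures everything a run depends on — input paths or simulation
parameters, the seed, fold count, outcome coding scheme, candidate grid,
the inverse-probability floor, the span of the birth window, age bins and
density options — so that a run can be reproduced from the config alone.
Its canonical YAML hash is embedded in every output artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import schema
from .errors import InvalidArgumentError

DEFAULT_SIMULATE = {
    "area_count": 10,
    "births_per_area": 1000,
    "women_per_area": [15000, 36000],
    "n_women": 8000,
    "sampling_rate": 0.05,
    "weight_dispersion": 0.3,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "runs"
    # either simulate inputs from this block, or read them from `inputs`
    simulate: Optional[dict] = field(default_factory=lambda: dict(DEFAULT_SIMULATE))
    inputs: Optional[dict] = None  # survey/births/pregnancies/population/polygons paths
    k_folds: int = 5
    coding_scheme: str = schema.DEFAULT_CODING_SCHEME
    candidate_grid: Optional[list] = None  # None -> models.DEFAULT_CANDIDATE_GRID
    g_floor: float = 0.05
    years_span: float = 3.0
    age_bins: list = field(default_factory=lambda: [list(b) for b in schema.DEFAULT_AGE_BINS])
    density: dict = field(default_factory=lambda: {"cell_size": None, "total_area": None})

    def __post_init__(self):
        if self.coding_scheme not in schema.CODING_SCHEMES:
            raise InvalidArgumentError(f"unknown coding_scheme {self.coding_scheme!r}")
        if self.simulate is None and self.inputs is None:
            raise InvalidArgumentError("config needs either a simulate block or input paths")
        schema.validate_age_bins(self.age_bins_tuples())
        if self.g_floor <= 0:
            raise InvalidArgumentError("g_floor must be > 0")
        if self.years_span <= 0:
            raise InvalidArgumentError("years_span must be > 0")
        if self.k_folds < 2:
            raise InvalidArgumentError("k_folds must be >= 2")

    def age_bins_tuples(self):
        return [tuple(b) for b in self.age_bins]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical_json(self) -> str:
        """Canonical run description: everything that determines the results.

        The output location is excluded — two runs of the same scientific
        configuration are the same run wherever they are written.
        """
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return json.dumps(d, sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def run_dir(self) -> Path:
        """Deterministic run directory named by the config hash, so reruns
        of an identical config land (byte-identically) in the same place."""
        return Path(self.outdir) / f"run-{self.hash()}"
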