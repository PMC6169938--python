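"""Coefficient-agnostic absolute-risk projection engine.

Projects 5-year and lifetime (to age 90) absolute risks of disease from a
subject's questionnaire relative risk and user-supplied piecewise-constant
hazard tables: a baseline composite incidence hazard ``h1`` and a competing
mortality hazard ``h2`` per age band.  Official BCRAT/CARE tables are not
redistributed; any table covering ages [35, 90) can be supplied via a YAML
config.

The projection over bands ``j`` intersected with ``[age, age + horizon)``
accumulates

    sum_j  h1_j r / (h1_j r + h2_j)
           * (1 - exp(-(h1_j r + h2_j) dt_j))
           * exp(-sum_{k<j} (h1_k r + h2_k) dt_k)

where ``r`` is the subject's relative risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

from .io import NULLIPAROUS, SubjectRecord

MIN_AGE = 35
MAX_AGE = 90

#: category label used internally for unknown/missing questionnaire answers
UNKNOWN = "unknown"


@dataclass(frozen=True)
class HazardTable:
    """Piecewise-constant hazards over contiguous half-open age bands."""

    age_bands: tuple[tuple[int, int], ...]
    incidence: tuple[float, ...]
    competing_mortality: tuple[float, ...]

    def __post_init__(self) -> None:
        bands = self.age_bands
        if not bands:
            raise ValueError("hazard table has no age bands")
        if len(self.incidence) != len(bands) or len(self.competing_mortality) != len(bands):
            raise ValueError("hazard arrays must match the number of age bands")
        if bands[0][0] != MIN_AGE or bands[-1][1] != MAX_AGE:
            raise ValueError(f"age bands must cover [{MIN_AGE},{MAX_AGE}), got {bands[0][0]}..{bands[-1][1]}")
        for (a, b), (c, _d) in zip(bands, bands[1:]):
            if b != c:
                raise ValueError(f"age bands not contiguous at {b} vs {c}")
        for a, b in bands:
            if b <= a:
                raise ValueError(f"empty age band [{a},{b})")
        if any(h < 0 for h in self.incidence) or any(h < 0 for h in self.competing_mortality):
            raise ValueError("hazards must be non-negative")


CoefValue = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class RelativeRiskModel:
    """Log-relative-risk per questionnaire category.

    ``coefficients`` maps variable name -> {category -> log RR}.  A
    category value may itself be a mapping ``{"lt50": x, "ge50": y}`` for
    an under-50 / 50-plus split.  Unknown categories always contribute 0.
    """

    coefficients: Mapping[str, Mapping[str, CoefValue]]

    VARIABLES = (
        "n_first_degree_relatives",
        "age_menarche",
        "age_first_birth",
        "n_biopsies",
        "hyperplasia",
    )

    def log_rr(self, variable: str, category: str, age: int) -> float:
        if category == UNKNOWN:
            return 0.0
        table = self.coefficients.get(variable)
        if table is None or category not in table:
            raise KeyError(f"relative-risk model has no coefficient for {variable}={category!r}")
        value = table[category]
        if isinstance(value, Mapping):
            return float(value["lt50"] if age < 50 else value["ge50"])
        return float(value)


def categorize(record: SubjectRecord) -> dict[str, str]:
    """Map a questionnaire record onto the model's category labels."""
    cats: dict[str, str] = {}
    cats["n_first_degree_relatives"] = (
        UNKNOWN if record.n_first_degree_relatives is None else record.n_first_degree_relatives
    )
    if record.age_menarche is None:
        cats["age_menarche"] = UNKNOWN
    elif record.age_menarche >= 14:
        cats["age_menarche"] = ">=14"
    elif record.age_menarche >= 12:
        cats["age_menarche"] = "12-13"
    else:
        cats["age_menarche"] = "<12"
    afb = record.age_first_birth
    if afb is None:
        cats["age_first_birth"] = UNKNOWN
    elif afb == NULLIPAROUS:
        cats["age_first_birth"] = NULLIPAROUS
    elif afb < 20:
        cats["age_first_birth"] = "<20"
    elif afb < 25:
        cats["age_first_birth"] = "20-24"
    elif afb < 30:
        cats["age_first_birth"] = "25-29"
    else:
        cats["age_first_birth"] = ">=30"
    if record.n_biopsies is None:
        cats["n_biopsies"] = UNKNOWN
    elif record.n_biopsies == 0:
        cats["n_biopsies"] = "0"
    elif record.n_biopsies == 1:
        cats["n_biopsies"] = "1"
    else:
        cats["n_biopsies"] = ">=2"
    cats["hyperplasia"] = UNKNOWN if record.hyperplasia is None else record.hyperplasia
    return cats


def relative_risk(record: SubjectRecord, model: RelativeRiskModel) -> float:
    """exp(sum of category log-coefficients); unknowns contribute 0."""
    total = 0.0
    for variable, category in categorize(record).items():
        total += model.log_rr(variable, category, record.age)
    return math.exp(total)


def absolute_risk(age: int, horizon: int, rr: float, hazards: HazardTable) -> float:
    """Competing-risk absolute probability of disease over ``horizon`` years."""
    if age < MIN_AGE:
        raise ValueError(f"projection restricted to ages >= {MIN_AGE}, got {age}")
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    if age + horizon > MAX_AGE:
        raise ValueError(f"age {age} + horizon {horizon} exceeds {MAX_AGE}")
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    start, end = float(age), float(age + horizon)
    total = 0.0
    cum_hazard = 0.0
    for (a, b), h1, h2 in zip(hazards.age_bands, hazards.incidence, hazards.competing_mortality):
        lo, hi = max(start, a), min(end, b)
        if hi <= lo:
            continue
        dt = hi - lo
        rate = h1 * rr + h2
        if rate > 0:
            total += (h1 * rr / rate) * (1.0 - math.exp(-rate * dt)) * math.exp(-cum_hazard)
        cum_hazard += rate * dt
    return total


@dataclass(frozen=True)
class AbsoluteRiskPair:
    subject_id: str
    five_year: float
    lifetime: float


def score_cohort(
    subjects: Sequence[SubjectRecord],
    model: RelativeRiskModel,
    hazards: HazardTable,
) -> list[AbsoluteRiskPair]:
    """5-year (horizon min(5, 90-age)) and lifetime (to 90) risks per subject."""
    out = []
    for s in subjects:
        rr = relative_risk(s, model)
        lifetime_horizon = MAX_AGE - s.age
        five_year_horizon = min(5, lifetime_horizon)
        out.append(
            AbsoluteRiskPair(
                subject_id=s.subject_id,
                five_year=absolute_risk(s.age, five_year_horizon, rr, hazards),
                lifetime=absolute_risk(s.age, lifetime_horizon, rr, hazards),
            )
        )
    return out


# ---------------------------------------------------------------------------
# config


def load_risk_config(path: Union[str, Path]) -> tuple[RelativeRiskModel, HazardTable]:
    """Load hazard table + relative-risk coefficients from a YAML file.

    Expected layout::

        hazard_table:
          age_bands: [[35, 40], [40, 45], ...]
          incidence: [0.001, ...]
          competing_mortality: [0.002, ...]
        relative_risk_model:
          n_first_degree_relatives: {"0": 0.0, "1": 0.4, "2+": 0.9}
          ...
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ht = raw["hazard_table"]
    hazards = HazardTable(
        age_bands=tuple(tuple(band) for band in ht["age_bands"]),
        incidence=tuple(float(x) for x in ht["incidence"]),
        competing_mortality=tuple(float(x) for x in ht["competing_mortality"]),
    )
    model = RelativeRiskModel(coefficients=raw["relative_risk_model"])
    return model, hazards


def dump_risk_config(model: RelativeRiskModel, hazards: HazardTable, path: Union[str, Path]) -> None:
    payload = {
        "hazard_table": {
            "age_bands": [list(band) for band in hazards.age_bands],
            "incidence": list(hazards.incidence),
            "competing_mortality": list(hazards.competing_mortality),
        },
        "relative_risk_model": {
            var: {cat: (dict(v) if isinstance(v, Mapping) else float(v)) for cat, v in table.items()}
            for var, table in model.coefficients.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


__all__ = [
    "MIN_AGE",
    "MAX_AGE",
    "UNKNOWN",
    "HazardTable",
    "RelativeRiskModel",
    "AbsoluteRiskPair",
    "categorize",
    "relative_risk",
    "absolute_risk",
    "score_cohort",
    "load_risk_config",
    "dump_risk_config",
]
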