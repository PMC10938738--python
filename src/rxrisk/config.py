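"""Configuration objects for the synthetic registry generator and the pipeline.

The generator emulates the linkage of a national prescription database
(annual dispensing cross-sections, 2005-2016) with a hip-fracture registry
(events 2006-2017 plus a 1994-2005 look-back history), at the resolution the
real registries provide: month and year for deaths, emigrations and
fractures, calendar-year medication profiles.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "CategorySpec",
    "FractureModel",
    "SimulationConfig",
    "CohortDefinition",
]


@dataclass
class CategorySpec:
    """Generative parameters for one disease category.

    Parameters
    ----------
    category_id : str
        Category identifier; should exist in the mapping used downstream.
    atc_code : str
        Representative full 7-character ATC code dispensed for this category.
    base_fill_prob : float
        Marginal probability that an average person (frailty 0, age 70)
        fills this category in a calendar year.
    frailty_loading : float
        Log-odds increase in the fill probability per unit of the person's
        latent frailty.
    mortality_or : float
        True odds ratio for death in the following year associated with
        having filled this category, conditional on the other categories,
        sex and age.
    """

    category_id: str
    atc_code: str
    base_fill_prob: float
    frailty_loading: float
    mortality_or: float

    def validate(self) -> None:
        if not 0.0 <= self.base_fill_prob <= 1.0:
            raise ValueError(f"base_fill_prob out of [0,1] for {self.category_id}")
        if self.mortality_or <= 0:
            raise ValueError(f"mortality_or must be positive for {self.category_id}")
        if len(self.atc_code) != 7:
            raise ValueError(f"atc_code must be 7 characters: {self.atc_code!r}")


@dataclass
class FractureModel:
    """Piecewise-constant (per calendar year) hip fracture hazard.

    log rate = base_log_rate + log_rr_per_unit * lagged_score
               + log_rr_per_year_age * (age - age_ref)
               + female_log_rr * is_female

    ``base_log_rate`` is the log fracture rate per person-year for a man at
    ``age_ref`` with a lagged comorbidity score of 0.  ``-inf`` is allowed
    and yields a zero-rate population.
    """

    base_log_rate: float = math.log(30 / 10_000)
    log_rr_per_unit: float = math.log(1.07)
    log_rr_per_year_age: float = 0.08
    female_log_rr: float = math.log(1.8)
    age_ref: float = 70.0


def default_category_specs() -> list[CategorySpec]:
    """Ten-category default panel with prevalences and mortality ORs spanning
    the weight bands (true weights, via the OR-to-weight rule: 0, -1, 3, 2,
    3, 4, 2, 0, 6, 6)."""
    return [
        CategorySpec("hypertension", "C03AA03", 0.35, 0.4, 1.00),
        CategorySpec("hyperlipidaemia", "C10AA01", 0.30, 0.3, 0.70),
        CategorySpec("pain", "N02AA01", 0.25, 0.6, 1.50),
        CategorySpec("depression", "N06AB04", 0.15, 0.5, 1.30),
        CategorySpec("diabetes", "A10BA02", 0.12, 0.5, 1.50),
        CategorySpec("chronic_airways_disease", "R03AC02", 0.12, 0.5, 1.70),
        CategorySpec("anxiety", "N05BA04", 0.12, 0.6, 1.30),
        CategorySpec("osteoporosis", "M05BA04", 0.10, 0.4, 1.00),
        CategorySpec("congestive_heart_failure", "C03DA01", 0.08, 0.8, 2.50),
        CategorySpec("malignancy", "L01XA01", 0.04, 0.5, 2.50),
    ]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic registry.

    Defaults reproduce the structure of the study population: dispensing
    cross-sections 2005-2016, fractures 2006-2017, 86% of person-years with
    an index fill (``nonfiller_rate`` 0.14), baseline ages 50-95 so that all
    attained-age groups (51-65, 66-80, >80) are populated, mortality driven
    by the disease categories, and a fracture hazard log-linear in the
    previous year's true comorbidity score, age and sex.
    """

    n_persons: int = 10_000
    seed: int = 0
    start_year: int = 2005
    end_year: int = 2016
    fracture_end_year: int = 2017
    category_specs: list[CategorySpec] = field(default_factory=default_category_specs)
    frailty_sd: float = 1.0
    fill_age_slope: float = 0.02
    fill_persistence: float = 0.7
    nonfiller_rate: float = 0.14
    nonindex_fill_rate: float = 0.3
    fracture_model: FractureModel = field(default_factory=FractureModel)
    baseline_mortality: float = 0.02
    mortality_age_slope: float = 0.09
    mortality_female_log_or: float = -0.25
    emigration_rate: float = 0.004
    washout_history_rate: float = 0.03
    institutionalization_rate: float = 0.0
    age_range: tuple[int, int] = (50, 95)
    female_fraction: float = 0.55

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if not self.category_specs:
            raise ValueError("category_specs must not be empty")
        for spec in self.category_specs:
            spec.validate()
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be non-negative")
        if self.end_year - self.start_year < 1:
            raise ValueError(
                "year range must span at least 2 years (lagged exposure needs "
                "a preceding year)"
            )
        for name in (
            "nonfiller_rate",
            "nonindex_fill_rate",
            "baseline_mortality",
            "emigration_rate",
            "washout_history_rate",
            "institutionalization_rate",
            "female_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "category_specs" in d:
            d["category_specs"] = [
                CategorySpec(**c) if isinstance(c, dict) else c
                for c in d["category_specs"]
            ]
        if "fracture_model" in d and isinstance(d["fracture_model"], dict):
            d["fracture_model"] = FractureModel(**d["fracture_model"])
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CohortDefinition:
    """Open-cohort follow-up window and entry rules.

    Follow-up runs January 2006 through December 2017; persons enter on
    January 1 of the calendar year they turn ``min_age`` (51) or of
    ``start_year``, whichever is later.  Fractures during the washout window
    (1994-2005) disqualify a person entirely.
    """

    start_year: int = 2006
    end_year: int = 2017
    min_age: int = 51
    washout_start: int = 1994
    washout_end: int = 2005

    def validate(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("follow-up start after end")
        if self.washout_end >= self.start_year:
            # washout must close before follow-up begins
            raise ValueError("washout window must end before follow-up starts")
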