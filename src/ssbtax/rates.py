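"""Demographic rate schedules for the diabetes projection.

Stand-ins for the national data systems the projection normally consumes:
age-specific diagnosed-diabetes incidence (survey-derived), age/sex-specific
all-cause mortality (vital statistics), and projected annual births
(official population projections).  Shapes are parametric — logistic in age
for incidence, Gompertz for mortality, linear trend for births — with
defaults chosen so the no-tax projection of adult diagnosed-diabetes
prevalence lands in a realistic range for Mexico (~13-22% by 2050).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

INCIDENCE_SCENARIOS = ("optimistic", "intermediate", "pessimistic")


@dataclass(frozen=True)
class RateSchedule:
    """Age-indexed event rates (events per person-year per age bin).

    ``age_grid`` holds the left edges of one-year age bins; ``rate_at``
    does a step lookup and ``annual_prob`` converts a rate to a one-year
    probability via ``1 - exp(-rate)``.
    """

    kind: str                      # {incidence, mortality}
    sex: str                       # {male, female, both}
    age_grid: np.ndarray
    rate: np.ndarray
    calendar_year: int | None = None

    def __post_init__(self):
        age = np.asarray(self.age_grid, float)
        rate = np.asarray(self.rate, float)
        object.__setattr__(self, "age_grid", age)
        object.__setattr__(self, "rate", rate)
        if age.shape != rate.shape:
            raise ConfigurationError("age_grid and rate must have equal length")
        if np.any(np.diff(age) <= 0):
            raise ConfigurationError("age_grid must be strictly increasing")
        if np.any(rate < 0) or not np.isfinite(rate).all():
            raise ConfigurationError("rates must be finite and >= 0")

    def rate_at(self, age) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.age_grid, np.asarray(age), side="right") - 1,
                      0, len(self.rate) - 1)
        out = self.rate[idx]
        return np.where(np.asarray(age) < self.age_grid[0], 0.0, out)

    def annual_prob(self, age) -> np.ndarray:
        return 1.0 - np.exp(-self.rate_at(age))


@dataclass(frozen=True)
class BirthProjection:
    """Projected annual births by sex over contiguous calendar years."""

    years: np.ndarray
    births_by_sex: dict  # sex -> array aligned with years

    def __post_init__(self):
        years = np.asarray(self.years, int)
        object.__setattr__(self, "years", years)
        if np.any(np.diff(years) != 1):
            raise ConfigurationError("projection years must be contiguous")
        for sex, b in self.births_by_sex.items():
            b = np.asarray(b, float)
            if b.shape != years.shape or np.any(b < 0):
                raise ConfigurationError(f"births for {sex} must be >= 0 and aligned")

    def births(self, year: int, sex: str) -> float:
        if year < self.years[0] or year > self.years[-1]:
            raise ConfigurationError(f"year {year} outside birth projection")
        return float(np.asarray(self.births_by_sex[sex], float)[year - self.years[0]])


@dataclass(frozen=True)
class IncidenceParams:
    """Logistic-in-age incidence shape with scenario-level multipliers.

    rate(a) = multiplier * rate_max / (1 + exp(-slope * (a - midpoint)))
    for a >= 20, zero below (incidence restricted to adults).
    """

    rate_max: float = 0.035         # per person-year at the plateau
    midpoint: float = 52.0          # years
    slope: float = 0.105            # 1/years
    multipliers: dict = field(default_factory=lambda: {
        "optimistic": 0.60, "intermediate": 0.80, "pessimistic": 1.00})

    def __post_init__(self):
        if self.rate_max <= 0 or self.slope <= 0:
            raise ConfigurationError("rate_max and slope must be positive")
        m = self.multipliers
        if not (m["optimistic"] < m["intermediate"] < m["pessimistic"]):
            raise ConfigurationError(
                "scenario multipliers must satisfy optimistic < intermediate < pessimistic")


def generate_incidence_schedule(scenario: str,
                                params: IncidenceParams | None = None) -> RateSchedule:
    """Diagnosed-diabetes incidence for one of the three secular scenarios."""
    params = params or IncidenceParams()
    if scenario not in INCIDENCE_SCENARIOS:
        raise ConfigurationError(
            f"unknown incidence scenario {scenario!r}; valid: {INCIDENCE_SCENARIOS}")
    ages = np.arange(0, 101)
    rate = params.multipliers[scenario] * params.rate_max / (
        1.0 + np.exp(-params.slope * (ages - params.midpoint)))
    rate[ages < 20] = 0.0
    return RateSchedule("incidence", "both", ages, rate)


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz all-cause mortality: rate(a) = level * exp(slope * a)."""

    level: float
    slope: float

    def __post_init__(self):
        if self.level < 0 or self.slope < 0:
            raise ConfigurationError("Gompertz parameters must be >= 0")


DEFAULT_MORTALITY = {
    "male": GompertzParams(level=1.05e-4, slope=0.082),
    "female": GompertzParams(level=0.70e-4, slope=0.085),
}


def generate_mortality_schedule(params: GompertzParams, sex: str = "both") -> RateSchedule:
    """All-cause mortality hazard by single year of age, Gompertz in age."""
    ages = np.arange(0, 101)
    rate = params.level * np.exp(params.slope * ages)
    return RateSchedule("mortality", sex, ages, rate)


def default_mortality_schedules() -> dict:
    return {sex: generate_mortality_schedule(p, sex)
            for sex, p in DEFAULT_MORTALITY.items()}


@dataclass(frozen=True)
class BirthParams:
    """Linear birth trend with a fixed male fraction at birth."""

    start_year: int = 2010
    end_year: int = 2050
    births_start: float = 2.2e6
    births_end: float = 1.9e6
    male_fraction: float = 0.512

    def __post_init__(self):
        if self.births_start < 0 or self.births_end < 0:
            raise ConfigurationError("birth counts must be >= 0")
        if not 0 < self.male_fraction < 1:
            raise ConfigurationError("male_fraction must be in (0, 1)")


def generate_births(params: BirthParams | None = None) -> BirthProjection:
    params = params or BirthParams()
    years = np.arange(params.start_year, params.end_year + 1)
    total = np.linspace(params.births_start, params.births_end, len(years))
    return BirthProjection(years, {
        "male": total * params.male_fraction,
        "female": total * (1 - params.male_fraction),
    })


def write_rate_schedule(path, schedule: RateSchedule) -> None:
    df = pd.DataFrame({"kind": schedule.kind, "sex": schedule.sex,
                       "age": schedule.age_grid.astype(int), "rate": schedule.rate})
    if schedule.calendar_year is not None:
        df["year"] = schedule.calendar_year
    df.to_csv(path, index=False)


def write_births(path, births: BirthProjection) -> None:
    rows = [(int(y), sex, float(births.births(int(y), sex)))
            for y in births.years for sex in sorted(births.births_by_sex)]
    pd.DataFrame(rows, columns=["year", "sex", "births"]).to_csv(path, index=False)


def read_births(path) -> BirthProjection:
    df = pd.read_csv(path)
    years = np.sort(df["year"].unique())
    by_sex = {sex: sub.sort_values("year")["births"].to_numpy()
              for sex, sub in df.groupby("sex")}
    return BirthProjection(years, by_sex)


def read_rate_schedule(path) -> RateSchedule:
    df = pd.read_csv(path)
    year = int(df["year"].iloc[0]) if "year" in df.columns else None
    return RateSchedule(str(df["kind"].iloc[0]), str(df["sex"].iloc[0]),
                        df["age"].to_numpy(), df["rate"].to_numpy(), year)
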