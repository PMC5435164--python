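"""Synthetic survey-population generator.

Generates individual-level microdata with the statistical structure of the
adult (20+) Mexican population as described by the 2012 national health and
nutrition survey: sex, age group and socioeconomic-status (SES) marginals,
sex/age/SES-patterned body-mass index, and a strongly right-skewed
taxed-beverage consumption distribution (mean 323.49 ml/person/day,
SD 520.44, quartile cuts 33.94 / 129.64 / 402.86).

Consumption is drawn from a zero-inflated two-component log-normal mixture
(a light-consumer and a heavy-consumer component) with multiplicative
sex, age-group and SES shifts, each normalised to population mean 1 so the
shifts redistribute consumption without moving the overall mean.  The
default mixture parameters were calibrated numerically (analytic moments
and CDF) against the five marginal targets above.

All randomness flows from one :class:`numpy.random.Generator` seeded from
``PopulationConfig.seed``; there is no global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, ValidationError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
SES_LEVELS = ("low", "medium", "high")
AGE_GROUPS = ("20-39", "40-59", "60+")
AGE_BANDS = ((20, 39), (40, 59), (60, 90))

POPULATION_COLUMNS = [
    "id", "sex", "age", "height_m", "weight_kg", "ses", "ssb_ml", "svy_weight",
]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def _check_probs(name: str, probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or not np.isfinite(p).all():
        raise ConfigurationError(f"{name} must be non-negative and finite, got {probs}")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1 within 1e-9, got sum {p.sum()!r}")
    return p


@dataclass(frozen=True)
class PopulationConfig:
    """Targets and knobs for the synthetic population.

    Probability vectors must sum to 1 within 1e-9.  The BMI surface is an
    additive model (grand mean + sex, age-group and SES offsets, each
    averaging to ~0 under the corresponding marginal) so stratum means
    reproduce the survey pattern while the overall mean stays at
    ``bmi_mean``.  Heights are sex-specific truncated normals; the defaults
    are synthetic conventions chosen to give a realistic mean height-squared
    for this population, not survey-printed values.
    """

    n: int = 10_000
    seed: int = 12345
    sex_probs: tuple[float, float] = (0.4487, 0.5513)
    age_group_probs: tuple[float, float, float] = (0.4721, 0.3420, 0.1859)
    ses_probs: tuple[float, float, float] = (0.33652, 0.32911, 0.33437)
    bmi_mean: float = 28.40
    bmi_sd: float = 5.0
    bmi_offsets_by_sex: tuple[float, float] = (-0.85, 0.69)
    bmi_offsets_by_age_group: tuple[float, float, float] = (-0.57, 1.19, -0.74)
    bmi_offsets_by_ses: tuple[float, float, float] = (-0.65, 0.34, 0.32)
    bmi_bounds: tuple[float, float] = (17.0, 55.0)
    height_params_by_sex: tuple[tuple[float, float], tuple[float, float]] = (
        (1.64, 0.068), (1.52, 0.062))
    height_bounds: tuple[float, float] = (1.35, 2.05)
    ssb_zero_prob: float = 0.05
    # (weight, mu, sigma) per log-normal component, log-ml scale
    ssb_components: tuple[tuple[float, float, float], ...] = (
        (0.5763, 4.0077, 1.1985), (0.4237, 6.1626, 0.7880))
    # multiplicative consumption shifts; each dimension renormalised to mean 1
    sex_consumption_shift: tuple[float, float] = (1.15, 0.8779)
    age_consumption_shift: tuple[float, float, float] = (1.25, 0.90, 0.5491)
    ses_consumption_shift: tuple[float, float, float] = (0.948, 1.080, 0.974)

    def __post_init__(self):
        if self.n < 0:
            raise DomainError(f"population size must be >= 0, got {self.n}")
        _check_probs("sex_probs", self.sex_probs)
        _check_probs("age_group_probs", self.age_group_probs)
        _check_probs("ses_probs", self.ses_probs)
        w = sum(c[0] for c in self.ssb_components)
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError(f"ssb component weights must sum to 1, got {w}")
        if not 0 <= self.ssb_zero_prob < 1:
            raise ConfigurationError("ssb_zero_prob must be in [0, 1)")
        for sd in (self.bmi_sd, *(s for _, s in self.height_params_by_sex),
                   *(c[2] for c in self.ssb_components)):
            if sd <= 0:
                raise ConfigurationError(f"standard deviations must be > 0, got {sd}")
        for shift in (self.sex_consumption_shift, self.age_consumption_shift,
                      self.ses_consumption_shift):
            if min(shift) <= 0:
                raise ConfigurationError("consumption shifts must be positive")

    def with_(self, **kw) -> "PopulationConfig":
        return replace(self, **kw)


def _normalised_shift(shift, probs) -> np.ndarray:
    m = np.asarray(shift, dtype=float)
    p = np.asarray(probs, dtype=float)
    return m / float(p @ m)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw from N(mean, sd) truncated to [lo, hi] by redrawing tails."""
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x[bad] = rng.normal(np.broadcast_to(mean, x.shape)[bad] if np.ndim(mean) else mean,
                            np.broadcast_to(sd, x.shape)[bad] if np.ndim(sd) else sd,
                            int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate ``config.n`` synthetic adults as a DataFrame.

    Columns: ``id, sex, age, height_m, weight_kg, ses, ssb_ml, svy_weight``.
    Deterministic given ``config.seed``; marginals converge to the config
    targets as n grows.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            POPULATION_COLUMNS,
            [np.int64, object, np.int64, float, float, object, float, float])})

    sex_idx = rng.choice(2, n, p=_check_probs("sex_probs", config.sex_probs))
    age_idx = rng.choice(3, n, p=_check_probs("age_group_probs", config.age_group_probs))
    lo = np.array([b[0] for b in AGE_BANDS])[age_idx]
    hi = np.array([b[1] for b in AGE_BANDS])[age_idx]
    age = rng.integers(lo, hi + 1)
    ses_idx = rng.choice(3, n, p=_check_probs("ses_probs", config.ses_probs))

    h_mean = np.array([p[0] for p in config.height_params_by_sex])[sex_idx]
    h_sd = np.array([p[1] for p in config.height_params_by_sex])[sex_idx]
    height = _truncated_normal(rng, h_mean, h_sd, *config.height_bounds, n)

    bmi_mu = (config.bmi_mean
              + np.asarray(config.bmi_offsets_by_sex)[sex_idx]
              + np.asarray(config.bmi_offsets_by_age_group)[age_idx]
              + np.asarray(config.bmi_offsets_by_ses)[ses_idx])
    bmi = _truncated_normal(rng, bmi_mu, config.bmi_sd, *config.bmi_bounds, n)
    weight = np.clip(bmi * height**2, 30.0, 250.0)

    shift = (_normalised_shift(config.sex_consumption_shift, config.sex_probs)[sex_idx]
             * _normalised_shift(config.age_consumption_shift, config.age_group_probs)[age_idx]
             * _normalised_shift(config.ses_consumption_shift, config.ses_probs)[ses_idx])
    comp_w = np.array([c[0] for c in config.ssb_components])
    comp = rng.choice(len(comp_w), n, p=comp_w)
    mu = np.array([c[1] for c in config.ssb_components])[comp]
    sig = np.array([c[2] for c in config.ssb_components])[comp]
    ssb = shift * np.exp(mu + sig * rng.standard_normal(n))
    ssb[rng.random(n) < config.ssb_zero_prob] = 0.0

    return pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "sex": pd.array(np.array(SEXES)[sex_idx], dtype=object),
        "age": age.astype(np.int64),
        "height_m": height,
        "weight_kg": weight,
        "ses": pd.array(np.array(SES_LEVELS)[ses_idx], dtype=object),
        "ssb_ml": ssb,
        "svy_weight": np.ones(n),
    })


def age_group_of(age) -> np.ndarray:
    """Map ages to the survey's three adult bands (20-39 / 40-59 / 60+)."""
    a = np.asarray(age)
    return np.asarray(AGE_GROUPS, dtype=object)[
        np.digitize(a, [40, 60])]


# ---------------------------------------------------------------------------
# weighted statistics
# ---------------------------------------------------------------------------

def weighted_mean(x, w) -> float:
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    return float(np.sum(x * w) / np.sum(w))


def weighted_sd(x, w) -> float:
    m = weighted_mean(x, w)
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    return float(np.sqrt(np.sum(w * (x - m) ** 2) / np.sum(w)))


def weighted_quantile(x, w, q) -> np.ndarray:
    """Weight-scale-invariant quantiles of ``x`` with positive weights ``w``.

    Each observation is treated as a mass ``w_k`` centred at the plotting
    position ``(C_k - w_k/2) / W`` (cumulative weight midpoint); quantiles
    interpolate linearly between adjacent positions.  For unit weights this
    is the classic Hazen definition; multiplying all weights by a constant
    leaves the result bit-identical.
    """
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    if x.size == 0:
        raise DomainError("cannot compute quantiles of an empty collection")
    if np.any(w <= 0):
        raise DomainError("weights must be strictly positive")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    t = (cw - ws / 2) / cw[-1]
    return np.interp(np.asarray(q, float), t, xs)


def assign_quartiles(pop: pd.DataFrame, column: str = "ssb_ml"):
    """Assign each individual a consumption quartile (weighted boundaries).

    Returns ``(labels, boundaries)`` where ``labels`` is a Series indexed
    like ``pop`` with values Q1..Q4 and ``boundaries`` the three weighted
    quartile cut points.  Values equal to a boundary fall in the lower
    quartile.
    """
    if len(pop) == 0:
        raise DomainError("cannot assign quartiles in an empty population")
    bounds = weighted_quantile(pop[column], pop["svy_weight"], [0.25, 0.5, 0.75])
    labels = np.asarray(QUARTILE_LABELS, dtype=object)[
        np.searchsorted(bounds, pop[column].to_numpy(), side="left")]
    return pd.Series(labels, index=pop.index, name="quartile"), bounds


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_population(path, pop: pd.DataFrame) -> None:
    """Write the population to CSV (UTF-8, documented header)."""
    pop.to_csv(path, index=False, columns=POPULATION_COLUMNS)


def _validate_rows(df: pd.DataFrame) -> None:
    checks = [
        ("sex", ~df["sex"].isin(SEXES), "sex must be male/female"),
        ("ses", ~df["ses"].isin(SES_LEVELS), "ses must be low/medium/high"),
        ("age", df["age"] < 20, "age must be >= 20"),
        ("height_m", (df["height_m"] < 1.2) | (df["height_m"] > 2.2),
         "height must be in [1.2, 2.2] m"),
        ("weight_kg", (df["weight_kg"] < 30) | (df["weight_kg"] > 250),
         "weight must be in [30, 250] kg"),
        ("ssb_ml", df["ssb_ml"] < 0, "ssb_ml must be >= 0"),
        ("svy_weight", df["svy_weight"] <= 0, "svy_weight must be > 0"),
    ]
    for col, bad, msg in checks:
        bad = bad | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row + 2}: {msg} (got {df[col].iloc[row]!r})")  # +2: header + 1-based


def read_population(path) -> pd.DataFrame:
    """Read and validate a population CSV.

    Unknown columns are ignored with a warning; missing or invalid fields
    raise :class:`ValidationError` naming the first offending file row.
    """
    df = pd.read_csv(path)
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in POPULATION_COLUMNS]
    if extra:
        logger.warning("ignoring unknown column(s): %s", ", ".join(extra))
        df = df.drop(columns=extra)
    for col, typ in [("id", np.int64), ("age", np.int64), ("height_m", float),
                     ("weight_kg", float), ("ssb_ml", float), ("svy_weight", float)]:
        try:
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column {col!r} is not numeric: {exc}") from exc
    df["sex"] = df["sex"].astype(object)
    df["ses"] = df["ses"].astype(object)
    _validate_rows(df)
    return df[POPULATION_COLUMNS]
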