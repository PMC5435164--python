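"""End-to-end orchestration: generate -> tax -> weight -> tables -> diabetes.

One :class:`RunConfig` drives the whole chain and every output is written
as CSV with fixed headers plus a JSON manifest capturing the seed, the
configuration hash and package version, so identical config + seed give
byte-identical output files.  The root seed fans out to per-stage child
seeds through :class:`numpy.random.SeedSequence` so stages can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bmi import prevalence_by_category, stratified_bmi_change
from .cra import sensitivity_table
from .diabetes import (averted_cases, link_from_changes, mexico_like_structure,
                       project)
from .errors import ConfigurationError
from .hall import HallParameters, bmi_at_times, initialize_state
from .population import (PopulationConfig, generate_population,
                         read_population, weighted_mean, write_population)
from .rates import (IncidenceParams, default_mortality_schedules,
                    generate_births, generate_incidence_schedule)
from .tax import (DEFAULT_CALORIC_DENSITY, DEFAULT_SERVING_SIZE, apply_tax,
                  scenario, summarize_consumption)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    seed: int = 12345
    n: int = 10_000
    population_path: str | None = None      # read instead of generating
    scenarios: tuple = ("avg10", "peak10", "avg20", "peak20")
    horizon_years: float = 10.0
    dt_days: float = 1.0
    caloric_density: float = DEFAULT_CALORIC_DENSITY
    serving_size_ml: float = DEFAULT_SERVING_SIZE
    incidence_scenario: str = "intermediate"
    rr_per_serving: float = 1.26
    dm_mortality_hr: float = 1.0
    diabetes_start_year: int = 2010
    diabetes_end_year: int = 2050
    tax_year: int = 2015
    pal: float = 1.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        return cls(**raw)

    def validate(self):
        for name in self.scenarios:
            scenario(name)  # raises on unknown names
        if self.population_path and not Path(self.population_path).exists():
            raise ConfigurationError(f"population file not found: {self.population_path}")
        return self


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full chain and write all tables; returns the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(2)
    tables: dict[str, pd.DataFrame] = {}

    logger.info("stage: population")
    if config.population_path:
        pop = read_population(config.population_path)
    else:
        pop = generate_population(PopulationConfig(n=config.n, seed=int(seeds[0])))
    write_population(outdir / "population.csv", pop)

    params = HallParameters(pal=config.pal)
    state = initialize_state(pop, params)
    base_bmi = (pop["weight_kg"] / pop["height_m"] ** 2).to_numpy()

    struct = mexico_like_structure()
    mort = default_mortality_schedules()
    births = generate_births()
    inc = generate_incidence_schedule(config.incidence_scenario, IncidenceParams())
    base_proj = project(struct, inc, mort, births,
                        start_year=config.diabetes_start_year,
                        end_year=config.diabetes_end_year,
                        tax_year=config.tax_year,
                        dm_mortality_hr=config.dm_mortality_hr)

    cons_rows, bmi_rows, prev_rows, diab_rows, crm_rows = [], [], [], [], []
    for name in config.scenarios:
        logger.info("stage: scenario %s", name)
        changes = apply_tax(pop, name, caloric_density=config.caloric_density,
                            serving_size_ml=config.serving_size_ml)
        cons = summarize_consumption(pop, changes, config.caloric_density)
        cons.insert(0, "scenario", name)
        cons_rows.append(cons)

        bmis = bmi_at_times(state, changes["delta_kcal"].to_numpy(),
                            years=config.horizon_years, dt=config.dt_days,
                            params=params, at_years=(1.0, config.horizon_years))
        change_tbl = stratified_bmi_change(pop, base_bmi, bmis)
        change_tbl.insert(0, "scenario", name)
        bmi_rows.append(change_tbl)

        prev = prevalence_by_category(pop, base_bmi, bmis[config.horizon_years])
        prev.insert(0, "scenario", name)
        prev_rows.append(prev)

        link = link_from_changes(pop, changes, config.rr_per_serving,
                                 config.serving_size_ml)
        cf = project(struct, inc, mort, births, link=link,
                     start_year=config.diabetes_start_year,
                     end_year=config.diabetes_end_year,
                     tax_year=config.tax_year,
                     dm_mortality_hr=config.dm_mortality_hr)
        d = cf.records[["year", "prevalence_pct", "incident_cases"]].copy()
        d.insert(0, "arm", name)
        d["baseline_prevalence_pct"] = base_proj.records["prevalence_pct"].to_numpy()
        d["cumulative_averted"] = [
            averted_cases(base_proj, cf, y, config.tax_year) if y >= config.tax_year
            else 0.0 for y in d["year"]]
        diab_rows.append(d)

        ode_mean = weighted_mean(bmis[config.horizon_years] - base_bmi,
                                 pop["svy_weight"])
        crm = sensitivity_table(pop, changes, ode_mean=ode_mean)
        crm.insert(0, "scenario", name)
        crm_rows.append(crm)

    d0 = base_proj.records[["year", "prevalence_pct", "incident_cases"]].copy()
    d0.insert(0, "arm", "no_tax")
    d0["baseline_prevalence_pct"] = d0["prevalence_pct"]
    d0["cumulative_averted"] = 0.0

    tables["consumption_summary"] = pd.concat(cons_rows, ignore_index=True)
    tables["bmi_change"] = pd.concat(bmi_rows, ignore_index=True)
    tables["prevalence"] = pd.concat(prev_rows, ignore_index=True)
    tables["diabetes_projection"] = pd.concat([d0, *diab_rows], ignore_index=True)
    tables["crm_sensitivity"] = pd.concat(crm_rows, ignore_index=True)

    paths = write_report(tables, outdir)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "outputs": sorted(p.name for p in paths),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True, default=str))
    return manifest


def write_report(tables: dict, outdir) -> list[Path]:
    """Write each table as CSV plus a short human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    lines = ["ssbtax run summary", "=" * 18]
    for name, table in tables.items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
        lines.append(f"{name}: {len(table)} rows -> {p.name}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return paths
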