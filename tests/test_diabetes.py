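"""Markov diabetes projection: hand oracle, conservation, counterfactuals."""

import numpy as np
import pytest

from ssbtax.diabetes import (DEFAULT_SES_SHARES, PopulationStructure, RiskLink,
                             averted_cases, incidence_multiplier,
                             link_from_changes, mexico_like_structure, project)
from ssbtax.errors import ConfigurationError, DomainError
from ssbtax.population import SES_LEVELS, SEXES
from ssbtax.rates import (BirthProjection, GompertzParams, RateSchedule,
                          default_mortality_schedules, generate_births,
                          generate_incidence_schedule,
                          generate_mortality_schedule)


def flat_schedule(kind, rate, min_age=0):
    ages = np.arange(0, 101)
    r = np.full(ages.shape, rate)
    r[ages < min_age] = 0.0
    return RateSchedule(kind, "both", ages, r)


def toy_inputs(mort_rate=0.1, inc_rate=0.2, start=2020, end=2022):
    """One male cohort of 1000 thirty-year-olds, constant hazards."""
    sus = np.zeros((2, 3, 101))
    sus[0, 0, 30] = 1000.0
    structure = PopulationStructure(susceptible=sus, diagnosed=np.zeros_like(sus))
    mort = {s: flat_schedule("mortality", mort_rate) for s in SEXES}
    inc = flat_schedule("incidence", inc_rate, min_age=20)
    years = np.arange(start, end + 1)
    births = BirthProjection(years, {"male": np.zeros_like(years, dtype=float),
                                     "female": np.zeros_like(years, dtype=float)})
    return structure, inc, mort, births


class TestMultiplier:
    def test_no_change_gives_unity(self):
        assert incidence_multiplier(RiskLink(), "low") == 1.0

    @pytest.mark.parametrize("delta, expected", [
        (-1.0, 1 / 1.26), (-0.5, 1.26 ** -0.5)])
    def test_power_evaluation(self, delta, expected):
        link = RiskLink(delta_servings_by_ses={"low": delta})
        assert incidence_multiplier(link, "low") == pytest.approx(expected, rel=1e-9)

    def test_link_from_population_changes(self, pop10k):
        from ssbtax.tax import apply_tax
        link = link_from_changes(pop10k, apply_tax(pop10k, "avg10"))
        for ses in SES_LEVELS:
            assert 0 < incidence_multiplier(link, ses) < 1


class TestToyOracle:
    def test_two_year_hand_computed_table(self):
        """Constant hazards admit a closed form: with annual survival
        s = exp(-0.1) and escape-from-diagnosis e = exp(-0.2),

            S(2) = 1000 s^2 e^2,
            D(2) = 1000 s^2 (1-e) (1 + e),
            incident(1) = 1000 s (1-e),  incident(2) = 1000 s^2 e (1-e).
        """
        structure, inc, mort, births = toy_inputs()
        res = project(structure, inc, mort, births, start_year=2020, end_year=2022)
        s, e = np.exp(-0.1), np.exp(-0.2)
        inc1 = 1000 * s * (1 - e)
        inc2 = 1000 * s**2 * e * (1 - e)
        d2 = 1000 * s**2 * (1 - e) * (1 + e)
        s2 = 1000 * s**2 * e**2
        got = res.records.set_index("year")
        assert got.loc[2021, "incident_cases"] == pytest.approx(inc1, rel=1e-12)
        assert got.loc[2022, "incident_cases"] == pytest.approx(inc2, rel=1e-12)
        assert got.loc[2022, "alive"] == pytest.approx(s2 + d2, rel=1e-12)
        assert got.loc[2022, "prevalence_pct"] == pytest.approx(
            100 * d2 / (s2 + d2), rel=1e-12)

    def test_incidence_abolished_averts_all_baseline_cases(self):
        structure, inc, mort, births = toy_inputs()
        base = project(structure, inc, mort, births, start_year=2020,
                       end_year=2022)
        link = RiskLink(rr_per_serving=1e12,
                        delta_servings_by_ses={s: -1.0 for s in SES_LEVELS})
        cf = project(structure, inc, mort, births, link=link, start_year=2020,
                     end_year=2022, tax_year=2020)
        assert cf.records["incident_cases"].sum() == pytest.approx(0.0, abs=1e-9)
        assert averted_cases(base, cf, 2022, from_year=2020) == pytest.approx(
            base.records["incident_cases"].sum(), rel=1e-9)

    def test_zero_incidence_zero_prevalence(self):
        structure, _, mort, births = toy_inputs()
        inc0 = flat_schedule("incidence", 0.0)
        res = project(structure, inc0, mort, births, start_year=2020, end_year=2022)
        assert (res.records["prevalence_pct"] == 0).all()

    def test_matches_stochastic_microsimulation(self):
        """Individual-level Bernoulli simulation of the same cohort agrees
        with the deterministic recursion within 3 binomial standard errors."""
        structure, inc, mort, births = toy_inputs(end=2025)
        res = project(structure, inc, mort, births, start_year=2020, end_year=2025)
        n = 200_000
        rng = np.random.default_rng(2020)
        alive = np.ones(n, bool)
        dm = np.zeros(n, bool)
        qd = 1 - np.exp(-0.1)
        qi = 1 - np.exp(-0.2)
        for _ in range(5):
            alive &= rng.random(n) >= qd
            new = alive & ~dm & (rng.random(n) < qi)
            dm |= new
        prev_micro = dm[alive].mean()
        se = np.sqrt(prev_micro * (1 - prev_micro) / alive.sum())
        assert res.records.iloc[-1]["prevalence_pct"] / 100 == pytest.approx(
            prev_micro, abs=3 * se)


@pytest.fixture(scope="module")
def default_inputs():
    return (mexico_like_structure(), generate_incidence_schedule("intermediate"),
            default_mortality_schedules(), generate_births())


class TestProjectionProperties:
    def test_person_conservation(self, default_inputs):
        structure, inc, mort, births = default_inputs
        res = project(structure, inc, mort, births)
        rec = res.records
        launched = structure.total
        born = sum(births.births(y, s) for y in range(2011, 2051) for s in SEXES)
        total = rec.iloc[-1]["alive"] + rec.iloc[-1]["dead"]
        assert total == pytest.approx(launched + born, rel=1e-9)

    def test_null_counterfactual_identical(self, default_inputs):
        structure, inc, mort, births = default_inputs
        base = project(structure, inc, mort, births)
        null_link = RiskLink(delta_servings_by_ses={s: 0.0 for s in SES_LEVELS})
        cf = project(structure, inc, mort, births, link=null_link)
        assert averted_cases(base, cf, 2050) == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(cf.records["prevalence_pct"],
                                   base.records["prevalence_pct"])

    def test_smaller_multiplier_lower_prevalence_more_averted(self, default_inputs):
        structure, inc, mort, births = default_inputs
        base = project(structure, inc, mort, births)
        mild = RiskLink(delta_servings_by_ses={s: -0.05 for s in SES_LEVELS})
        strong = RiskLink(delta_servings_by_ses={s: -0.30 for s in SES_LEVELS})
        cf_mild = project(structure, inc, mort, births, link=mild)
        cf_strong = project(structure, inc, mort, births, link=strong)
        after = base.records["year"] >= 2015
        assert np.all(cf_strong.records.loc[after, "prevalence_pct"]
                      < cf_mild.records.loc[after, "prevalence_pct"])
        assert averted_cases(base, cf_strong, 2050) > averted_cases(base, cf_mild, 2050)

    def test_incidence_scenarios_ordered_every_year(self, default_inputs):
        structure, _, mort, births = default_inputs
        prev = {}
        for scen in ("optimistic", "intermediate", "pessimistic"):
            inc = generate_incidence_schedule(scen)
            prev[scen] = project(structure, inc, mort, births).records["prevalence_pct"]
        assert np.all(prev["pessimistic"] >= prev["intermediate"])
        assert np.all(prev["intermediate"] >= prev["optimistic"])

    def test_rr_confidence_bounds_bracket_central_averted(self, default_inputs,
                                                          pop10k):
        from ssbtax.tax import apply_tax
        structure, inc, mort, births = default_inputs
        changes = apply_tax(pop10k, "avg10")
        base = project(structure, inc, mort, births)
        averted = {}
        for rr in (1.12, 1.26, 1.41):
            link = link_from_changes(pop10k, changes, rr_per_serving=rr)
            cf = project(structure, inc, mort, births, link=link)
            averted[rr] = averted_cases(base, cf, 2030)
        assert averted[1.12] < averted[1.26] < averted[1.41]

    def test_excess_mortality_lowers_prevalence(self, default_inputs):
        structure, inc, mort, births = default_inputs
        plain = project(structure, inc, mort, births)
        excess = project(structure, inc, mort, births, dm_mortality_hr=1.8)
        assert excess.prevalence(2050) < plain.prevalence(2050)

    def test_configuration_errors(self, default_inputs):
        structure, inc, mort, births = default_inputs
        with pytest.raises(ConfigurationError):
            project(structure, inc, mort, births, start_year=2050, end_year=2040)
        with pytest.raises(ConfigurationError):
            project(structure, inc, mort, births, end_year=2080)

    def test_mismatched_horizons_rejected(self, default_inputs):
        structure, inc, mort, births = default_inputs
        a = project(structure, inc, mort, births, end_year=2030)
        b = project(structure, inc, mort, births, end_year=2040)
        with pytest.raises(DomainError):
            averted_cases(a, b, 2030)
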