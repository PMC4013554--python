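"""Annual-cycle engine: rate conversion, stepping, aging, aggregation."""

import math

import pytest

from dmforecast import (
    Compartments,
    GeneratorParams,
    ModelConfig,
    Stratum,
    advance_population,
    generate_bundle,
    rate_to_probability,
    run_bundle,
    run_model,
    step_stratum,
)
from dmforecast.engine import RunResult
from dmforecast.strata import ALL_STRATA


class TestRateToProbability:
    @pytest.mark.parametrize(
        "rate, mode, expected",
        [
            (0.0129, "exponential", 1 - math.exp(-0.0129)),
            (0.0, "exponential", 0.0),
            (0.0, "direct", 0.0),
            (0.0129, "direct", 0.0129),
            (1.7, "direct", 1.0),
        ],
    )
    def test_modes(self, rate, mode, expected):
        assert rate_to_probability(rate, mode) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1)


class TestStepStratum:
    def test_null_dynamics(self):
        comp = Compartments(100, 50, 25, 10)
        nxt, flows = step_stratum(comp, 0.0, 6.74, 1.44, 0.0, 0.0)
        assert nxt == comp
        assert (flows.new_cases, flows.deaths_other, flows.deaths_diabetes) == (0, 0, 0)

    def test_single_compartment_closed_form(self):
        comp = Compartments(1000, 0, 0, 0)
        nxt, flows = step_stratum(comp, 0.0129, 6.74, 1.44, 0.0, 0.0)
        assert flows.new_cases == pytest.approx(1000 * (1 - math.exp(-0.0129)))
        assert nxt.healthy == pytest.approx(1000 * math.exp(-0.0129))
        assert nxt.diabetes == pytest.approx(flows.new_cases)

    def test_diabetic_deaths_split_proportionally_to_hazards(self):
        # case fatality 0.15% and other-cause mortality 0.01%/yr: the
        # joint exit 1-exp(-0.0016) splits 15:1 between the death states.
        comp = Compartments(0, 0, 0, 1000)
        nxt, flows = step_stratum(comp, 0.0, 6.74, 1.44, 0.0015, 0.0001)
        total_exit = 1000 * (1 - math.exp(-0.0016))
        assert flows.deaths_diabetes + flows.deaths_other == pytest.approx(total_exit)
        assert flows.deaths_diabetes / flows.deaths_other == pytest.approx(15.0)
        assert flows.deaths_diabetes == pytest.approx(total_exit * 15 / 16)

    def test_exposed_states_transition_faster(self):
        comp = Compartments(100, 100, 100, 0)
        nxt, _ = step_stratum(comp, 0.02, 6.74, 1.44, 0.0, 0.0)
        assert nxt.obese < nxt.smokers < nxt.healthy

    def test_conservation(self):
        comp = Compartments(800, 120, 60, 20)
        nxt, flows = step_stratum(comp, 0.05, 6.74, 1.44, 0.01, 0.005)
        total_out = nxt.living + flows.deaths_other + flows.deaths_diabetes
        assert total_out == pytest.approx(comp.living, rel=1e-12)


class TestAdvancePopulation:
    def test_closed_strata_identity_and_scaling(self):
        states = {
            s: Compartments(100.0, 50.0, 25.0, 25.0) for s in ALL_STRATA
        }
        same = advance_population(states, {s: 200.0 for s in ALL_STRATA})
        assert same[ALL_STRATA[0]] == states[ALL_STRATA[0]]
        doubled = advance_population(states, {s: 400.0 for s in ALL_STRATA})
        c = doubled[ALL_STRATA[0]]
        assert (c.healthy, c.diabetes) == (200.0, 50.0)
        # prevalence share unchanged
        assert c.diabetes / c.living == pytest.approx(25.0 / 200.0)

    def test_missing_next_year_population_rejected(self):
        states = {s: Compartments(10, 0, 0, 0) for s in ALL_STRATA}
        pop = {s: 10.0 for s in ALL_STRATA[:-1]}
        with pytest.raises(ValueError, match="missing next-year population"):
            advance_population(states, pop)

    def test_band_shift_moves_tenth_downstream(self):
        states = {s: Compartments(900.0, 0.0, 0.0, 100.0) for s in ALL_STRATA}
        trends = {
            (f, s): 0.0 for f in ("obesity", "smoking") for s in ALL_STRATA
        }
        # next population set to post-shift totals so no rescale occurs
        oldest = Stratum("male", "75+")
        second = Stratum("male", "35-44")
        next_pop = {}
        for s in ALL_STRATA:
            if s.age_band == "25-34":
                next_pop[s] = 900.0
            elif s.age_band == "75+":
                next_pop[s] = 1000.0 * (1 - 1 / 15) + 100.0
            else:
                next_pop[s] = 1000.0
        out = advance_population(
            states,
            next_pop,
            "band_shift",
            next_trends=trends,
            rr_obese={"male": 6.74, "female": 12.41},
            rr_smoker={"male": 1.44, "female": 1.44},
        )
        # 35-44 receives a tenth of 25-34 and loses a tenth of itself
        assert out[second].living == pytest.approx(1000.0)
        assert out[second].diabetes == pytest.approx(100.0)
        # 75+ keeps 14/15 of itself plus inflow from 65-74
        assert out[oldest].living == pytest.approx(1000 * 14 / 15 + 100)

    def test_band_shift_entrants_carry_risk_factor_mix(self):
        states = {s: Compartments(1000.0, 0.0, 0.0, 0.0) for s in ALL_STRATA}
        trends = {
            (f, s): (0.3 if f == "obesity" else 0.2)
            for f in ("obesity", "smoking")
            for s in ALL_STRATA
        }
        next_pop = {s: 2000.0 if s.age_band == "25-34" else 900.0 for s in ALL_STRATA}
        out = advance_population(
            states,
            next_pop,
            "band_shift",
            next_trends=trends,
            rr_obese={"male": 6.74, "female": 12.41},
            rr_smoker={"male": 1.44, "female": 1.44},
            entrant_diabetes_prev=0.0,
        )
        entry = out[Stratum("male", "25-34")]
        assert entry.living == pytest.approx(2000.0)
        assert entry.obese > 0.0 and entry.smokers > 0.0
        assert entry.diabetes == 0.0


class TestRunModel:
    def test_null_run_stays_at_zero(self, noiseless_bundle):
        b = noiseless_bundle
        hz = b.hazards.scaled(0.0)
        baseline = {s: 0.0 for s in ALL_STRATA}
        res = run_model(b.config, hz, baseline, b.population, b.build_trends())
        assert (res.prevalence("total")["prevalence"] == 0.0).all()

    def test_start_year_echoes_aggregated_baseline(self, default_bundle):
        res = run_bundle(default_bundle)
        total = res.prevalence("total")
        pop0 = {
            s: default_bundle.population[(default_bundle.config.start_year, s)]
            for s in ALL_STRATA
        }
        expected = sum(
            default_bundle.baseline[s] * pop0[s] for s in ALL_STRATA
        ) / sum(pop0.values())
        assert total.iloc[0]["prevalence"] == pytest.approx(expected, rel=1e-12)
        assert total.iloc[0]["prevalence"] == pytest.approx(0.085, abs=1e-12)

    def test_conservation_per_stratum_cycle(self, default_bundle):
        res = run_bundle(default_bundle)
        states = res.states.set_index(["year", "sex", "age_band"])
        for row in res.flows.itertuples(index=False):
            start = states.loc[(row.year, row.sex, row.age_band)]
            living_start = (
                start.healthy + start.obese + start.smokers + start.diabetes
            )
            balance = row.living_after_step + row.deaths_other + row.deaths_diabetes
            assert balance == pytest.approx(living_start, rel=1e-9)

    def test_zero_remission_diabetes_only_falls_by_death(self, default_bundle):
        res = run_bundle(default_bundle)
        assert (res.flows.new_cases >= 0).all()
        # cumulative deaths are non-decreasing per stratum
        for (_, _), grp in res.states.groupby(["sex", "age_band"]):
            grp = grp.sort_values("year")
            assert grp.dead_diabetes.is_monotonic_increasing
            assert grp.dead_other.is_monotonic_increasing

    def test_raising_obesity_never_lowers_prevalence(self, noiseless_bundle):
        lo = run_bundle(noiseless_bundle).prevalence("total")["prevalence"]
        hi_params = GeneratorParams(
            noise_sd=0.0,
            obesity_start={"male": 0.22, "female": 0.30},
            obesity_slope={"male": 0.010, "female": 0.018},
        )
        hi_bundle = generate_bundle(hi_params)
        hi = run_bundle(hi_bundle).prevalence("total")["prevalence"]
        assert (hi >= lo - 1e-12).all()

    def test_prevalence_approaches_one_without_mortality(self, noiseless_bundle):
        b = noiseless_bundle
        config = ModelConfig(start_year=1992, end_year=3192)
        hz = b.hazards
        no_death = type(hz)(
            incidence=hz.incidence,
            case_fatality={s: 0.0 for s in ALL_STRATA},
            total_mortality={s: 0.0 for s in ALL_STRATA},
            rr_obese=hz.rr_obese,
            rr_smoker=hz.rr_smoker,
        )
        pop = {
            (y, s): 1000.0 for y in config.years() for s in ALL_STRATA
        }
        trends = {
            (f, s): type(next(iter(b.build_trends().values())))(
                stratum=s, factor=f,
                values={y: 0.3 if f == "obesity" else 0.2 for y in config.years()},
            )
            for f in ("obesity", "smoking")
            for s in ALL_STRATA
        }
        res = run_model(config, no_death, {s: 0.0 for s in ALL_STRATA}, pop, trends)
        total = res.prevalence("total")
        assert total.iloc[-1]["prevalence"] > 0.99
        assert total["prevalence"].is_monotonic_increasing

    def test_deterministic_rerun_is_identical(self, default_bundle):
        a = run_bundle(default_bundle)
        b = run_bundle(default_bundle)
        assert a.states.equals(b.states)
        assert a.flows.equals(b.flows)

    def test_band_shift_mode_runs_and_conserves(self):
        bundle = generate_bundle(
            GeneratorParams(random_seed=3), aging_mode="band_shift"
        )
        res = run_bundle(bundle)
        total = res.prevalence("total")
        assert ((total.prevalence >= 0) & (total.prevalence <= 1)).all()
        # exogenous totals still honoured each year
        living = (
            res.states.assign(
                living=lambda d: d[["healthy", "obese", "smokers", "diabetes"]].sum(axis=1)
            )
            .groupby("year")["living"]
            .sum()
        )
        for year, value in living.items():
            expected = sum(
                bundle.population[(year, s)] for s in ALL_STRATA
            )
            assert value == pytest.approx(expected, rel=1e-9)


class TestAggregatePrevalence:
    @staticmethod
    def _result_from_counts(rows):
        import pandas as pd

        states = pd.DataFrame(rows)
        for col in ("dead_other", "dead_diabetes"):
            states[col] = 0.0
        return RunResult(states=states, flows=pd.DataFrame())

    def test_single_stratum(self):
        res = self._result_from_counts(
            [dict(year=2000, sex="male", age_band="25-34",
                  healthy=700, obese=50, smokers=0, diabetes=250)]
        )
        assert res.prevalence("total").iloc[0]["prevalence"] == pytest.approx(0.25)

    def test_weighted_mean_across_strata(self):
        res = self._result_from_counts(
            [
                dict(year=2000, sex="male", age_band="25-34",
                     healthy=900, obese=0, smokers=0, diabetes=100),
                dict(year=2000, sex="female", age_band="25-34",
                     healthy=2100, obese=0, smokers=0, diabetes=900),
            ]
        )
        assert res.prevalence("total").iloc[0]["prevalence"] == pytest.approx(0.25)
        by_sex = res.prevalence("sex").set_index("sex")["prevalence"]
        assert by_sex["male"] == pytest.approx(0.10)
        assert by_sex["female"] == pytest.approx(0.30)

    def test_sex_totals_recombine_to_overall(self, default_bundle):
        res = run_bundle(default_bundle)
        states = res.states.copy()
        states["living"] = states[["healthy", "obese", "smokers", "diabetes"]].sum(axis=1)
        weights = states.groupby(["year", "sex"])["living"].sum().unstack()
        by_sex = res.prevalence("sex").pivot(index="year", columns="sex", values="prevalence")
        recombined = (by_sex * weights).sum(axis=1) / weights.sum(axis=1)
        total = res.prevalence("total").set_index("year")["prevalence"]
        assert recombined.values == pytest.approx(total.values, rel=1e-12)
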