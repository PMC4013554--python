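"""Annual-cycle Markov engine for the diabetes prevalence projection.

Each model year, every stratum's living population is partitioned into
Healthy / Obese / Smokers / Diabetes pools, the overall incidence is
decomposed into state-specific incidences (calibrated at the start year
by default, so that rising exposure prevalence raises aggregate
incidence), and one cycle of competing transitions is applied:

* Healthy, Obese and Smokers move to Diabetes (at I_h, I_h·RR_obese and
  I_h·RR_smoker respectively) or to death from other causes (total
  mortality m).
* Diabetics die of the disease (case fatality f) or of other causes (m);
  there is no remission.

Competing risks within a cycle are treated as additive hazards converted
jointly to an exit probability (1 - exp(-Σh) in exponential mode) and
split proportionally between destinations, which avoids
order-of-operations artifacts of sequential subtraction.

Between years the strata are re-anchored: the exogenous population
trajectory fixes each stratum's living total, and the exposure pools are
re-partitioned from the exogenous risk-factor trends, so only the
diabetes prevalence is evolved by the transition dynamics. Person counts
are continuous (fractional) throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .inputs import (
    BaselinePrevalence,
    Factor,
    HazardTable,
    InputBundle,
    ModelConfig,
    PopulationTrajectory,
    TrendSeries,
)
from .partition import Compartments, decompose_incidence, partition_stratum
from .strata import AGE_BANDS, ALL_STRATA, BAND_WIDTHS, SEXES, Stratum

RateMode = Literal["exponential", "direct"]


def rate_to_probability(rate: float, mode: RateMode = "exponential") -> float:
    """Convert an annual rate to a one-cycle transition probability.

    Exponential mode assumes a constant hazard within the cycle and
    returns ``1 - exp(-rate)``; direct mode treats the rate as a
    probability, capped at 1.
    """
    if rate < 0.0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if mode == "exponential":
        return 1.0 - math.exp(-rate)
    return min(rate, 1.0)


def competing_exit_probabilities(
    hazards: tuple[float, ...], mode: RateMode = "exponential"
) -> tuple[float, ...]:
    """Per-destination exit probabilities for competing hazards in one cycle.

    The total hazard is converted jointly and the exit probability split
    proportionally to the individual hazards.
    """
    total = sum(hazards)
    if total <= 0.0:
        return tuple(0.0 for _ in hazards)
    p_exit = rate_to_probability(total, mode)
    return tuple(p_exit * h / total for h in hazards)


@dataclass(frozen=True)
class Flows:
    """Person flows produced by one stratum cycle."""

    new_cases: float
    deaths_other: float
    deaths_diabetes: float


def step_stratum(
    comp: Compartments,
    incidence_healthy: float,
    rr_obese: float,
    rr_smoker: float,
    case_fatality: float,
    total_mortality: float,
    mode: RateMode = "exponential",
) -> tuple[Compartments, Flows]:
    """Apply one annual cycle of transitions to a stratum.

    Returns the post-cycle compartments (before any population
    re-anchoring) and the flows. Conservation holds exactly: persons in
    equal persons out plus deaths.
    """
    if incidence_healthy < 0.0:
        raise ValueError("incidence must be >= 0")
    m = total_mortality
    p_hd, p_hm = competing_exit_probabilities((incidence_healthy, m), mode)
    p_od, p_om = competing_exit_probabilities((incidence_healthy * rr_obese, m), mode)
    p_sd, p_sm = competing_exit_probabilities((incidence_healthy * rr_smoker, m), mode)
    p_df, p_dm = competing_exit_probabilities((case_fatality, m), mode)

    new_cases = comp.healthy * p_hd + comp.obese * p_od + comp.smokers * p_sd
    deaths_other = (
        comp.healthy * p_hm
        + comp.obese * p_om
        + comp.smokers * p_sm
        + comp.diabetes * p_dm
    )
    deaths_diabetes = comp.diabetes * p_df

    nxt = Compartments(
        healthy=comp.healthy * (1.0 - p_hd - p_hm),
        obese=comp.obese * (1.0 - p_od - p_om),
        smokers=comp.smokers * (1.0 - p_sd - p_sm),
        diabetes=comp.diabetes * (1.0 - p_df - p_dm) + new_cases,
    )
    return nxt, Flows(new_cases, deaths_other, deaths_diabetes)


def advance_population(
    states: Mapping[Stratum, Compartments],
    next_population: Mapping[Stratum, float],
    aging_mode: Literal["closed_strata", "band_shift"] = "closed_strata",
    *,
    next_trends: Mapping[tuple[Factor, Stratum], float] | None = None,
    rr_obese: Mapping[str, float] | None = None,
    rr_smoker: Mapping[str, float] | None = None,
    entrant_diabetes_prev: float = 0.0,
) -> dict[Stratum, Compartments]:
    """Reconcile post-cycle states with next year's exogenous population.

    ``closed_strata``: each stratum's compartments are rescaled by one
    common factor so the living total equals next year's population;
    prevalence shares are preserved and no persons flow between bands.

    ``band_shift``: one band-width's worth of each band (1/10 per year;
    1/15 for the open-ended 75+ band, which exits the modelled ages)
    moves to the next band carrying its compartment mix; entrants to
    25-34 fill that band's deficit with the next year's risk-factor mix
    and a configurable diabetes prevalence (default 0); all bands are
    then rescaled to the exogenous totals.
    """
    for s in states:
        if s not in next_population:
            raise ValueError(f"missing next-year population for {s}")

    if aging_mode == "band_shift":
        shifted: dict[Stratum, Compartments] = {}
        for sex in SEXES:
            inflow = Compartments(0.0, 0.0, 0.0, 0.0)
            for band in AGE_BANDS:
                s = Stratum(sex, band)
                comp = states[s]
                out_frac = 1.0 / BAND_WIDTHS[band]
                kept = 1.0 - out_frac
                shifted[s] = Compartments(
                    healthy=comp.healthy * kept + inflow.healthy,
                    obese=comp.obese * kept + inflow.obese,
                    smokers=comp.smokers * kept + inflow.smokers,
                    diabetes=comp.diabetes * kept + inflow.diabetes,
                )
                inflow = Compartments(
                    healthy=comp.healthy * out_frac,
                    obese=comp.obese * out_frac,
                    smokers=comp.smokers * out_frac,
                    diabetes=comp.diabetes * out_frac,
                )
                # outflow from 75+ leaves the modelled population
            entry = Stratum(sex, AGE_BANDS[0])
            deficit = next_population[entry] - shifted[entry].living
            if deficit > 0.0:
                if next_trends is None or rr_obese is None or rr_smoker is None:
                    raise ValueError(
                        "band_shift aging needs next-year trends and RRs for entrants"
                    )
                entrants = partition_stratum(
                    deficit,
                    entrant_diabetes_prev * deficit,
                    next_trends[("obesity", entry)],
                    next_trends[("smoking", entry)],
                    rr_obese[sex],
                    rr_smoker[sex],
                )
                cur = shifted[entry]
                shifted[entry] = Compartments(
                    healthy=cur.healthy + entrants.healthy,
                    obese=cur.obese + entrants.obese,
                    smokers=cur.smokers + entrants.smokers,
                    diabetes=cur.diabetes + entrants.diabetes,
                )
        states = shifted

    out: dict[Stratum, Compartments] = {}
    for s, comp in states.items():
        target = next_population[s]
        if comp.living <= 0.0:
            # Extinct stratum repopulated exogenously: all entrants healthy
            # until the next partition re-anchors the exposure pools.
            out[s] = Compartments(target, 0.0, 0.0, 0.0)
            continue
        scale = target / comp.living
        out[s] = Compartments(
            healthy=comp.healthy * scale,
            obese=comp.obese * scale,
            smokers=comp.smokers * scale,
            diabetes=comp.diabetes * scale,
        )
    return out


@dataclass
class RunResult:
    """Projection output: per-year, per-stratum states and flows.

    ``states`` has one row per (year, stratum) with the four living
    compartments and cumulative deaths; ``flows`` has one row per cycle
    (years start..end-1) with new cases, deaths and the pre-rescale
    living total after the cycle (used for conservation checks).
    """

    states: pd.DataFrame
    flows: pd.DataFrame

    def prevalence(
        self, by: Literal["total", "sex", "stratum"] = "total"
    ) -> pd.DataFrame:
        return aggregate_prevalence(self, by=by)

    def diabetes_count(self) -> pd.Series:
        """Total number of living diabetics per year."""
        return self.states.groupby("year")["diabetes"].sum()

    def write(self, directory: str | Path) -> None:
        """Write tidy CSV results and a summary JSON to ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        states_long = self.states.melt(
            id_vars=["year", "sex", "age_band"], var_name="compartment",
            value_name="value",
        )
        states_long.to_csv(directory / "states.csv", index=False)
        flows_long = self.flows.melt(
            id_vars=["year", "sex", "age_band"], var_name="flow",
            value_name="value",
        )
        flows_long.to_csv(directory / "flows.csv", index=False)
        total = self.prevalence("total").set_index("year")["prevalence"]
        by_sex = self.prevalence("sex")
        summary = {
            "years": [int(y) for y in total.index],
            "prevalence_total": [float(v) for v in total],
            "prevalence_male": [
                float(v)
                for v in by_sex[by_sex.sex == "male"].sort_values("year")["prevalence"]
            ],
            "prevalence_female": [
                float(v)
                for v in by_sex[by_sex.sex == "female"].sort_values("year")["prevalence"]
            ],
            "diabetes_count": [float(v) for v in self.diabetes_count()],
        }
        (directory / "summary.json").write_text(json.dumps(summary, indent=1))

    @classmethod
    def read(cls, directory: str | Path) -> "RunResult":
        """Round-trip reader for :meth:`write` output."""
        directory = Path(directory)
        states = (
            pd.read_csv(directory / "states.csv")
            .pivot_table(
                index=["year", "sex", "age_band"], columns="compartment",
                values="value", sort=False,
            )
            .reset_index()
        )
        states.columns.name = None
        flows = (
            pd.read_csv(directory / "flows.csv")
            .pivot_table(
                index=["year", "sex", "age_band"], columns="flow",
                values="value", sort=False,
            )
            .reset_index()
        )
        flows.columns.name = None
        return cls(states=states, flows=flows)


def aggregate_prevalence(
    result: RunResult, by: Literal["total", "sex", "stratum"] = "total"
) -> pd.DataFrame:
    """Population-weighted diabetes prevalence over living persons.

    The total is consistent with the sex-specific values recombined with
    the same population weights.
    """
    df = result.states.copy()
    df["living"] = df[["healthy", "obese", "smokers", "diabetes"]].sum(axis=1)
    if by == "total":
        keys = ["year"]
    elif by == "sex":
        keys = ["year", "sex"]
    elif by == "stratum":
        keys = ["year", "sex", "age_band"]
    else:
        raise ValueError(f"unknown grouping {by!r}")
    g = df.groupby(keys, sort=True)[["diabetes", "living"]].sum()
    if g.empty:
        raise ValueError("empty grouping")
    out = (g["diabetes"] / g["living"]).rename("prevalence").reset_index()
    return out


def run_model(
    config: ModelConfig,
    hazards: HazardTable,
    baseline: BaselinePrevalence,
    population: PopulationTrajectory,
    trends: Mapping[tuple[Factor, Stratum], TrendSeries],
) -> RunResult:
    """Run the annual-cycle projection over all strata and years.

    The start-year aggregated prevalence equals the aggregated baseline
    input exactly: the first recorded year is the partitioned baseline,
    before any transition is applied.
    """
    years = list(config.years())
    state_rows: list[dict] = []
    flow_rows: list[dict] = []

    # Initial diabetes counts from the baseline prevalence surface.
    diabetes = {
        s: baseline[s] * population[(years[0], s)] for s in ALL_STRATA
    }

    comps: dict[Stratum, Compartments] = {}
    dead_other = {s: 0.0 for s in ALL_STRATA}
    dead_diabetes = {s: 0.0 for s in ALL_STRATA}

    for i, year in enumerate(years):
        # (1)-(2) re-anchor: exogenous living total and exposure trends.
        for s in ALL_STRATA:
            living = population[(year, s)]
            comps[s] = partition_stratum(
                living,
                min(diabetes[s], living),
                trends[("obesity", s)][year],
                trends[("smoking", s)][year],
                hazards.rr_obese[s.sex],
                hazards.rr_smoker[s.sex],
            )
            state_rows.append(
                {
                    "year": year,
                    "sex": s.sex,
                    "age_band": s.age_band,
                    "healthy": comps[s].healthy,
                    "obese": comps[s].obese,
                    "smokers": comps[s].smokers,
                    "diabetes": comps[s].diabetes,
                    "dead_other": dead_other[s],
                    "dead_diabetes": dead_diabetes[s],
                }
            )
        if year == years[-1]:
            break

        # Calibrate the healthy-state incidence. In baseline mode I_h is
        # fixed from the start-year shares, so later growth of the
        # exposed pools raises the aggregate incidence; per-cycle mode
        # re-decomposes every year, pinning aggregate incidence to the
        # input rate regardless of the trends.
        if i == 0 or config.incidence_anchor == "per_cycle":
            incidence_healthy = {
                s: decompose_incidence(
                    hazards.incidence[s],
                    comps[s].nondiabetic_shares(),
                    hazards.rr_obese[s.sex],
                    hazards.rr_smoker[s.sex],
                )
                for s in ALL_STRATA
            }

        # (3)-(4) step each stratum.
        stepped: dict[Stratum, Compartments] = {}
        for s in ALL_STRATA:
            i_h = incidence_healthy[s]
            nxt, flows = step_stratum(
                comps[s],
                i_h,
                hazards.rr_obese[s.sex],
                hazards.rr_smoker[s.sex],
                hazards.case_fatality[s],
                hazards.total_mortality[s],
                config.rate_conversion,
            )
            stepped[s] = nxt
            dead_other[s] += flows.deaths_other
            dead_diabetes[s] += flows.deaths_diabetes
            flow_rows.append(
                {
                    "year": year,
                    "sex": s.sex,
                    "age_band": s.age_band,
                    "new_cases": flows.new_cases,
                    "deaths_other": flows.deaths_other,
                    "deaths_diabetes": flows.deaths_diabetes,
                    "living_after_step": nxt.living,
                }
            )

        # (5) advance to next year's exogenous population.
        next_year = years[i + 1]
        next_pop = {s: population[(next_year, s)] for s in ALL_STRATA}
        next_trend_values = {
            (f, s): trends[(f, s)][next_year]
            for f in ("obesity", "smoking")
            for s in ALL_STRATA
        }
        advanced = advance_population(
            stepped,
            next_pop,
            config.aging_mode,
            next_trends=next_trend_values,
            rr_obese=hazards.rr_obese,
            rr_smoker=hazards.rr_smoker,
            entrant_diabetes_prev=config.entrant_diabetes_prev,
        )
        diabetes = {s: advanced[s].diabetes for s in ALL_STRATA}

    return RunResult(
        states=pd.DataFrame(state_rows), flows=pd.DataFrame(flow_rows)
    )


def run_bundle(bundle: InputBundle, capped: bool | None = None) -> RunResult:
    """Convenience wrapper: build trends from the bundle's survey points
    (capped per the config scenario unless overridden) and run."""
    if capped is None:
        capped = bundle.config.scenario == "capped"
    trends = bundle.build_trends(capped=capped)
    return run_model(
        bundle.config, bundle.hazards, bundle.baseline, bundle.population, trends
    )
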