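"""Input data model: risk-factor trend construction and validation.

Exogenous inputs to the projection are (a) annual population counts per
stratum, (b) sparse survey measurements of obesity and current-smoking
prevalence, (c) diabetes prevalence per stratum at the start year, and
(d) a table of transition hazards (incidence, case fatality, total
mortality, relative risks).

Survey points are turned into complete annual series by linear
interpolation between surveys and linear extrapolation beyond them,
using the overall observed slope between the first and last survey as
the future rate of increase. All series are clamped to the unit
interval, because they are prevalence proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping

from pydantic import BaseModel, model_validator

from .strata import ALL_STRATA, SEXES, Stratum

Factor = Literal["obesity", "smoking"]


@dataclass(frozen=True)
class SurveyPoint:
    """A single survey measurement of a risk-factor prevalence."""

    stratum: Stratum
    year: int
    prevalence: float
    factor: Factor

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(
                f"prevalence {self.prevalence} outside [0, 1] for "
                f"{self.stratum} {self.factor} {self.year}"
            )


@dataclass(frozen=True)
class TrendSeries:
    """Annual risk-factor prevalence for one stratum over the model years."""

    stratum: Stratum
    factor: Factor
    values: Mapping[int, float]

    def __getitem__(self, year: int) -> float:
        return self.values[year]

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.values))


def build_trend(
    points: Iterable[SurveyPoint], years: Iterable[int]
) -> TrendSeries:
    """Construct a complete annual series from sparse survey points.

    Piecewise-linear between adjacent surveys. Beyond the last survey the
    series continues with the overall observed slope, i.e. the slope of
    the chord from the first to the last survey point. Before the first
    survey it is back-extrapolated with the first segment's slope. A
    single point yields a constant series. Every value is clamped to
    [0, 1].
    """
    pts = sorted(points, key=lambda p: p.year)
    if not pts:
        raise ValueError("build_trend requires at least one survey point")
    seen_years = [p.year for p in pts]
    if len(set(seen_years)) != len(seen_years):
        raise ValueError(
            f"duplicate survey years {seen_years} for "
            f"{pts[0].stratum} {pts[0].factor}"
        )
    keys = {(p.stratum, p.factor) for p in pts}
    if len(keys) != 1:
        raise ValueError("survey points mix strata or factors")

    xs = [float(p.year) for p in pts]
    ys = [p.prevalence for p in pts]

    if len(pts) == 1:
        def value_at(year: int) -> float:
            return ys[0]
    else:
        # Overall observed rate of increase: first-to-last chord.
        forward_slope = (ys[-1] - ys[0]) / (xs[-1] - xs[0])
        back_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])

        def value_at(year: int) -> float:
            if year <= xs[0]:
                return ys[0] + back_slope * (year - xs[0])
            if year >= xs[-1]:
                return ys[-1] + forward_slope * (year - xs[-1])
            for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
                if x0 <= year <= x1:
                    return y0 + (y1 - y0) * (year - x0) / (x1 - x0)
            raise AssertionError("unreachable")  # pragma: no cover

    values = {int(y): min(1.0, max(0.0, value_at(int(y)))) for y in years}
    return TrendSeries(stratum=pts[0].stratum, factor=pts[0].factor, values=values)


def apply_cap(series: TrendSeries, cap: float) -> TrendSeries:
    """Cap a trend series at ``cap``: each value becomes ``min(value, cap)``.

    Idempotent; values already at or below the cap are unchanged.
    """
    if not 0.0 < cap <= 1.0:
        raise ValueError(f"cap must be in (0, 1], got {cap}")
    return replace(
        series, values={y: min(v, cap) for y, v in series.values.items()}
    )


@dataclass(frozen=True)
class HazardTable:
    """Annual transition hazards per stratum, in per-person-per-year units.

    Printed sources typically give incidence and total mortality per 1000
    population and case fatality in percent; here everything is stored as
    a proportion/rate per person per year (one canonical unit).

    Relative risks of developing diabetes apply to the exposed states:
    ``rr_obese`` and ``rr_smoker`` are per sex and must be >= 1.
    """

    incidence: Mapping[Stratum, float]
    case_fatality: Mapping[Stratum, float]
    total_mortality: Mapping[Stratum, float]
    rr_obese: Mapping[str, float]
    rr_smoker: Mapping[str, float]

    def scaled(self, factor: float) -> "HazardTable":
        """All hazards and RRs multiplied by ``factor``; RRs floored at 1."""
        return HazardTable(
            incidence={s: v * factor for s, v in self.incidence.items()},
            case_fatality={s: v * factor for s, v in self.case_fatality.items()},
            total_mortality={
                s: v * factor for s, v in self.total_mortality.items()
            },
            rr_obese={k: max(1.0, v * factor) for k, v in self.rr_obese.items()},
            rr_smoker={k: max(1.0, v * factor) for k, v in self.rr_smoker.items()},
        )


BaselinePrevalence = Mapping[Stratum, float]
PopulationTrajectory = Mapping[tuple[int, Stratum], float]


class ModelConfig(BaseModel):
    """Run settings for the projection.

    ``extremes_factor`` is the ± proportion used by the analysis of
    extremes; ``cap_male``/``cap_female`` are the obesity capping points
    of the capped scenario. ``aging_mode`` selects how strata evolve
    between years; ``rate_conversion`` selects how annual rates become
    per-cycle probabilities.

    ``incidence_anchor`` controls when the overall incidence is
    decomposed into the healthy-state incidence: ``baseline`` (default)
    calibrates I_h once from the start-year exposure shares and holds it
    fixed, so rising obesity raises aggregate incidence through the
    growing exposed pools; ``per_cycle`` re-decomposes against each
    year's shares, which keeps the aggregate incident flow pinned to the
    input rate and thereby neutralises risk-factor trends.
    """

    start_year: int = 1992
    end_year: int = 2022
    extremes_factor: float = 0.20
    scenario: Literal["uncapped", "capped"] = "uncapped"
    cap_male: float = 0.35
    cap_female: float = 0.60
    aging_mode: Literal["closed_strata", "band_shift"] = "closed_strata"
    rate_conversion: Literal["exponential", "direct"] = "exponential"
    incidence_anchor: Literal["baseline", "per_cycle"] = "baseline"
    entrant_diabetes_prev: float = 0.0
    random_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if not 0.0 < self.extremes_factor < 1.0:
            raise ValueError("extremes_factor must be in (0, 1)")
        for cap in (self.cap_male, self.cap_female):
            if not 0.0 < cap <= 1.0:
                raise ValueError("caps must be in (0, 1]")
        if not 0.0 <= self.entrant_diabetes_prev <= 1.0:
            raise ValueError("entrant_diabetes_prev must be in [0, 1]")
        return self

    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def cap_for(self, sex: str) -> float:
        return self.cap_male if sex == "male" else self.cap_female


@dataclass
class InputBundle:
    """A complete, self-consistent set of model inputs."""

    config: ModelConfig
    population: PopulationTrajectory
    obesity_points: list[SurveyPoint]
    smoking_points: list[SurveyPoint]
    baseline: BaselinePrevalence
    hazards: HazardTable

    def survey_points(self, factor: Factor, stratum: Stratum) -> list[SurveyPoint]:
        pts = self.obesity_points if factor == "obesity" else self.smoking_points
        return [p for p in pts if p.stratum == stratum]

    def build_trends(
        self, capped: bool = False
    ) -> dict[tuple[Factor, Stratum], TrendSeries]:
        """Annual trend series for both factors and all strata.

        With ``capped=True`` the obesity series are capped at the per-sex
        capping points; smoking is never capped.
        """
        years = self.config.years()
        trends: dict[tuple[Factor, Stratum], TrendSeries] = {}
        for factor in ("obesity", "smoking"):
            for stratum in ALL_STRATA:
                series = build_trend(self.survey_points(factor, stratum), years)
                if capped and factor == "obesity":
                    series = apply_cap(series, self.config.cap_for(stratum.sex))
                trends[(factor, stratum)] = series
        return trends


@dataclass(frozen=True)
class Violation:
    """One validation finding: which field, where, and what is wrong."""

    field: str
    message: str
    stratum: Stratum | None = None
    year: int | None = None

    def __str__(self) -> str:
        where = " ".join(
            str(x) for x in (self.stratum, self.year) if x is not None
        )
        return f"{self.field}{' [' + where + ']' if where else ''}: {self.message}"


def validate_inputs(
    hazards: HazardTable,
    baseline: BaselinePrevalence,
    population: PopulationTrajectory,
    trends: Mapping[tuple[Factor, Stratum], TrendSeries],
    years: Iterable[int] | None = None,
) -> list[Violation]:
    """Check every structural invariant of the inputs; report, don't throw.

    Returns an empty list iff all invariants hold: all 12 strata covered
    by hazards and baseline, every (year, stratum) population present and
    non-negative, every trend year present with values in [0, 1], rates
    non-negative and RRs >= 1.
    """
    out: list[Violation] = []
    year_list = sorted({y for (y, _s) in population}) if years is None else sorted(years)

    for s in ALL_STRATA:
        for name, table in (
            ("incidence", hazards.incidence),
            ("case_fatality", hazards.case_fatality),
            ("total_mortality", hazards.total_mortality),
        ):
            if s not in table:
                out.append(Violation(name, "missing stratum", stratum=s))
            elif table[s] < 0:
                out.append(
                    Violation(name, f"negative rate {table[s]}", stratum=s)
                )
        if s not in baseline:
            out.append(Violation("baseline", "missing stratum", stratum=s))
        elif not 0.0 <= baseline[s] <= 1.0:
            out.append(
                Violation("baseline", f"prevalence {baseline[s]} outside [0, 1]", stratum=s)
            )

    for sex in SEXES:
        for name, table in (("rr_obese", hazards.rr_obese), ("rr_smoker", hazards.rr_smoker)):
            if sex not in table:
                out.append(Violation(name, f"missing sex {sex}"))
            elif table[sex] < 1.0:
                out.append(Violation(name, f"RR {table[sex]} below 1 for {sex}"))

    for y in year_list:
        for s in ALL_STRATA:
            if (y, s) not in population:
                out.append(Violation("population", "missing entry", stratum=s, year=y))
            elif population[(y, s)] < 0:
                out.append(
                    Violation(
                        "population",
                        f"negative count {population[(y, s)]}",
                        stratum=s,
                        year=y,
                    )
                )

    for (factor, s), series in trends.items():
        for y in year_list:
            if y not in series.values:
                out.append(
                    Violation(f"{factor}_trend", "missing year", stratum=s, year=y)
                )
            elif not 0.0 <= series.values[y] <= 1.0:
                out.append(
                    Violation(
                        f"{factor}_trend",
                        f"value {series.values[y]} outside [0, 1]",
                        stratum=s,
                        year=y,
                    )
                )
    for factor in ("obesity", "smoking"):
        for s in ALL_STRATA:
            if (factor, s) not in trends:
                out.append(Violation(f"{factor}_trend", "missing stratum", stratum=s))
    return out
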