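"""Synthetic input bundles and a microsimulation validation oracle.

No public accession carries the original stratified survey inputs, so
this module generates complete, internally consistent bundles that
emulate their structure: linearly rising risk-factor prevalences sampled
at sparse survey years (three obesity surveys, two smoking surveys), a
growing stratified population, an age-increasing baseline diabetes
prevalence surface, and a literature-style hazard table.

Default calibration targets the printed anchors of the application
setting (Saudi adults 25+, 1992-2022): male obesity peaking near 34.5%
and female near 58.8% at the 2005 survey, an adult population of roughly
6.5 million in 1992, and a start-year aggregated diabetes prevalence of
8.5%. The bundles are in that regime without claiming to reproduce the
unpublished survey microdata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .engine import RateMode, competing_exit_probabilities
from .inputs import HazardTable, InputBundle, ModelConfig, SurveyPoint
from .partition import Compartments
from .strata import AGE_BANDS, ALL_STRATA, SEXES, Stratum

# Transition hazards per sex and age band, one canonical unit
# (per person per year). Incidence and total mortality are commonly
# printed per 1000 population, case fatality in percent.
_INCIDENCE_PER_1000 = {
    "male": (12.90, 17.70, 18.90, 20.70, 22.40, 26.70),
    "female": (12.90, 15.00, 15.90, 16.70, 19.70, 30.70),
}
_CASE_FATALITY_PCT = {
    "male": (0.15, 0.39, 0.67, 1.20, 1.35, 2.10),
    "female": (0.16, 0.43, 0.62, 0.96, 1.90, 4.62),
}
_TOTAL_MORTALITY_PER_1000 = {
    "male": (0.10, 0.50, 1.10, 2.50, 3.30, 6.10),
    "female": (0.10, 0.50, 1.00, 1.80, 4.10, 11.60),
}
_RR_OBESE = {"male": 6.74, "female": 12.41}
_RR_SMOKER = {"male": 1.44, "female": 1.44}


def reference_hazards() -> HazardTable:
    """The default hazard table (meta-analytic RRs; disease-model rates)."""
    return HazardTable(
        incidence={
            Stratum(sex, band): _INCIDENCE_PER_1000[sex][i] / 1000.0
            for sex in SEXES
            for i, band in enumerate(AGE_BANDS)
        },
        case_fatality={
            Stratum(sex, band): _CASE_FATALITY_PCT[sex][i] / 100.0
            for sex in SEXES
            for i, band in enumerate(AGE_BANDS)
        },
        total_mortality={
            Stratum(sex, band): _TOTAL_MORTALITY_PER_1000[sex][i] / 1000.0
            for sex in SEXES
            for i, band in enumerate(AGE_BANDS)
        },
        rr_obese=dict(_RR_OBESE),
        rr_smoker=dict(_RR_SMOKER),
    )


class GeneratorParams(BaseModel):
    """Parameters of the synthetic bundle generator.

    Risk-factor prevalence for (factor, sex, band, year) follows the line
    ``(start + slope * (year - start_year)) * age_mult[band]``; survey
    points sample it at the survey years with truncated-normal jitter of
    scale ``noise_sd`` on the prevalence scale. The baseline diabetes
    surface is an age profile rescaled (if ``target_start_prevalence`` is
    set) so the population-weighted start-year prevalence hits the target
    exactly. Population grows exponentially at ``pop_growth_rate`` per
    year from a fixed 1992-style age pyramid.
    """

    start_year: int = 1992
    end_year: int = 2022
    obesity_start: dict[str, float] = Field(
        default_factory=lambda: {"male": 0.17, "female": 0.25}
    )
    obesity_slope: dict[str, float] = Field(
        default_factory=lambda: {"male": 0.008, "female": 0.016}
    )
    smoking_start: dict[str, float] = Field(
        default_factory=lambda: {"male": 0.21, "female": 0.05}
    )
    smoking_slope: dict[str, float] = Field(
        default_factory=lambda: {"male": 0.003, "female": 0.0015}
    )
    obesity_age_mult: dict[str, tuple[float, ...]] = Field(
        default_factory=lambda: {
            "male": (0.75, 1.26, 1.15, 1.05, 0.90, 0.70),
            "female": (0.65, 1.05, 1.284, 1.20, 1.00, 0.80),
        }
    )
    smoking_age_mult: dict[str, tuple[float, ...]] = Field(
        default_factory=lambda: {
            "male": (1.10, 1.15, 1.00, 0.85, 0.60, 0.40),
            "female": (0.90, 1.00, 1.10, 1.00, 0.80, 0.50),
        }
    )
    obesity_survey_years: tuple[int, ...] = (1992, 1997, 2005)
    smoking_survey_years: tuple[int, ...] = (1992, 2005)
    baseline_age_profile: tuple[float, ...] = (0.025, 0.06, 0.11, 0.16, 0.19, 0.20)
    target_start_prevalence: float | None = 0.085
    pop_start_total: float = 6.5e6
    pop_band_shares: tuple[float, ...] = (0.38, 0.26, 0.17, 0.10, 0.06, 0.03)
    pop_male_share: float = 0.5
    pop_growth_rate: float = 0.032
    noise_sd: float = 0.005
    random_seed: int = 0

    def line_value(self, factor: str, sex: str, band: str, year: int) -> float:
        start = (self.obesity_start if factor == "obesity" else self.smoking_start)[sex]
        slope = (self.obesity_slope if factor == "obesity" else self.smoking_slope)[sex]
        mult = (
            self.obesity_age_mult if factor == "obesity" else self.smoking_age_mult
        )[sex][AGE_BANDS.index(band)]
        return (start + slope * (year - self.start_year)) * mult


def _jitter(rng: np.random.Generator, value: float, sd: float) -> float:
    if sd <= 0.0:
        return value
    a, b = (0.0 - value) / sd, (1.0 - value) / sd
    return float(stats.truncnorm.rvs(a, b, loc=value, scale=sd, random_state=rng))


def generate_bundle(
    params: GeneratorParams | None = None, **config_overrides
) -> InputBundle:
    """Generate a complete input bundle; deterministic given the seed.

    ``config_overrides`` are forwarded to :class:`ModelConfig` (e.g.
    ``aging_mode="band_shift"``). Raises if a configured line leaves
    [0, 1] at a survey year before jitter truncation.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.random_seed)
    config = ModelConfig(
        start_year=params.start_year,
        end_year=params.end_year,
        random_seed=params.random_seed,
        **config_overrides,
    )

    points: dict[str, list[SurveyPoint]] = {"obesity": [], "smoking": []}
    for factor, years in (
        ("obesity", params.obesity_survey_years),
        ("smoking", params.smoking_survey_years),
    ):
        for stratum in ALL_STRATA:
            for year in years:
                value = params.line_value(factor, stratum.sex, stratum.age_band, year)
                if not 0.0 <= value <= 1.0:
                    raise ValueError(
                        f"configured {factor} line for {stratum} leaves [0, 1] "
                        f"at survey year {year}: {value}"
                    )
                points[factor].append(
                    SurveyPoint(
                        stratum=stratum,
                        year=year,
                        prevalence=_jitter(rng, value, params.noise_sd),
                        factor=factor,  # type: ignore[arg-type]
                    )
                )

    population = {
        (year, Stratum(sex, band)): (
            params.pop_start_total
            * params.pop_band_shares[AGE_BANDS.index(band)]
            * (params.pop_male_share if sex == "male" else 1.0 - params.pop_male_share)
            * (1.0 + params.pop_growth_rate) ** (year - params.start_year)
        )
        for year in config.years()
        for sex in SEXES
        for band in AGE_BANDS
    }

    profile = {
        Stratum(sex, band): params.baseline_age_profile[AGE_BANDS.index(band)]
        for sex in SEXES
        for band in AGE_BANDS
    }
    if params.target_start_prevalence is not None:
        y0 = params.start_year
        weighted = sum(
            profile[s] * population[(y0, s)] for s in ALL_STRATA
        ) / sum(population[(y0, s)] for s in ALL_STRATA)
        scale = params.target_start_prevalence / weighted
        baseline = {s: min(1.0, v * scale) for s, v in profile.items()}
    else:
        baseline = dict(profile)

    return InputBundle(
        config=config,
        population=population,
        obesity_points=points["obesity"],
        smoking_points=points["smoking"],
        baseline=baseline,
        hazards=reference_hazards(),
    )


@dataclass
class MicrosimTrajectory:
    """Stochastic cohort trajectory with Monte-Carlo standard errors."""

    counts: pd.DataFrame  # one row per year, columns per compartment
    stderr: pd.DataFrame  # plug-in binomial SE per compartment per year
    n_individuals: int


_COMPARTMENTS = ("healthy", "obese", "smokers", "diabetes", "dead_other", "dead_diabetes")


def microsim_oracle(
    initial: Compartments,
    case_fatality: float,
    total_mortality: float,
    rr_obese: float,
    rr_smoker: float,
    incidence_healthy: float,
    n_individuals: int,
    years: int,
    seed: int,
    mode: RateMode = "exponential",
) -> MicrosimTrajectory:
    """Stochastic individual-level counterpart of the compartment cycle.

    ``n_individuals`` persons are allocated to the living compartments in
    proportion to ``initial`` and transitioned each cycle with the same
    per-cycle competing-exit probabilities as the deterministic engine,
    drawn as per-compartment multinomials (equivalent to independent
    Bernoulli draws per individual). Returns counts per year and plug-in
    binomial standard errors sqrt(n p(1-p)).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)

    living = initial.living
    if living <= 0:
        raise ValueError("initial population must be positive")
    fractions = np.array(
        [initial.healthy, initial.obese, initial.smokers, initial.diabetes]
    ) / living
    # Largest-remainder rounding so the counts sum exactly to n.
    raw = fractions * n_individuals
    counts_living = np.floor(raw).astype(int)
    remainder = n_individuals - counts_living.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    counts_living[order[:remainder]] += 1

    m = total_mortality
    # (p_to_diabetes, p_to_dead_other) per living state; diabetics split
    # between disease-specific and other-cause death.
    probs = {
        0: competing_exit_probabilities((incidence_healthy, m), mode),
        1: competing_exit_probabilities((incidence_healthy * rr_obese, m), mode),
        2: competing_exit_probabilities((incidence_healthy * rr_smoker, m), mode),
        3: competing_exit_probabilities((case_fatality, m), mode),
    }

    state = np.zeros(6, dtype=np.int64)
    state[:4] = counts_living
    rows = [state.copy()]
    for _ in range(years):
        nxt = state.copy()
        for code in (0, 1, 2):
            p_dia, p_dead = probs[code]
            moved = rng.multinomial(state[code], [p_dia, p_dead, 1 - p_dia - p_dead])
            nxt[code] -= moved[0] + moved[1]
            nxt[3] += moved[0]
            nxt[4] += moved[1]
        p_df, p_dm = probs[3]
        moved = rng.multinomial(state[3], [p_df, p_dm, 1 - p_df - p_dm])
        nxt[3] -= moved[0] + moved[1]
        nxt[5] += moved[0]
        nxt[4] += moved[1]
        state = nxt
        rows.append(state.copy())

    counts = pd.DataFrame(rows, columns=_COMPARTMENTS)
    counts.insert(0, "year", range(years + 1))
    p_hat = counts[list(_COMPARTMENTS)] / n_individuals
    stderr = np.sqrt(n_individuals * p_hat * (1.0 - p_hat))
    stderr.insert(0, "year", counts["year"])
    return MicrosimTrajectory(
        counts=counts, stderr=stderr, n_individuals=n_individuals
    )
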