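"""Uncertainty via analysis of extremes and capped/uncapped scenarios.

The analysis of extremes runs the model three times: at base values, and
with every epidemiological parameter (baseline prevalence, survey
risk-factor prevalences, incidence, case fatality, total mortality, and
relative risks — but not the population structure) scaled coherently by
(1 - factor) and (1 + factor). Scaled proportions are clamped to [0, 1]
and scaled RRs floored at 1. The per-year (low, base, high) aggregated
prevalences form the uncertainty band.

The scenario analysis contrasts uncapped linear obesity trends with
trends capped at the per-sex capping points (the highest observed
prevalence); smoking is never capped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .engine import RunResult, run_bundle
from .inputs import InputBundle, SurveyPoint


def _scaled_bundle(bundle: InputBundle, factor: float) -> InputBundle:
    """Bundle with every epidemiological parameter multiplied by ``factor``."""

    def scale_points(points: list[SurveyPoint]) -> list[SurveyPoint]:
        return [
            replace(p, prevalence=min(1.0, max(0.0, p.prevalence * factor)))
            for p in points
        ]

    return InputBundle(
        config=bundle.config,
        population=bundle.population,  # population structure is never scaled
        obesity_points=scale_points(bundle.obesity_points),
        smoking_points=scale_points(bundle.smoking_points),
        baseline={
            s: min(1.0, max(0.0, v * factor)) for s, v in bundle.baseline.items()
        },
        hazards=bundle.hazards.scaled(factor),
    )


@dataclass
class UncertaintyBand:
    """Per-year (low, base, high) aggregated prevalence band."""

    table: pd.DataFrame  # columns: year, low, base, high
    runs: dict[str, RunResult]

    def at(self, year: int) -> tuple[float, float, float]:
        row = self.table.loc[self.table.year == year]
        if row.empty:
            raise KeyError(f"year {year} outside the band")
        r = row.iloc[0]
        return float(r.low), float(r.base), float(r.high)


def analysis_of_extremes(
    bundle: InputBundle, factor: float | None = None
) -> UncertaintyBand:
    """Three full model runs at base and ±``factor`` extreme parameter sets.

    ``factor`` defaults to the bundle config's ``extremes_factor``. The
    low and high runs scale all parameters coherently in the same
    direction; no mixed-direction search for true extrema is attempted.
    """
    if factor is None:
        factor = bundle.config.extremes_factor
    if not 0.0 <= factor < 1.0:
        raise ValueError(f"extremes factor must be in [0, 1), got {factor}")

    runs = {
        "base": run_bundle(bundle),
        "low": run_bundle(_scaled_bundle(bundle, 1.0 - factor)),
        "high": run_bundle(_scaled_bundle(bundle, 1.0 + factor)),
    }
    cols = {
        name: res.prevalence("total").set_index("year")["prevalence"]
        for name, res in runs.items()
    }
    table = pd.DataFrame(
        {"low": cols["low"], "base": cols["base"], "high": cols["high"]}
    ).reset_index()
    return UncertaintyBand(table=table, runs=runs)


@dataclass
class ScenarioComparison:
    """Paired uncapped (scenario 1) / capped (scenario 2) runs."""

    uncapped: RunResult
    capped: RunResult
    table: pd.DataFrame  # columns: year, scenario1, scenario2, difference


def run_scenarios(bundle: InputBundle) -> ScenarioComparison:
    """Run the uncapped and capped obesity scenarios on shared inputs.

    The difference column is scenario1 - scenario2 aggregated prevalence;
    it is zero until the cap binds and non-negative afterwards.
    """
    uncapped = run_bundle(bundle, capped=False)
    capped = run_bundle(bundle, capped=True)
    s1 = uncapped.prevalence("total").set_index("year")["prevalence"]
    s2 = capped.prevalence("total").set_index("year")["prevalence"]
    table = pd.DataFrame(
        {"scenario1": s1, "scenario2": s2, "difference": s1 - s2}
    ).reset_index()
    return ScenarioComparison(uncapped=uncapped, capped=capped, table=table)
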