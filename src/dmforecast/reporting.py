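"""Comparison reports against published external prevalence estimates.

External model estimates (IDF Diabetes Atlas, GBD study, and four older
modelling studies) are shipped as a static packaged table; the report is
a presentation join of those rows against the projection output. Nothing
is recomputed here — every model number traces to the RunResult and every
reference number to the packaged table.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Literal

import pandas as pd

from .engine import RunResult


def format_percent(value: float) -> float:
    """Proportion -> percent with half-up rounding to 1 decimal place."""
    return float(
        Decimal(str(value * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def load_reference_estimates() -> pd.DataFrame:
    """Packaged external estimates: columns source, year, group,
    prevalence_pct."""
    with resources.files("dmforecast.data").joinpath(
        "reference_estimates.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    bad = df[(df.prevalence_pct <= 0) | (df.prevalence_pct >= 100)]
    if not bad.empty or df.source.isna().any() or (df.source == "").any():
        raise ValueError("invalid packaged reference estimates")
    return df


def comparison_report(
    result: RunResult,
    refs: pd.DataFrame | None,
    years: Iterable[int],
    grouping: Literal["total", "sex"] = "total",
) -> pd.DataFrame:
    """Side-by-side table of model vs reference prevalence estimates (%).

    One row per (year, group); the model column is formatted to one
    decimal percent, reference sources become one column each. Years must
    lie inside the run range.
    """
    years = sorted(int(y) for y in years)
    if refs is None:
        refs = pd.DataFrame(columns=["source", "year", "group", "prevalence_pct"])

    if grouping == "total":
        prev = result.prevalence("total").assign(group="total")
    else:
        prev = result.prevalence("sex").rename(columns={"sex": "group"})
    run_years = set(prev.year)
    outside = [y for y in years if y not in run_years]
    if outside:
        raise ValueError(f"years {outside} outside the run range")

    rows = prev[prev.year.isin(years)].copy()
    rows["model_pct"] = rows["prevalence"].map(format_percent)
    table = rows[["year", "group", "model_pct"]].reset_index(drop=True)

    matching = refs[refs.group.isin(set(table.group))]
    if not matching.empty:
        wide = matching.pivot_table(
            index=["year", "group"], columns="source",
            values="prevalence_pct", sort=False,
        ).reset_index()
        wide.columns.name = None
        table = table.merge(wide, on=["year", "group"], how="left")
    return table
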