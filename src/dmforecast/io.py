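"""On-disk bundle format: one long CSV of tables plus a YAML config.

``inputs.csv`` columns: year, sex, age_band, measure, value. Measures:

* ``population`` — person counts, every model year;
* ``obesity_prev`` / ``smoking_prev`` — survey points at survey years;
* ``diabetes_prev`` — baseline prevalence, start year only;
* ``incidence`` / ``case_fatality`` / ``total_mortality`` — annual
  hazards per person per year, time-invariant (year left empty).

``config.yaml`` holds the scalar run settings keyed exactly as
:class:`~dmforecast.inputs.ModelConfig` fields, plus a
``relative_risks`` section with the per-sex RRs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .inputs import HazardTable, InputBundle, ModelConfig, SurveyPoint
from .strata import ALL_STRATA, SEXES, Stratum, validate_stratum

_HAZARD_MEASURES = ("incidence", "case_fatality", "total_mortality")


def write_bundle(bundle: InputBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for (year, s), count in sorted(bundle.population.items()):
        rows.append(
            {"year": year, "sex": s.sex, "age_band": s.age_band,
             "measure": "population", "value": count}
        )
    for pts, measure in (
        (bundle.obesity_points, "obesity_prev"),
        (bundle.smoking_points, "smoking_prev"),
    ):
        for p in pts:
            rows.append(
                {"year": p.year, "sex": p.stratum.sex,
                 "age_band": p.stratum.age_band, "measure": measure,
                 "value": p.prevalence}
            )
    for s in ALL_STRATA:
        rows.append(
            {"year": bundle.config.start_year, "sex": s.sex,
             "age_band": s.age_band, "measure": "diabetes_prev",
             "value": bundle.baseline[s]}
        )
    for measure, table in zip(
        _HAZARD_MEASURES,
        (bundle.hazards.incidence, bundle.hazards.case_fatality,
         bundle.hazards.total_mortality),
    ):
        for s in ALL_STRATA:
            rows.append(
                {"year": "", "sex": s.sex, "age_band": s.age_band,
                 "measure": measure, "value": table[s]}
            )
    pd.DataFrame(rows).to_csv(directory / "inputs.csv", index=False)

    config = bundle.config.model_dump()
    config["relative_risks"] = {
        "rr_obese": dict(bundle.hazards.rr_obese),
        "rr_smoker": dict(bundle.hazards.rr_smoker),
    }
    (directory / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))


def read_bundle(directory: str | Path) -> InputBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    directory = Path(directory)
    raw = yaml.safe_load((directory / "config.yaml").read_text())
    rrs = raw.pop("relative_risks")
    config = ModelConfig(**raw)

    df = pd.read_csv(directory / "inputs.csv", float_precision="round_trip")
    missing = {"year", "sex", "age_band", "measure", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"inputs.csv missing columns {sorted(missing)}")

    population: dict[tuple[int, Stratum], float] = {}
    points: dict[str, list[SurveyPoint]] = {"obesity": [], "smoking": []}
    baseline: dict[Stratum, float] = {}
    hazard_cols: dict[str, dict[Stratum, float]] = {m: {} for m in _HAZARD_MEASURES}

    for row in df.itertuples(index=False):
        stratum = validate_stratum(row.sex, row.age_band)
        measure = row.measure
        if measure == "population":
            population[(int(row.year), stratum)] = float(row.value)
        elif measure in ("obesity_prev", "smoking_prev"):
            factor = "obesity" if measure == "obesity_prev" else "smoking"
            points[factor].append(
                SurveyPoint(stratum=stratum, year=int(row.year),
                            prevalence=float(row.value), factor=factor)  # type: ignore[arg-type]
            )
        elif measure == "diabetes_prev":
            baseline[stratum] = float(row.value)
        elif measure in _HAZARD_MEASURES:
            hazard_cols[measure][stratum] = float(row.value)
        else:
            raise ValueError(f"unknown measure {measure!r} in inputs.csv")

    hazards = HazardTable(
        incidence=hazard_cols["incidence"],
        case_fatality=hazard_cols["case_fatality"],
        total_mortality=hazard_cols["total_mortality"],
        rr_obese={sex: float(rrs["rr_obese"][sex]) for sex in SEXES},
        rr_smoker={sex: float(rrs["rr_smoker"][sex]) for sex in SEXES},
    )
    return InputBundle(
        config=config,
        population=population,
        obesity_points=points["obesity"],
        smoking_points=points["smoking"],
        baseline=baseline,
        hazards=hazards,
    )
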