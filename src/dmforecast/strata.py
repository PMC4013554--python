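"""Sex × age-band stratification of the adult (25+) population.

The model is stratified into 12 cells: two sexes crossed with six
ten-year age bands (the last band is open-ended, 75+). Age-band labels
are fixed strings and used verbatim in every file format.
"""

from __future__ import annotations

from typing import NamedTuple

SEXES: tuple[str, ...] = ("male", "female")

AGE_BANDS: tuple[str, ...] = ("25-34", "35-44", "45-54", "55-64", "65-74", "75+")

#: Nominal width (years) of each band; the open-ended 75+ band is treated
#: as 15 years wide for cohort-aging bookkeeping.
BAND_WIDTHS: dict[str, int] = {
    "25-34": 10,
    "35-44": 10,
    "45-54": 10,
    "55-64": 10,
    "65-74": 10,
    "75+": 15,
}


class Stratum(NamedTuple):
    """One sex × age-band cell."""

    sex: str
    age_band: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.sex} {self.age_band}"


#: All 12 strata in fixed iteration order (men first, then women,
#: youngest to oldest). Every loop in the package iterates in this order
#: so that runs are bit-reproducible.
ALL_STRATA: tuple[Stratum, ...] = tuple(
    Stratum(sex, band) for sex in SEXES for band in AGE_BANDS
)


def validate_stratum(sex: str, age_band: str) -> Stratum:
    """Return the canonical :class:`Stratum`, raising ``ValueError`` on
    unknown labels."""
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    if age_band not in AGE_BANDS:
        raise ValueError(
            f"unknown age band {age_band!r}; expected one of {AGE_BANDS}"
        )
    return Stratum(sex, age_band)
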