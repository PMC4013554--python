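"""Build an annual obesity trend from three sparse survey points.

Surveys measure prevalence only in a few years; the model needs a value
for every year. Interior years are linearly interpolated and future
years extrapolated with the overall observed slope (first-to-last
chord), clamped to [0, 1].
"""

from dmforecast import Stratum, SurveyPoint, apply_cap, build_trend

stratum = Stratum("female", "45-54")
points = [
    SurveyPoint(stratum=stratum, year=1992, prevalence=0.32, factor="obesity"),
    SurveyPoint(stratum=stratum, year=1997, prevalence=0.41, factor="obesity"),
    SurveyPoint(stratum=stratum, year=2005, prevalence=0.588, factor="obesity"),
]
series = build_trend(points, range(1992, 2023))
capped = apply_cap(series, 0.60)

print("year  uncapped  capped(0.60)")
for year in (1992, 1997, 2000, 2005, 2010, 2022):
    print(f"{year}  {series[year]:.3f}     {capped[year]:.3f}")

# The uncapped series keeps rising at the 1992-2005 chord slope
# ((0.588-0.32)/13 per year) and would exceed the highest observed
# value; the capped series levels off at 60% from the year the cap
# first binds.
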