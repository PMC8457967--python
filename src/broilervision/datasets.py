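"""Bundled example data: winter rearing-trial period means.

Per-period mean ammonia concentration (ppm) and temperature-humidity
index recorded in a floor-rearing broiler chamber over eight winter days
(2019-12-22 .. 2020-01-03), three one-hour analysis periods per day
(06:00, 12:00, 18:00 starts).  These 24 paired means are the standard
worked example for the correlation stage: THI against ammonia gives a
clearly positive Kendall association.
"""

from __future__ import annotations

from .envstats import PeriodSummary, period_label

__all__ = ["load_trial_period_means"]

_DATES = ("2019-12-22", "2019-12-23", "2019-12-24", "2019-12-25",
          "2019-12-26", "2019-12-29", "2020-01-02", "2020-01-03")

# rows: period start hour 6, 12, 18; columns: the eight dates
_NH3_PPM = {
    6:  (50.00, 25.23, 33.47, 44.92, 38.44, 24.36, 19.88, 23.34),
    12: (29.40, 26.98, 21.75, 35.63, 30.46, 22.55, 15.60, 9.14),
    18: (23.55, 31.26, 21.93, 44.07, 46.62, 32.15, 26.81, 26.55),
}
_THI = {
    6:  (61.45, 52.59, 56.34, 60.97, 57.33, 55.48, 53.13, 55.95),
    12: (58.48, 57.33, 55.04, 58.91, 54.99, 59.32, 54.48, 51.25),
    18: (58.10, 57.03, 54.98, 61.02, 55.97, 57.88, 56.43, 56.84),
}


def load_trial_period_means() -> list[PeriodSummary]:
    """The 24 (date, period) summaries of the winter trial, in date order."""
    out = []
    for d, date in enumerate(_DATES):
        for hour in (6, 12, 18):
            out.append(PeriodSummary(
                date=date,
                period=period_label(hour),
                mean_nh3=_NH3_PPM[hour][d],
                thi=_THI[hour][d],
            ))
    return out
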