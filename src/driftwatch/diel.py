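"""Solar day/night geometry and diel summaries.

Sunrise and sunset are computed with the NOAA solar-calculator algorithm:
Julian-century ephemeris for the sun's geometric mean longitude and anomaly,
equation of centre, apparent longitude, obliquity with nutation correction,
then equation of time and declination, and finally the hour angle at a
zenith of 90.833° (geometric horizon plus standard atmospheric refraction
and the solar disc radius — the conventional "official" sunrise). A
civil-twilight boundary (zenith 96°) is available as an alternative
day/night definition.

The study site sits at 49.58° N where spring days lengthen monotonically and
the sun rises and sets every day, so no polar-day handling is needed; the
functions refuse latitudes inside the polar circles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from driftwatch.errors import InvalidParameterError

#: default study-site coordinates (decimal degrees)
SITE_LATITUDE = 49.578497
SITE_LONGITUDE = 15.251671

ZENITH_OFFICIAL = 90.833
ZENITH_CIVIL = 96.0


@dataclass(frozen=True)
class DielWindow:
    """Sunrise/sunset instants (UTC) bounding daylight on one calendar date."""

    date: Date
    sunrise: pd.Timestamp
    sunset: pd.Timestamp
    latitude: float
    longitude: float


_DEG = math.pi / 180.0


def _sun_ephemeris(julian_centuries: float) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes)."""
    T = julian_centuries
    mean_long = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    mean_anom = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    ecc = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    m = mean_anom * _DEG
    centre = (
        math.sin(m) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + math.sin(2 * m) * (0.019993 - 0.000101 * T)
        + math.sin(3 * m) * 0.000289
    )
    omega = (125.04 - 1934.136 * T) * _DEG
    apparent_long = (mean_long + centre - 0.00569 - 0.00478 * math.sin(omega)) * _DEG
    obliq0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    obliq = (obliq0 + 0.00256 * math.cos(omega)) * _DEG
    decl = math.asin(math.sin(obliq) * math.sin(apparent_long))
    var_y = math.tan(obliq / 2.0) ** 2
    l0 = mean_long * _DEG
    eqtime = 4.0 / _DEG * (
        var_y * math.sin(2 * l0)
        - 2 * ecc * math.sin(m)
        + 4 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y**2 * math.sin(4 * l0)
        - 1.25 * ecc**2 * math.sin(2 * m)
    )
    return decl, eqtime


def _event_minutes(
    day: Date, latitude: float, longitude: float, zenith: float, rising: bool
) -> float:
    """Minutes after 00:00 UTC of sunrise/sunset, iteratively refined."""
    # Julian day at 00:00 UTC via the Unix epoch (JD 2440587.5)
    jd0 = pd.Timestamp(day).value / 86400e9 + 2440587.5
    lat = math.radians(latitude)
    minutes = 720.0  # start the refinement from civil noon
    for _ in range(3):
        T = (jd0 + minutes / 1440.0 - 2451545.0) / 36525.0
        decl, eqtime = _sun_ephemeris(T)
        cos_ha = math.cos(math.radians(zenith)) / (math.cos(lat) * math.cos(decl)) - math.tan(
            lat
        ) * math.tan(decl)
        if not -1.0 <= cos_ha <= 1.0:
            raise InvalidParameterError(
                f"sun does not cross zenith {zenith}° at latitude {latitude} on {day}"
            )
        ha = math.degrees(math.acos(cos_ha))
        if not rising:
            ha = -ha
        minutes = 720.0 - 4.0 * (longitude + ha) - eqtime
    return minutes


def solar_times(
    day: Date | pd.Timestamp,
    latitude: float = SITE_LATITUDE,
    longitude: float = SITE_LONGITUDE,
    zenith: float = ZENITH_OFFICIAL,
) -> DielWindow:
    """Sunrise and sunset (UTC) on ``day`` at the given coordinates.

    Raises
    ------
    InvalidParameterError
        For latitudes poleward of 66° (polar day/night is out of scope) or
        when the sun never crosses the requested zenith on that date.
    """
    if abs(latitude) >= 66.0:
        raise InvalidParameterError(
            f"latitudes within the polar circles are unsupported (got {latitude})"
        )
    day = pd.Timestamp(day).date()
    base = pd.Timestamp(day, tz="UTC")
    rise = base + pd.Timedelta(minutes=_event_minutes(day, latitude, longitude, zenith, True))
    sett = base + pd.Timedelta(minutes=_event_minutes(day, latitude, longitude, zenith, False))
    return DielWindow(day, rise, sett, latitude, longitude)


def day_fraction(
    bins: pd.DatetimeIndex,
    bin_width: pd.Timedelta = pd.Timedelta(hours=1),
    latitude: float = SITE_LATITUDE,
    longitude: float = SITE_LONGITUDE,
    zenith: float = ZENITH_OFFICIAL,
) -> pd.Series:
    """Fraction of each bin falling between sunrise and sunset.

    A bin fully inside daylight scores 1, a night bin 0, and a bin containing
    sunrise or sunset the exact covered fraction, so day + night fractions
    always sum to one. Bins are assumed not to straddle UTC midnight (the
    hourly grid is aligned to whole hours).
    """
    width_ns = bin_width.value
    out = np.zeros(len(bins))
    windows: dict[Date, DielWindow] = {}
    for i, b in enumerate(bins):
        d = b.date()
        if d not in windows:
            windows[d] = solar_times(d, latitude, longitude, zenith)
        w = windows[d]
        lo = max(b.value, w.sunrise.value)
        hi = min(b.value + width_ns, w.sunset.value)
        out[i] = max(hi - lo, 0) / width_ns
    return pd.Series(out, index=bins, name="day_fraction")


def label_bins(day_frac: pd.Series) -> pd.Series:
    """Binary period label per bin: 1 = night, 0 = day, by majority fraction.

    Fractional weights (``day_frac``) should be preferred for share
    computations; the binary label is the model covariate.
    """
    return (day_frac < 0.5).astype(int).rename("period_night")


def diel_profile(values: pd.Series) -> pd.Series:
    """Mean of an hourly-binned series by UTC hour of day (24 values).

    ``values`` must be indexed by bin-start timestamps on the hourly grid.
    Hours never observed yield NaN rather than silently 0.
    """
    prof = values.groupby(values.index.hour).mean()
    return prof.reindex(range(24)).rename_axis("hour_utc")
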