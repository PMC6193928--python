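"""Independent sunrise/sunset oracle: the NOAA solar-calculator spreadsheet
formulation (Julian-century ephemeris), implemented separately from the
package's fractional-year Fourier formulation so the two can cross-check."""

import math

import pandas as pd


def _julian_day(ts: pd.Timestamp) -> float:
    y, m, d = ts.year, ts.month, ts.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    frac = (ts.hour + ts.minute / 60 + ts.second / 3600) / 24
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5 + frac


def sunrise_sunset_utc(day, latitude: float, longitude: float, zenith: float = 90.833):
    """(sunrise, sunset) as UTC Timestamps via the spreadsheet recipe."""

    def solar_quantities(t_frac_of_day: float):
        jd = _julian_day(pd.Timestamp(day)) + t_frac_of_day
        T = (jd - 2451545.0) / 36525.0
        L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360
        M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
        e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
        Mr = math.radians(M)
        C = (
            math.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
            + math.sin(2 * Mr) * (0.019993 - 0.000101 * T)
            + math.sin(3 * Mr) * 0.000289
        )
        true_long = L0 + C
        omega = 125.04 - 1934.136 * T
        app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
        eps0 = 23 + (26 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60) / 60
        eps = eps0 + 0.00256 * math.cos(math.radians(omega))
        decl = math.degrees(
            math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long)))
        )
        y = math.tan(math.radians(eps / 2)) ** 2
        L0r = math.radians(L0)
        eqtime = 4 * math.degrees(
            y * math.sin(2 * L0r)
            - 2 * e * math.sin(Mr)
            + 4 * e * y * math.sin(Mr) * math.cos(2 * L0r)
            - 0.5 * y * y * math.sin(4 * L0r)
            - 1.25 * e * e * math.sin(2 * Mr)
        )
        return decl, eqtime

    lat = math.radians(latitude)

    def event(rising: bool) -> pd.Timestamp:
        minutes = 720.0
        for _ in range(3):
            decl, eqtime = solar_quantities(minutes / 1440.0)
            dr = math.radians(decl)
            cos_ha = math.cos(math.radians(zenith)) / (math.cos(lat) * math.cos(dr)) - math.tan(
                lat
            ) * math.tan(dr)
            ha = math.degrees(math.acos(max(-1.0, min(1.0, cos_ha))))
            if not rising:
                ha = -ha
            minutes = 720.0 - 4.0 * (longitude + ha) - eqtime
        base = pd.Timestamp(pd.Timestamp(day).date(), tz="UTC")
        return base + pd.Timedelta(minutes=minutes)

    return event(True), event(False)
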