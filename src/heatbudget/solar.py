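"""Solar geometry: elevation angle from timestamp and site coordinates.

Implements the standard NOAA low-precision algorithm (fractional-year
Fourier series for declination and the equation of time), accurate to a
few tenths of a degree — ample for partitioning irradiance into beam and
diffuse components on a human energy budget.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["solar_elevation_deg", "SOLAR_CONSTANT_WM2"]

SOLAR_CONSTANT_WM2 = 1361.0


def solar_elevation_deg(timestamps, latitude_deg: float, longitude_deg: float):
    """Solar elevation angle(s) in degrees above the horizon.

    ``timestamps`` — a Timestamp, a DatetimeIndex or anything
    ``pd.to_datetime`` accepts; naive values are interpreted as UTC.
    Negative results mean the sun is below the horizon.
    """
    ts = pd.to_datetime(timestamps)
    scalar = isinstance(ts, pd.Timestamp)
    idx = pd.DatetimeIndex([ts]) if scalar else pd.DatetimeIndex(ts)
    if idx.tz is not None:
        idx = idx.tz_convert("UTC").tz_localize(None)

    doy = idx.dayofyear.to_numpy(dtype=float)
    hour_utc = (
        idx.hour.to_numpy(dtype=float)
        + idx.minute.to_numpy(dtype=float) / 60.0
        + idx.second.to_numpy(dtype=float) / 3600.0
    )

    # fractional year, radians (NOAA)
    g = 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour_utc - 12.0) / 24.0)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    # equation of time, minutes
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )

    time_offset = eqtime + 4.0 * longitude_deg  # minutes
    tst = hour_utc * 60.0 + time_offset  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle

    lat = np.deg2rad(latitude_deg)
    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    elev = np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))
    return float(elev[0]) if scalar else elev
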