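"""Closed-form heat-stress indices.

* ``heat_index`` — the NWS apparent-temperature procedure: the simple
  averaged formula for mild conditions, switching to the full Rothfusz
  regression (with the low-/high-humidity adjustments) when the
  preliminary estimate reaches 80 °F.  Fahrenheit-native internally;
  the public surface is Celsius.
* ``wet_bulb_stull`` — Stull's empirical natural wet-bulb temperature
  from air temperature and relative humidity.
* ``wbgt`` — wet bulb globe temperature, the ISO 7243 outdoor weighting
  0.7·Tw + 0.2·Tg + 0.1·Ta.

All functions accept scalars or numpy arrays and return the same shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .micromet import MicrometRecord

__all__ = [
    "IndexValue",
    "heat_index",
    "wet_bulb_stull",
    "wbgt",
    "wbgt_from_weather",
    "c_to_f",
    "f_to_c",
]

# Rothfusz regression coefficients (°F, %RH)
_ROTHFUSZ = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)


@dataclass(frozen=True)
class IndexValue:
    """A computed index value with an echo of its inputs."""

    value_c: float
    method: str  # "HI" or "WBGT"
    inputs_echo: dict


def c_to_f(t):
    """Celsius to Fahrenheit."""
    return np.multiply(t, 1.8) + 32.0


def f_to_c(t):
    """Fahrenheit to Celsius."""
    return (np.asarray(t, dtype=float) - 32.0) / 1.8 if np.ndim(t) else (t - 32.0) / 1.8


def _rothfusz_f(t_f, rh):
    c0, c1, c2, c3, c4, c5, c6, c7, c8 = _ROTHFUSZ
    return (
        c0
        + c1 * t_f
        + c2 * rh
        + c3 * t_f * rh
        + c4 * t_f * t_f
        + c5 * rh * rh
        + c6 * t_f * t_f * rh
        + c7 * t_f * rh * rh
        + c8 * t_f * t_f * rh * rh
    )


def heat_index(ta_c, rh_pct):
    """NWS heat index, °C in and out.

    Procedure: convert Ta to °F; evaluate the simple formula
    ``0.5·(T + 61 + (T−68)·1.2 + RH·0.094)``.  If the average of that
    result and T is below 80 °F the simple value is the answer.
    Otherwise the full Rothfusz regression applies, with the NWS
    corrections for very dry (RH < 13 %, 80–112 °F) and very humid
    (RH > 85 %, 80–87 °F) conditions.

    Raises ``ValueError`` outside Ta ∈ [−20, 60] °C or RH ∈ [0, 100] %.
    """
    ta = np.asarray(ta_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("rh_pct must lie in [0, 100]")
    if np.any((ta < -20) | (ta > 60)):
        raise ValueError("ta_c must lie in [-20, 60] °C")

    t_f = c_to_f(ta)
    simple = 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2 + rh * 0.094)
    use_full = 0.5 * (simple + t_f) >= 80.0

    full = _rothfusz_f(t_f, rh)
    # low-humidity correction
    low = (rh < 13.0) & (t_f >= 80.0) & (t_f <= 112.0)
    adj_low = ((13.0 - rh) / 4.0) * np.sqrt(
        np.clip(17.0 - np.abs(t_f - 95.0), 0.0, None) / 17.0
    )
    full = np.where(low, full - adj_low, full)
    # high-humidity correction
    high = (rh > 85.0) & (t_f >= 80.0) & (t_f <= 87.0)
    adj_high = ((rh - 85.0) / 10.0) * ((87.0 - t_f) / 5.0)
    full = np.where(high, full + adj_high, full)

    hi_f = np.where(use_full, full, simple)
    hi_c = (hi_f - 32.0) / 1.8
    return float(hi_c) if np.ndim(ta_c) == 0 and np.ndim(rh_pct) == 0 else hi_c


def wet_bulb_stull(ta_c, rh_pct):
    """Stull's empirical natural wet-bulb temperature, °C.

    Valid for RH between roughly 5 % and 99 %; outside that range a
    warning is issued and the formula is still evaluated.  Arctangents
    take dimensionless arguments with RH in percent.
    """
    ta = np.asarray(ta_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 5.0) | (rh > 99.0)):
        warnings.warn(
            "wet_bulb_stull evaluated outside its stated validity RH in [5, 99] %",
            stacklevel=2,
        )
    tw = (
        ta * np.arctan(0.151977 * np.sqrt(rh + 8.313659))
        + np.arctan(ta + rh)
        - np.arctan(rh - 1.676331)
        + 0.00391838 * rh**1.5 * np.arctan(0.023101 * rh)
        - 4.686035
    )
    return float(tw) if np.ndim(ta_c) == 0 and np.ndim(rh_pct) == 0 else tw


def wbgt(tw_c, tg_c, ta_c):
    """Wet bulb globe temperature: 0.7·Tw + 0.2·Tg + 0.1·Ta (°C).

    The outdoor ISO 7243 weighting; the three weights sum to one, so the
    result is a convex combination of its inputs.
    """
    out = (
        0.7 * np.asarray(tw_c, dtype=float)
        + 0.2 * np.asarray(tg_c, dtype=float)
        + 0.1 * np.asarray(ta_c, dtype=float)
    )
    scalar = all(np.ndim(x) == 0 for x in (tw_c, tg_c, ta_c))
    return float(out) if scalar else out


def wbgt_from_weather(rec: MicrometRecord) -> float:
    """WBGT for one observation: Stull wet-bulb from (Ta, RH), measured Tg.

    Requires a black-globe temperature on the record; no globe model is
    substituted here.
    """
    if rec.tg_c is None:
        raise ValueError(
            "record has no black-globe temperature (tg_c); WBGT requires a measured "
            "or simulated globe temperature"
        )
    tw = wet_bulb_stull(rec.ta_c, rec.rh_pct)
    return wbgt(tw, rec.tg_c, rec.ta_c)
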