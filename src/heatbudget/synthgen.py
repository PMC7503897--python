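"""Seeded synthetic micrometeorological series.

Emulates a mid-day field session at an open sports field: clear-sky
solar radiation from site geometry, a diurnal air-temperature wave with
autocorrelated noise, relative humidity anti-correlated with
temperature, lognormal autocorrelated wind, and two empirical closures
for what the instruments would see — a black-globe temperature that
rises above air temperature with radiant load and falls with wind, and
an artificial-turf surface temperature that does the same more
strongly.  Everything is reproducible from an explicit integer seed;
there is no global RNG state.

The bundled session specs (:func:`may_session_spec`,
:func:`october_session_spec`) target the mean conditions of two
documented sessions on a Texas turf field — an early-summer afternoon
(Ta 33.3 °C, RH 48 %, Ws 2.4 m/s, SR 886.8 W/m²) and an early-autumn
one (Ta 34.0 °C, RH 42.9 %, Ws 4.04 m/s, SR 574.3 W/m²).

The globe and turf closures are monotone empirical forms meant as test
scaffolding with plausible magnitudes (midday globe excess of roughly
5–15 °C, turf surfaces tens of degrees above air temperature in calm
sun), not as validated instrument models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .micromet import MicrometSeries
from .solar import SOLAR_CONSTANT_WM2, solar_elevation_deg

__all__ = ["GeneratorSpec", "generate", "may_session_spec", "october_session_spec"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic session.

    Times are UTC instants.  ``clear_sky_transmittance`` is the broadband
    atmospheric transmittance τ_atm in SR = S0·sin β·τ_atm^(1/sin β).
    ``ta_amp`` is the half-amplitude of the full diurnal temperature
    wave; over a short afternoon window only its slowly varying part is
    seen, and the wave is re-centred so the window mean equals
    ``ta_mean``.  Noise scales are standard deviations of the AR(1)
    perturbations (fractional for wind and solar radiation).
    """

    seed: int
    start: str
    end: str
    interval_s: float = 10.0
    latitude_deg: float = 30.63
    longitude_deg: float = -96.33
    ta_mean_c: float = 33.0
    ta_amp_c: float = 4.0
    rh_mean_pct: float = 45.0
    rh_slope_pct_per_c: float = 3.0
    ws_mean_ms: float = 2.5
    clear_sky_transmittance: float = 0.72
    noise_ta_c: float = 0.25
    noise_rh_pct: float = 1.5
    noise_ws_lognorm: float = 0.40
    noise_sr_frac: float = 0.03
    ar1_phi: float = 0.8
    globe_c1: float = 0.02  # °C per W/m²
    globe_c2: float = 0.7  # s/m (wind damping)
    turf_c3: float = 0.035  # °C per absorbed W/m²
    turf_c4: float = 0.5  # s/m (wind damping)
    turf_albedo: float = 0.08

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        if not (0.0 < self.clear_sky_transmittance <= 1.0):
            raise ValueError("clear_sky_transmittance must lie in (0, 1]")
        for name in ("noise_ta_c", "noise_rh_pct", "noise_ws_lognorm", "noise_sr_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation sigma.

    Re-centred to zero mean over the window: the generator's contract
    is that session-window means track the configured targets, so the
    slow component of the noise must not shift them.
    """
    if sigma == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x - x.mean()


def generate(spec: GeneratorSpec) -> MicrometSeries:
    """Generate a validated synthetic series from *spec*.

    Deterministic given the spec (including its seed).  Values are
    clipped to the physical bounds of the record invariants (RH to
    [5, 99] %, wind and radiation to non-negative); night-time records
    get SR = 0 and globe temperature equal to air temperature.
    """
    start = pd.Timestamp(spec.start)
    end = pd.Timestamp(spec.end)
    if end <= start:
        raise ValueError(f"degenerate time window: end {end} <= start {start}")
    times = pd.date_range(start, end, freq=pd.Timedelta(seconds=spec.interval_s), inclusive="left")
    n = len(times)
    rng = np.random.default_rng(spec.seed)

    elev = solar_elevation_deg(times, spec.latitude_deg, spec.longitude_deg)
    sin_b = np.sin(np.deg2rad(np.clip(elev, 0.0, None)))
    day = sin_b > 0.0
    sr_clear = np.zeros(n)
    tau = spec.clear_sky_transmittance
    sr_clear[day] = SOLAR_CONSTANT_WM2 * sin_b[day] * tau ** (1.0 / sin_b[day])
    sr = sr_clear * (1.0 + _ar1(rng, n, spec.ar1_phi, spec.noise_sr_frac))
    sr = np.clip(sr, 0.0, None)

    # diurnal wave, re-centred so the window mean is exactly ta_mean
    hour = times.hour.to_numpy() + times.minute.to_numpy() / 60.0 + times.second.to_numpy() / 3600.0
    wave = spec.ta_amp_c * np.cos(np.pi * (hour - 20.5) / 12.0)  # peak ~ 20:30 UTC
    wave = wave - wave.mean()
    ta = spec.ta_mean_c + wave + _ar1(rng, n, spec.ar1_phi, spec.noise_ta_c)

    rh = (
        spec.rh_mean_pct
        - spec.rh_slope_pct_per_c * (ta - spec.ta_mean_c)
        + _ar1(rng, n, spec.ar1_phi, spec.noise_rh_pct)
    )
    n_clipped = int(np.sum((rh < 5.0) | (rh > 99.0)))
    rh = np.clip(rh, 5.0, 99.0)

    g = _ar1(rng, n, spec.ar1_phi, 1.0) if spec.noise_ws_lognorm > 0 else np.zeros(n)
    s = spec.noise_ws_lognorm
    ws = spec.ws_mean_ms * np.exp(s * g - 0.5 * s * s)

    tg = ta + spec.globe_c1 * sr / (1.0 + spec.globe_c2 * ws)
    ts = ta + spec.turf_c3 * sr * (1.0 - spec.turf_albedo) / (1.0 + spec.turf_c4 * ws)

    frame = pd.DataFrame(
        {
            "timestamp": times,
            "ta_c": ta,
            "rh_pct": rh,
            "ws_ms": ws,
            "sr_wm2": sr,
            "tg_c": tg,
            "ts_c": ts,
        }
    )
    metadata = {
        "generator": "heatbudget.synthgen",
        "seed": str(spec.seed),
        "latitude_deg": str(spec.latitude_deg),
        "longitude_deg": str(spec.longitude_deg),
        "rh_values_clipped": str(n_clipped),
    }
    return MicrometSeries(frame=frame, interval_s=spec.interval_s, metadata=metadata)


def may_session_spec(seed: int = 0) -> GeneratorSpec:
    """Early-summer afternoon session: 2 h from 13:30 local (UTC−5).

    Targets: mean Ta 33.3 °C, RH 48 %, Ws 2.4 m/s, SR ≈ 886.8 W/m².
    """
    return GeneratorSpec(
        seed=seed,
        start="2020-05-19T18:30:00",
        end="2020-05-19T20:30:00",
        ta_mean_c=33.3,
        rh_mean_pct=48.0,
        ws_mean_ms=2.4,
        clear_sky_transmittance=0.711,
    )


def october_session_spec(seed: int = 0) -> GeneratorSpec:
    """Early-autumn afternoon session: 1 h from 13:30 local (UTC−5).

    Targets: mean Ta 34.0 °C, RH 42.9 %, Ws 4.04 m/s, SR ≈ 574.3 W/m².
    """
    return GeneratorSpec(
        seed=seed,
        start="2019-10-10T18:30:00",
        end="2019-10-10T19:30:00",
        ta_mean_c=34.0,
        rh_mean_pct=42.9,
        ws_mean_ms=4.04,
        clear_sky_transmittance=0.622,
    )
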