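# Methods

This note documents the models implemented in `heatbudget`, the
constants behind them, the synthetic-data generator used for testing,
and the design choices made where the formulations were genuinely open.

## Heat index

The NWS practical procedure, Fahrenheit-native. The simple formula
`0.5·(T + 61 + (T − 68)·1.2 + RH·0.094)` is evaluated first; when the
average of that result and T reaches 80 °F the full Rothfusz
regression replaces it, with the two NWS corrections: subtract
`((13 − RH)/4)·√((17 − |T − 95|)/17)` for RH < 13 % at 80–112 °F, add
`((RH − 85)/10)·((87 − T)/5)` for RH > 85 % at 80–87 °F. The
regression coefficients are the canonical nine (−42.379, 2.04901523,
10.14333127, −0.22475541, −6.83783·10⁻³, −5.481717·10⁻², 1.22874·10⁻³,
8.5282·10⁻⁴, −1.99·10⁻⁶).

The branch hand-off is only approximately continuous: on a 0.005 °F
scan of the 79–81 °F band the largest step is ≈ 2.3 °F, at high
humidity. This is a property of the published procedure, not of this
implementation; the test suite asserts the jump stays below 2.5 °F.

## Wet-bulb temperature and WBGT

Stull's empirical natural wet-bulb formula is evaluated exactly as
published (arctangents in radians, RH in percent; square root on
RH + 8.313659, RH^3/2 in the fourth term). Its stated validity is
RH ∈ [5, 99] %; outside, the package warns and still evaluates.

Two caveats, both measured against an iterative psychrometer-balance
oracle (Tetens saturation vapor pressure, psychrometric constant
γ = 0.0667 kPa/K):

* the fit's deviation from the psychrometric balance is ≈ 0.1–0.3 °C
  at moderate warm-humid conditions but grows to ≈ 1.3 °C at the dry
  (RH → 5 %) edge of the domain;
* the physical bound Tw ≤ Ta is violated by at most 0.011 °C on the
  RH = 99 edge above 43 °C — within the formula's own ±0.1 °C
  saturation error.

WBGT uses the outdoor ISO 7243 weights 0.7/0.2/0.1 (all positive,
summing to one). The package requires a measured or simulated globe
temperature; it deliberately does not substitute a globe model when
`tg_c` is absent.

## Energy budget

`EB = M + R_abs − Conv − Evap − T_remitted`, all in W/m² of body
surface area (DuBois: `0.007184·(100·h)^0.725·m^0.425`). The budget
equation and the persona parameterization (child vs adult) are the
modelled surface; the sub-models below are this package's own
closures in the COMFA lineage, with every constant in
`ConstantsRegistry` so the model can be recalibrated from
configuration.

* **Metabolism** `M = MET × RMR × (1 − work_fraction)`;
  work_fraction defaults to 0.
* **Core temperature** `Tc = 36.5 + 0.0043·M` °C — a linear rise of
  the regulated set-point supplying the sensible-heat gradient.
* **Resistance network** (units s/m): tissue
  `rt = clamp(104 − 0.25·M, 10, 104)` (vasodilation with workload);
  clothing `rc = clo·0.155·ρcp` (1 clo = 0.155 m²K/W); boundary layer
  from the Hilpert cylinder correlation, `ra = ρcp·d/(Nu·k_air)` with
  `d = BSA/(π·height)`, `Nu = C·Re^n` per Reynolds band, and wind
  floored at 0.3 m/s so the forced-convection form does not
  degenerate at calm.
* **Convection** `Conv = ρcp·(Tc − Ta)/(rt + rc + ra)`; skin and
  clothing-surface temperatures are read off the network
  (`Tsk = Ta + Conv·(ra + rc)/ρcp`, `Tsurf = Ta + Conv·ra/ρcp`).
  Negative Conv is sensible heat gain.
* **Radiation absorbed.** Global horizontal irradiance SR splits into
  diffuse `K_d = f_d·SR` and beam-normal `K_bn = (SR − K_d)/sin β`
  (clamped at the solar constant; suppressed, with a warning, when
  the sun is within 2° of the horizon yet SR > 50 W/m²). Shortwave on
  the cylinder: `(1 − α_cl)·[τ·(cos β/π)·K_bn + τ·0.5·SVF·K_d +
  0.5·α_g·SR]`, where τ is shade transmissivity and SVF the sky-view
  factor. Longwave: half the body's view split between clear sky
  (Idso emissivity `0.70 + 5.95·10⁻⁵·e_hPa·exp(1500/Ta_K)`) and
  obstructions at air temperature, half seeing the ground at its
  surface temperature. Solar elevation comes from the record
  timestamp and the site's coordinates (NOAA low-precision
  algorithm) or can be passed explicitly.
* **Evaporation** `E_pot = (ρcp/γ)·(e_s(Tsk) − e_air)/(ra + r_cv)`
  with Tetens `e_s`; skin wettedness ramps linearly from 0.06 at rest
  to 1 at M = 400 W/m²; the result is capped at
  `sweat_capacity_factor × 365 W/m²` (0.5 for the child) and floored
  at zero (no condensation gain).
* **Re-emission** `ε·σ·Tsurf⁴` with ε = 0.95.

Default constants: ρcp = 1212 J m⁻³K⁻¹, γ = 0.0667 kPa/K,
ν = 1.6·10⁻⁵ m²/s, k_air = 0.0267 W m⁻¹K⁻¹, ε_ground = 0.95,
clothing albedo 0.37, r_cv = 150 s/m (chosen so the evaporation
closure reproduces the design-time hand evaluation for the athlete
persona at session-mean conditions), diffuse fraction 0.15
(clear-sky).

### Personas and sites

The bundled study design (`study_defaults`): a child athlete (1.378 m,
31.9 kg — WHO-median 10-year-old — RMR 52 W/m², MET 7, clo 1.3 for
uniform and pads, half sweat capacity) on open artificial turf
(albedo 0.08, surface temperature taken from the record); an adult
coach (1.75 m, 70 kg, RMR 42 W/m², MET 4, clo 0.6) on sideline grass,
whose surface temperature is taken equal to air temperature; a seated
adult parent (MET 1.3, clo 0.5) under an oak with transmissivity
0.175 and SVF 0.5. Posture is carried as metadata and does not enter
the numerics. The child/adult contrast flows entirely through the
profile parameters — one code path, two parameterizations.

## Category scales

Published five-level tables leave sub-unit gaps between printed bands
(e.g. HI 31.7 → 32.2) and one WBGT Orange/Red overlap. Classification
here must be total and monotone, so bins are half-open and contiguous
on cutpoints HI [26.7, 32.2, 40.6, 54.4] °C, EB [60, 120, 200, 340]
W/m², WBGT [27.9, 30.6, 32.4, 33.4] °C; the contested WBGT sliver
resolves to the more severe category (Red starts at 32.4). Levels are
stored as ordinals 0–4; display names are presentation only, which is
what makes percent-agreement between methods well defined. The
EB↔HI band correspondence (Harlan) is served from the same cutpoints
so the two can never disagree on a label.

## Synthetic sessions

The generator emulates a mid-day session at an open Texas field
(30.63° N, 96.33° W): clear-sky irradiance `S0·sin β·τ_atm^(1/sin β)`,
a window-re-centred diurnal temperature wave with AR(1) noise, RH
anti-correlated with temperature (−3 points/°C, clipped to [5, 99]),
lognormal AR(1) wind, plus two monotone instrument closures —
`Tg = Ta + 0.02·SR/(1 + 0.7·Ws)` and turf
`Ts = Ta + 0.035·SR·(1 − 0.08)/(1 + 0.5·Ws)` — giving midday globe
excesses of ~5–15 °C and turf surfaces tens of degrees above air
temperature in calm sun. All AR(1) components are re-centred to zero
mean over the window: the generator's contract is that session-window
means track the configured targets, and the two bundled specs (early
summer: Ta 33.3 °C, RH 48 %, Ws 2.4 m/s, 2 h; early autumn: Ta
34.0 °C, RH 42.9 %, Ws 4.04 m/s, 1 h) carry atmospheric
transmittances (0.711, 0.622) solved so the clear-sky window mean
matches each session's mean irradiance. Randomness comes only from
the explicit seed; no global RNG state.

What the generator does **not** emulate: clouds, precipitation,
instrument drift and radiation error, gusts faster than the AR(1)
decorrelation, multi-day structure. Tests passing on synthetic data
therefore demonstrate internal consistency and the qualitative
persona orderings, not agreement with any specific field record.

## Problem sizes and numerical choices

The test suite and acceptance checks run on desk-scale inputs chosen
as representative rather than exhaustive: sessions of 360–720 records
(10-s cadence), property grids of ~10²–10³ points, and a 10⁴-point
random sweep for the conservation identity. Conservation holds to
1e-9 by construction and is re-summed independently in tests. CSV
round-trips are asserted to 1e-9 on floats. Ties at category
cutpoints go to the more severe level (half-open bins, right side).

## Known limitations

* Steady-state only: no heat storage, no transient core-temperature
  dynamics, no acclimatization.
* The evaporation cap is a single number per persona; real sweat
  capacity varies with fitness, hydration and heat adaptation.
* The cylinder interception factor `cos β/π` underweights beam
  radiation at high sun for non-cylindrical postures; seated posture
  is not geometrically modelled.
* Child physiology beyond RMR, sweat capacity and anthropometry
  (e.g. elevated skin temperature) is not modelled — no published
  closure was adopted for it.
* The natural wet bulb is approximated by an aspirated-psychrometer
  fit; in strong sun the true natural wet bulb runs warmer, so the
  computed WBGT is, if anything, optimistic.
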