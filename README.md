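# heatbudget

Heat-stress assessment for young athletes on outdoor fields: the
standard meteorological indices (heat index, WBGT) side by side with a
person-specific human energy budget, on the same micrometeorological
time series, classified on the same five-level heat-stress scale.

The package exists because the standard indices answer a different
question than the one a coach needs answered. The heat index and WBGT
describe the *air*; a 10-year-old playing football on artificial turf
is a small, high-metabolism body with half an adult's sweating
capacity, absorbing radiation from a 60 °C surface. An energy-budget
model makes that difference explicit — and shows the sideline adults
why their own comfort is a poor guide to the players' risk.

## Models

**Heat index (HI)** — the NWS apparent temperature: a simple averaged
formula at mild conditions, switching to the Rothfusz regression
(with the low-/high-humidity corrections) once the preliminary value
reaches 80 °F. °F-native internally, °C at the surface.

**WBGT** — the ISO 7243 outdoor weighting

    WBGT = 0.7·Tw + 0.2·Tg + 0.1·Ta

with the natural wet-bulb temperature Tw from Stull's empirical
formula in Ta and RH, and Tg a measured (or simulated) black-globe
temperature.

**Energy budget (EB)** — net heat gain per unit body surface area,

    EB = M + R_abs − Conv − Evap − T_remitted      [W/m²]

evaluated for a clothed cylinder: metabolic heat M = MET × RMR;
absorbed short- and long-wave radiation from a beam/diffuse/reflected
decomposition with sky-view factor and shade transmissivity; sensible
convection through a tissue–clothing–boundary-layer resistance
network; psychrometric evaporation capped by sweating capacity;
Stefan–Boltzmann re-emission from the clothing surface. A child and an
adult share one code path and differ only through the
`PersonProfile` parameters (child: RMR 52 W/m², MET 7 for football,
half adult sweat capacity, WHO-median 10-year-old anthropometry).

Each method's values map onto a shared 0–4 ordinal scale
(Safe … Extreme Danger / Green … Black) so percent-agreement between
methods is well defined.

## Worked example

```python
>>> import pandas as pd, heatbudget as hb
>>> hb.heat_index(34.0, 42.9)          # autumn session mean conditions
36.20423923275788
>>> tw = hb.wet_bulb_stull(33.3, 48.0) # summer session mean conditions
>>> tw
24.749879254598046
>>> hb.wbgt(tw, 40.0, 33.3)
28.654915478218633
```

A heat index of 36.2 °C is "Extreme Caution" (band 32.2–40 °C) and a
WBGT of 28.7 °C is only "Yellow — use discretion", yet the energy
budget for the three personas at the same early-summer mean
conditions (turf surface at 60 °C) tells a different story:

```python
>>> from heatbudget import budget as bd, categorize as cat
>>> profiles, sites, scales = hb.study_defaults()
>>> rec = hb.MicrometRecord(pd.Timestamp("2020-05-19T19:30:00"), ta_c=33.3,
...     rh_pct=48.0, ws_ms=2.4, sr_wm2=886.8, tg_c=40.0, ts_c=60.0)
>>> for name, site in (("athlete", "turf_field"), ("coach", "grass_sideline"),
...                    ("parent", "oak_shade")):
...     bb = bd.energy_budget(profiles[name], rec, sites[site])
...     label = scales["EB"].levels[cat.classify(bb.budget_wm2, scales["EB"])]
...     print(f"{name:8s} {bb.budget_wm2:7.1f} W/m^2  -> {label}")
athlete    325.7 W/m^2  -> Danger
coach      163.1 W/m^2  -> Extreme Caution
parent      67.2 W/m^2  -> Caution
```

The child on the turf sits two heat-stress levels above the shaded
parent in the identical weather. Over a full simulated two-hour
session (`heatbudget simulate --session may`, then `heatbudget run`)
the per-method category ranges diverge the same way: HI reports
"Extreme Caution", WBGT "Green–Yellow", and the child energy budget
"Danger".

The same pipeline is available from the shell:

```sh
heatbudget simulate --session may --seed 3 --out may.csv
heatbudget run --series may.csv --profile athlete --methods HI,WBGT,CK --outdir report/
```

writing `per_timestep.csv`, `summary.csv`, `categories.csv`,
`agreement.csv` and a plain-text report.

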