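"""End-to-end analysis: personas × sites × methods → report blocks.

A :class:`Scenario` pairs one persona with one radiative site context
and a set of methods; :func:`run_scenario` evaluates every selected
method at every timestep of a series and assembles a :class:`RunReport`
whose blocks mirror the tables a field study reports: a per-timestep
table, a max/min/mean summary, the observed category range per method,
the percent of time in each heat-stress level, and the pairwise
percent-agreement matrix between methods.

Methods
-------
``HI``     heat index from (Ta, RH)
``WBGT``   wet bulb globe temperature from (Stull Tw, measured Tg, Ta)
``COMFA``  energy budget of an adult persona
``CK``     energy budget of a child persona (child parameter set)

All methods in one run share the same timestamps; a method whose
required inputs are missing fails the whole scenario rather than
silently dropping rows, so agreement comparisons are always aligned.

:func:`study_defaults` bundles the three personas of the study design —
a 10-year-old boy playing football on artificial turf (RMR 52 W/m²,
MET 7), a 40-year-old coach standing on sideline grass (RMR 42 W/m²,
MET 4, ground at air temperature) and a seated parent under an oak
(shade transmissivity 17.5 %, sky view factor 50 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import budget as bd
from . import categorize as cat
from . import indices as idx
from .micromet import MicrometSeries, summarize

__all__ = ["Scenario", "RunReport", "run_scenario", "study_defaults", "load_config"]

METHODS = ("HI", "WBGT", "COMFA", "CK")

# coordinates of the bundled study field (central Texas)
FIELD_LATITUDE_DEG = 30.63
FIELD_LONGITUDE_DEG = -96.33


@dataclass(frozen=True)
class Scenario:
    persona: bd.PersonProfile
    site: bd.SiteContext
    methods: tuple[str, ...] = ("HI", "WBGT")
    constants: bd.ConstantsRegistry = bd.DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("scenario needs at least one method")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
        if "CK" in self.methods and self.persona.age_class != "child":
            raise ValueError("CK (child energy budget) requires a child persona")
        if "COMFA" in self.methods and self.persona.age_class != "adult":
            raise ValueError("COMFA (adult energy budget) requires an adult persona")


@dataclass
class RunReport:
    """All report blocks of one scenario run.

    Every block is derived from ``per_timestep``; the summary block is
    produced by :func:`heatbudget.micromet.summarize` on that table (no
    second aggregation path), and ``config_echo`` is complete enough to
    rerun the scenario.
    """

    per_timestep: pd.DataFrame
    summary: pd.DataFrame
    category_range: dict[str, str]
    time_in_category: pd.DataFrame
    agreement: pd.DataFrame
    config_echo: dict = field(default_factory=dict)


def _method_value_column(method: str) -> str:
    return {"HI": "hi_c", "WBGT": "wbgt_c", "COMFA": "eb_wm2", "CK": "eb_wm2"}[method]


def _method_scale(method: str, scales: dict[str, cat.CategoryScale]) -> cat.CategoryScale:
    return scales[{"HI": "HI", "WBGT": "WBGT", "COMFA": "EB", "CK": "EB"}[method]]


def run_scenario(series: MicrometSeries, scenario: Scenario) -> RunReport:
    """Evaluate every selected method per timestep and build the report.

    Deterministic given the series and the scenario configuration.
    Raises a named error when the series lacks a column a selected
    method needs (Tg for WBGT, a ground-surface temperature for sites
    that read it from the record).
    """
    frame = series.frame
    scales = cat.default_scales()
    out = frame[[c for c in frame.columns]].copy()

    needs_budget = [m for m in scenario.methods if m in ("COMFA", "CK")]
    if "WBGT" in scenario.methods and "tg_c" not in frame.columns:
        raise ValueError("WBGT selected but series has no black-globe column tg_c")
    if needs_budget and scenario.site.use_record_surface_temp and "ts_c" not in frame.columns:
        raise ValueError(
            f"{needs_budget[0]} selected with a site that reads the ground-surface "
            "temperature from the record, but the series has no ts_c column"
        )

    site = scenario.site
    if needs_budget and site.latitude_deg is None:
        lat = series.metadata.get("latitude_deg")
        lon = series.metadata.get("longitude_deg")
        if lat is None or lon is None:
            raise ValueError(
                "energy-budget methods need solar geometry: set site latitude/longitude "
                "or provide them in the series metadata"
            )
        site = bd.SiteContext(
            **{**_site_dict(site), "latitude_deg": float(lat), "longitude_deg": float(lon)}
        )

    if "HI" in scenario.methods:
        out["hi_c"] = idx.heat_index(frame["ta_c"].to_numpy(), frame["rh_pct"].to_numpy())
    if "WBGT" in scenario.methods:
        tw = idx.wet_bulb_stull(frame["ta_c"].to_numpy(), frame["rh_pct"].to_numpy())
        out["tw_c"] = tw
        out["wbgt_c"] = idx.wbgt(tw, frame["tg_c"].to_numpy(), frame["ta_c"].to_numpy())
    if needs_budget:
        cols = {k: [] for k in ("m_wm2", "rabs_wm2", "conv_wm2", "evap_wm2", "tremit_wm2", "eb_wm2")}
        for rec in series.records:
            bb = bd.energy_budget(scenario.persona, rec, site, constants=scenario.constants)
            cols["m_wm2"].append(bb.m_wm2)
            cols["rabs_wm2"].append(bb.rabs_wm2)
            cols["conv_wm2"].append(bb.conv_wm2)
            cols["evap_wm2"].append(bb.evap_wm2)
            cols["tremit_wm2"].append(bb.tremit_wm2)
            cols["eb_wm2"].append(bb.budget_wm2)
        for k, v in cols.items():
            out[k] = v

    # per-method labels
    label_series: dict[str, cat.CategorySeries] = {}
    for m in scenario.methods:
        scale = _method_scale(m, scales)
        cs = cat.classify_series(out[_method_value_column(m)].to_numpy(), scale,
                                 timestamps=out["timestamp"].to_numpy())
        label_series[m] = cs
        out[f"level_{m.lower()}"] = cs.labels
        out[f"label_{m.lower()}"] = [scale.levels[i] for i in cs.labels]

    numeric = [c for c in out.columns if out[c].dtype.kind == "f"]
    summary = summarize(out, numeric)

    cat_range = {
        m: cat.render_range(label_series[m], _method_scale(m, scales)) for m in scenario.methods
    }
    tic = pd.DataFrame(
        {m: cat.time_in_category(label_series[m]) for m in scenario.methods},
        index=[f"level_{i}" for i in range(5)],
    )
    methods = list(scenario.methods)
    agree = pd.DataFrame(
        [[cat.agreement_pct(label_series[a], label_series[b]) for b in methods] for a in methods],
        index=methods,
        columns=methods,
    )

    echo = {
        "persona": _dataclass_dict(scenario.persona),
        "site": _site_dict(site),
        "methods": methods,
        "constants": scenario.constants.as_dict(),
        "series_metadata": dict(series.metadata),
        "interval_s": series.interval_s,
    }
    return RunReport(
        per_timestep=out,
        summary=summary,
        category_range=cat_range,
        time_in_category=tic,
        agreement=agree,
        config_echo=echo,
    )


def _dataclass_dict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def _site_dict(site: bd.SiteContext) -> dict:
    return _dataclass_dict(site)


def study_defaults() -> tuple[dict[str, bd.PersonProfile], dict[str, bd.SiteContext], dict[str, cat.CategoryScale]]:
    """The bundled personas, sites and category scales of the study design.

    Personas: the boy athlete (child, RMR 52 W/m², MET 7, football
    uniform and pads), the coach (adult, RMR 42 W/m², MET 4, shirt and
    long pants) and the seated parent (adult, light clothing, low
    activity).  Sites: the open artificial-turf field (surface
    temperature read from the record), the grass sideline (surface at
    air temperature) and the oak shade (transmissivity 0.175, sky view
    factor 0.5, grass underfoot).
    """
    profiles = {
        "athlete": bd.PersonProfile(
            label="athlete",
            age_class="child",
            height_m=1.378,
            mass_kg=31.9,
            rmr_wm2=52.0,
            met=7.0,
            clo=1.3,
            sweat_capacity_factor=0.5,
            posture="standing",
        ),
        "coach": bd.PersonProfile(
            label="coach",
            age_class="adult",
            height_m=1.75,
            mass_kg=70.0,
            rmr_wm2=42.0,
            met=4.0,
            clo=0.6,
            sweat_capacity_factor=1.0,
            posture="standing",
        ),
        "parent": bd.PersonProfile(
            label="parent",
            age_class="adult",
            height_m=1.75,
            mass_kg=70.0,
            rmr_wm2=42.0,
            met=1.3,
            clo=0.5,
            sweat_capacity_factor=1.0,
            posture="seated",
        ),
    }
    sites = {
        "turf_field": bd.SiteContext(
            sky_view_factor=1.0,
            shade_transmissivity=1.0,
            ground_albedo=0.08,
            use_record_surface_temp=True,
            latitude_deg=FIELD_LATITUDE_DEG,
            longitude_deg=FIELD_LONGITUDE_DEG,
        ),
        "grass_sideline": bd.SiteContext(
            sky_view_factor=1.0,
            shade_transmissivity=1.0,
            ground_albedo=0.25,
            latitude_deg=FIELD_LATITUDE_DEG,
            longitude_deg=FIELD_LONGITUDE_DEG,
        ),
        "oak_shade": bd.SiteContext(
            sky_view_factor=0.5,
            shade_transmissivity=0.175,
            ground_albedo=0.25,
            latitude_deg=FIELD_LATITUDE_DEG,
            longitude_deg=FIELD_LONGITUDE_DEG,
        ),
    }
    return profiles, sites, cat.default_scales()


#: persona -> its default site in the three-persona comparison
DEFAULT_PERSONA_SITES = {"athlete": "turf_field", "coach": "grass_sideline", "parent": "oak_shade"}


def load_config(path) -> tuple[dict[str, bd.PersonProfile], dict[str, bd.SiteContext], dict]:
    """Load persona and site blocks from a YAML configuration file.

    Layout::

        personas:
          athlete: {age_class: child, height_m: 1.378, ...}
        sites:
          turf_field: {sky_view_factor: 1.0, ...}
        constants:          # optional registry overrides
          rho_cp: 1212.0

    Unknown keys raise; persona/site values are validated by their
    dataclasses.  Returns (profiles, sites, constants_overrides).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    profiles = {
        name: bd.PersonProfile(label=name, **block)
        for name, block in (raw.get("personas") or {}).items()
    }
    sites = {name: bd.SiteContext(**block) for name, block in (raw.get("sites") or {}).items()}
    return profiles, sites, raw.get("constants") or {}
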