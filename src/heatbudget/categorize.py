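"""Five-level heat-stress classification and inter-method comparison.

Each method (heat index, WBGT, energy budget) maps its value onto the
same five-level ordinal scale — 0 safest to 4 most dangerous — via four
ascending cutpoints.  Display names differ per method (Safe…Extreme
Danger for HI and the energy budget, Green…Black for the athletics
WBGT guideline) but the ordinal scale is shared, which is what makes
percent-agreement between methods well defined.

Published category tables leave small gaps between adjacent bands
(rounding artifacts of the printed bounds) and, for WBGT, one overlap
between the Orange and Red rows.  Classification must be total and
monotone, so the bins here are half-open and contiguous, anchored at
the lower bound of each upper band; the WBGT Orange/Red overlap is
resolved at 32.4 °C (the more severe category wins on the contested
sliver).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CategoryScale",
    "CategorySeries",
    "classify",
    "classify_series",
    "harlan_eb_to_hi_band",
    "agreement_pct",
    "time_in_category",
    "category_range",
    "default_scales",
    "HI_LEVEL_NAMES",
    "WBGT_LEVEL_NAMES",
]

HI_LEVEL_NAMES = ("Safe", "Caution", "Extreme Caution", "Danger", "Extreme Danger")
WBGT_LEVEL_NAMES = ("Green", "Yellow", "Orange", "Red", "Black")


@dataclass(frozen=True)
class CategoryScale:
    """An ordered five-level scale with four ascending cutpoints.

    ``classify(v)`` = number of cutpoints ≤ v; bins are half-open
    [c_i, c_{i+1}), so every finite value maps to exactly one level.
    """

    method: str  # "HI", "WBGT" or "EB"
    levels: tuple[str, str, str, str, str]
    cutpoints: tuple[float, float, float, float]  # method units, ascending

    def __post_init__(self) -> None:
        if len(self.levels) != 5 or len(self.cutpoints) != 4:
            raise ValueError("scale needs exactly five levels and four cutpoints")
        if not all(a < b for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValueError("cutpoints must be strictly ascending")


def default_scales() -> dict[str, CategoryScale]:
    """The canonical scales: HI °C, energy budget W/m², athletics WBGT °C."""
    return {
        "HI": CategoryScale("HI", HI_LEVEL_NAMES, (26.7, 32.2, 40.6, 54.4)),
        "EB": CategoryScale("EB", HI_LEVEL_NAMES, (60.0, 120.0, 200.0, 340.0)),
        "WBGT": CategoryScale("WBGT", WBGT_LEVEL_NAMES, (27.9, 30.6, 32.4, 33.4)),
    }


@dataclass
class CategorySeries:
    """Per-timestep ordinal heat-stress levels for one method."""

    labels: np.ndarray  # int levels, 0..4
    method: str
    timestamps: object = None  # optional DatetimeIndex aligned with labels

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() > 4):
            raise ValueError("levels must lie in 0..4")

    def __len__(self) -> int:
        return len(self.labels)


def classify(value: float, scale: CategoryScale) -> int:
    """Map one value to its ordinal level (0 safest … 4 most dangerous)."""
    if not np.isfinite(value):
        raise ValueError(f"cannot classify non-finite value {value!r}")
    return int(np.searchsorted(scale.cutpoints, value, side="right"))


def classify_series(values, scale: CategoryScale, timestamps=None) -> CategorySeries:
    """Vectorized :func:`classify` over a value array."""
    vals = np.asarray(values, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("cannot classify non-finite values")
    labels = np.searchsorted(scale.cutpoints, vals, side="right")
    return CategorySeries(labels=labels, method=scale.method, timestamps=timestamps)


# Harlan correspondence between energy-budget bands and heat-index bands.
# Rows: (EB band text, HI band text, label); the numeric cuts are the EB scale's.
_HARLAN_ROWS = (
    ("<60", "<26.7", "Safe"),
    ("60-120", "26.7-31.7", "Caution"),
    ("121-200", "32.2-40", "Extreme Caution"),
    ("201-339", "40.6-53.9", "Danger"),
    (">=340", ">=54.4", "Extreme Danger"),
)


def harlan_eb_to_hi_band(eb_wm2: float) -> tuple[str, str]:
    """Map an energy-budget value onto its heat-index band.

    Returns ``(hi_band_text, label)`` from the published
    correspondence: 60–120 W/m² ↔ HI 26.7–31.7 °C (Caution),
    121–200 ↔ 32.2–40 (Extreme Caution), 201–339 ↔ 40.6–53.9 (Danger),
    ≥340 ↔ ≥54.4 (Extreme Danger), below 60 ↔ below 26.7 (Safe).
    Band membership uses the same half-open bins as the EB scale so the
    label always agrees with :func:`classify`.
    """
    level = classify(eb_wm2, default_scales()["EB"])
    _, hi_band, label = _HARLAN_ROWS[level]
    return hi_band, label


def agreement_pct(a: CategorySeries, b: CategorySeries) -> float:
    """Percent of timesteps on which two methods assign the same level."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if a.timestamps is not None and b.timestamps is not None:
        if not np.array_equal(np.asarray(a.timestamps), np.asarray(b.timestamps)):
            raise ValueError("series are not aligned on the same timestamps")
    if len(a) == 0:
        raise ValueError("cannot compare empty series")
    return 100.0 * float(np.mean(a.labels == b.labels))


def time_in_category(c: CategorySeries) -> np.ndarray:
    """Percent of time spent in each of the five levels (sums to 100)."""
    if len(c) == 0:
        raise ValueError("empty category series")
    counts = np.bincount(c.labels, minlength=5)[:5]
    return 100.0 * counts / len(c)


def category_range(c: CategorySeries) -> tuple[int, int]:
    """Observed (min level, max level) over the series."""
    if len(c) == 0:
        raise ValueError("empty category series")
    return int(c.labels.min()), int(c.labels.max())


def render_range(c: CategorySeries, scale: CategoryScale) -> str:
    """Render the observed range as 'X-Y', or 'X' when only one level occurs."""
    lo, hi = category_range(c)
    if lo == hi:
        return scale.levels[lo]
    return f"{scale.levels[lo]}-{scale.levels[hi]}"
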