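"""Body-weight, consumption, murinometric, and glucose calculators.

Covers the quantitative monitoring arm of the diabetes-induction protocol:
weekly body-weight gain, cage-level food and water accounting, terminal
murinometric indices (Lee index, BMI, specific rate of weight gain, food
efficiency coefficient, AP/TC ratio), relative organ weights, the
glucometer ceiling (600 mg/dL) censoring rule, and Tukey boxplot outlier
fences.

Units follow laboratory convention: weights in grams, lengths in
centimetres, glucose in mg/dL, water in millilitres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ABOVE_RANGE",
    "GLUCOMETER_CEILING",
    "WeightSeries",
    "CageConsumptionRecord",
    "GlucoseReading",
    "MorphometricMeasures",
    "OrganWeight",
    "CensoredValue",
    "body_weight_gain_pct",
    "daily_food_consumption",
    "daily_water_consumption",
    "lee_index",
    "body_mass_index",
    "specific_rate_weight_gain",
    "food_efficiency_coefficient",
    "ap_tc_ratio",
    "relative_organ_weight",
    "censor_glucose",
    "flag_outliers",
    "weight_loss_fraction",
]

#: Upper reading limit of the glucometer (mg/dL).  Readings above it are
#: reported by the meter as "HI" and recorded at the ceiling, censored.
GLUCOMETER_CEILING = 600.0

#: Sentinel for an above-range glucometer reading ("HI" on the display).
ABOVE_RANGE = "HI"

#: Default protocol duration in days (7 weeks) for the specific rate of
#: weight gain.
DEFAULT_PROTOCOL_DAYS = 49


@dataclass(frozen=True)
class WeightSeries:
    """Ordered weekly body weights for one animal."""

    animal_id: str
    weights: tuple[tuple[int, float], ...]  # (week, grams)
    terminal_fasted: bool = True

    def __post_init__(self) -> None:
        weeks = [w for w, _ in self.weights]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("weeks must be strictly increasing")
        if any(g <= 0 for _, g in self.weights):
            raise ValueError("body weights must be positive")


@dataclass(frozen=True)
class CageConsumptionRecord:
    """Cage-level food (and water) accounting for one week.

    ``water_total_24h_ml`` applies from week 4 onwards, when water intake
    became too large for weekly bottle accounting and was measured over a
    single 24-h window instead.
    """

    cage_id: str
    week: int
    food_weight_start_g: float
    food_weight_end_g: float
    n_animals: int
    n_days: int = 7
    water_weight_start_g: float | None = None
    water_weight_end_g: float | None = None
    water_total_24h_ml: float | None = None

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.food_weight_start_g < self.food_weight_end_g:
            raise ValueError("food weight cannot increase over the week")


class CensoredValue(NamedTuple):
    """A glucometer value after applying the 600 mg/dL ceiling."""

    value: float
    censored: bool


@dataclass(frozen=True)
class GlucoseReading:
    animal_id: str
    week: int
    state: str  # "fasted" (12 h) or "fed" (2 h after feeding)
    raw: float | str
    value: float
    censored: bool

    def __post_init__(self) -> None:
        if self.value > GLUCOMETER_CEILING:
            raise ValueError("stored glucose value cannot exceed the meter ceiling")


@dataclass(frozen=True)
class MorphometricMeasures:
    """Terminal murinometric measures for one animal.

    NAL: nasal-anal length; TC: thoracic perimeter; AP: abdominal
    perimeter (all cm).  The final body weight is taken before the 12-h
    terminal fast; the fasting weight immediately before euthanasia.
    """

    animal_id: str
    final_body_weight_g: float
    final_fasting_body_weight_g: float
    nal_cm: float
    tc_cm: float
    ap_cm: float
    total_food_consumption_g: float
    duration_days: int = DEFAULT_PROTOCOL_DAYS

    def __post_init__(self) -> None:
        for f in (
            self.final_body_weight_g,
            self.final_fasting_body_weight_g,
            self.nal_cm,
            self.tc_cm,
            self.ap_cm,
        ):
            if f <= 0:
                raise ValueError("lengths and weights must be positive")


@dataclass(frozen=True)
class OrganWeight:
    animal_id: str
    organ: str
    weight_g: float

    def __post_init__(self) -> None:
        if self.weight_g <= 0:
            raise ValueError("organ weight must be positive")


# --------------------------------------------------------------------------
# Weight and consumption
# --------------------------------------------------------------------------

def body_weight_gain_pct(
    current_g: float, initial_g: float, *, denominator: str = "current"
) -> float:
    """Body weight gain (%) between the initial weight and a later one.

    The study's formula normalises by the *current* weight:
    ``(current - initial) / current * 100``.  The conventional variant
    normalising by the initial weight is available with
    ``denominator="initial"``.
    """
    if current_g <= 0:
        raise ValueError("current weight must be positive")
    if denominator == "current":
        return (current_g - initial_g) / current_g * 100.0
    if denominator == "initial":
        if initial_g <= 0:
            raise ValueError("initial weight must be positive")
        return (current_g - initial_g) / initial_g * 100.0
    raise ValueError(f"unknown denominator {denominator!r}")


def daily_food_consumption(
    start_g: float, end_g: float, n_animals: int, n_days: int
) -> float:
    """Mean daily food consumption per animal (g/animal/day) from the
    cage food-hopper weights at the beginning and end of the week."""
    if n_animals < 1 or n_days < 1:
        raise ValueError("n_animals and n_days must be >= 1")
    if start_g < end_g:
        raise ValueError("food weight cannot increase over the period")
    return (start_g - end_g) / (n_animals * n_days)


def daily_water_consumption(total_24h_ml: float, n_animals: int) -> float:
    """Per-animal daily water intake (mL) from a 24-h cage total."""
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if total_24h_ml < 0:
        raise ValueError("water volume cannot be negative")
    return total_24h_ml / n_animals


# --------------------------------------------------------------------------
# Murinometric indices
# --------------------------------------------------------------------------

def lee_index(final_weight_g: float, nal_cm: float, *, scale: float = 1.0) -> float:
    """Lee adiposity index: final body weight over the cubed nasal-anal
    length, ``scale * weight / NAL**3``.

    The default ``scale=1`` evaluates the ratio verbatim; some
    laboratories multiply by a power of ten or take a cube root, so an
    explicit multiplier is exposed.
    """
    if nal_cm <= 0:
        raise ValueError("NAL must be positive")
    return scale * final_weight_g / nal_cm**3


def body_mass_index(final_fasting_weight_g: float, nal_cm: float) -> float:
    """Rodent BMI (g/cm^2): fasting terminal weight over the squared
    nasal-anal length."""
    if nal_cm <= 0:
        raise ValueError("NAL must be positive")
    return final_fasting_weight_g / nal_cm**2


def specific_rate_weight_gain(
    final_g: float, initial_g: float, days: int = DEFAULT_PROTOCOL_DAYS
) -> float:
    """Specific rate of weight gain (g/g/day basis):
    ``(final - initial) / (initial * days)``.

    ``final`` is the non-fasted terminal weight.
    """
    if initial_g <= 0:
        raise ValueError("initial weight must be positive")
    if days < 1:
        raise ValueError("days must be >= 1")
    return (final_g - initial_g) / (initial_g * days)


def food_efficiency_coefficient(final_g: float, initial_g: float, total_food_g: float) -> float:
    """Food efficiency coefficient (g weight gain per g food consumed)."""
    if total_food_g <= 0:
        raise ValueError("total food consumption must be positive")
    return (final_g - initial_g) / total_food_g


def ap_tc_ratio(ap_cm: float, tc_cm: float) -> float:
    """Abdominal over thoracic perimeter; a central-adiposity marker."""
    if tc_cm <= 0:
        raise ValueError("thoracic perimeter must be positive")
    return ap_cm / tc_cm


def relative_organ_weight(organ_g: float, body_g: float) -> float:
    """Organ weight relative to body weight, in grams per kilogram."""
    if body_g <= 0:
        raise ValueError("body weight must be positive")
    return organ_g / (body_g / 1000.0)


# --------------------------------------------------------------------------
# Glucose censoring and outliers
# --------------------------------------------------------------------------

def censor_glucose(raw: float | str) -> CensoredValue:
    """Apply the glucometer ceiling to a raw reading.

    An ``ABOVE_RANGE`` ("HI") reading is recorded at 600 mg/dL and marked
    censored.  A numeric reading above 600 cannot come from the meter, so
    it is ingested tolerantly the same way; values at or below the
    ceiling pass through uncensored.  Idempotent.
    """
    if isinstance(raw, str):
        if raw.strip().upper() == ABOVE_RANGE:
            return CensoredValue(GLUCOMETER_CEILING, True)
        raise ValueError(f"unrecognised glucometer reading {raw!r}")
    v = float(raw)
    if v < 0:
        raise ValueError(f"negative glucose reading: {v}")
    if v > GLUCOMETER_CEILING:
        return CensoredValue(GLUCOMETER_CEILING, True)
    return CensoredValue(v, False)


def flag_outliers(values: Sequence[float]) -> set[float]:
    """Tukey boxplot outliers: values outside
    ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]``.

    Quartiles use linear interpolation between order statistics.  Returns
    the set of flagged values; requires at least four observations for
    the fences to be meaningful.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("at least 4 values are required for boxplot fences")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {float(v) for v in arr[(arr < lo) | (arr > hi)]}


def weight_loss_fraction(
    weights_prev: Mapping[str, float], weights_now: Mapping[str, float]
) -> float:
    """Percent of animals whose weight decreased between two weeks.

    Both mappings must cover the same animals; returns
    ``100 * (# animals with now < prev) / (# animals)``.
    """
    if set(weights_prev) != set(weights_now):
        raise ValueError("animal sets differ between the two weeks")
    if not weights_prev:
        raise ValueError("empty animal set")
    lost = sum(1 for a in weights_prev if weights_now[a] < weights_prev[a])
    return 100.0 * lost / len(weights_prev)
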