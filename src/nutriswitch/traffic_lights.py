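"""Traffic-light (green/amber/red) classification of fat, saturates, sugars, salt.

Implements the UK FSA front-of-pack signpost thresholds: separate cutoff sets
per 100 g for foods and per 100 ml for drinks, plus per-portion "high" (red)
criteria that apply to foods only, when a serving size is known. Energy is
displayed alongside the four lights but never carries a colour.

Boundary semantics follow the printed cutoffs exactly: a value equal to the
green maximum is green, a value equal to the amber maximum is amber, and red
requires strictly exceeding the red threshold. Values are compared exactly;
no rounding is applied first. Salt is derived from sodium before
classification (``salt_g = sodium_mg * 2.5 / 1000``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .food_db import FoodRecord, salt_from_sodium

__all__ = [
    "Color",
    "Nutrient",
    "NutrientCutoffs",
    "TrafficLightThresholds",
    "TrafficLightLabel",
    "DEFAULT_THRESHOLDS",
    "classify_nutrient",
    "label_record",
]


class Color(str, Enum):
    GREEN = "green"
    AMBER = "amber"
    RED = "red"


class Nutrient(str, Enum):
    TOTAL_FAT = "total_fat"
    SATURATED_FAT = "saturated_fat"
    SUGARS = "sugars"
    SALT = "salt"


@dataclass(frozen=True)
class NutrientCutoffs:
    """Cutoffs for one nutrient on one basis (per 100 g or per 100 ml).

    green iff value <= green_max; red iff value > red_exceeds; amber between.
    ``portion_red_exceeds`` is the per-portion red criterion (foods only).
    """

    green_max: float
    red_exceeds: float
    portion_red_exceeds: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.green_max < self.red_exceeds:
            raise ValueError(
                f"green_max ({self.green_max}) must be < red_exceeds ({self.red_exceeds})")


@dataclass(frozen=True)
class TrafficLightThresholds:
    """Complete threshold configuration: food and drink cutoffs per nutrient."""

    food: dict[Nutrient, NutrientCutoffs]
    drink: dict[Nutrient, NutrientCutoffs]

    def __post_init__(self) -> None:
        for table in (self.food, self.drink):
            missing = set(Nutrient) - set(table)
            if missing:
                raise ValueError(f"thresholds missing nutrients: {sorted(n.value for n in missing)}")

    def cutoffs(self, nutrient: Nutrient, is_drink: bool) -> NutrientCutoffs:
        return (self.drink if is_drink else self.food)[nutrient]


# FSA signpost cutoffs: foods per 100 g (with per-portion red criteria),
# drinks per 100 ml (no portion criteria).
DEFAULT_THRESHOLDS = TrafficLightThresholds(
    food={
        Nutrient.TOTAL_FAT: NutrientCutoffs(3.0, 20.0, 21.0),
        Nutrient.SATURATED_FAT: NutrientCutoffs(1.5, 5.0, 6.0),
        Nutrient.SUGARS: NutrientCutoffs(5.0, 12.5, 15.0),
        Nutrient.SALT: NutrientCutoffs(0.30, 1.50, 2.40),
    },
    drink={
        Nutrient.TOTAL_FAT: NutrientCutoffs(1.5, 10.0),
        Nutrient.SATURATED_FAT: NutrientCutoffs(0.75, 2.5),
        Nutrient.SUGARS: NutrientCutoffs(2.5, 6.3),
        Nutrient.SALT: NutrientCutoffs(0.30, 1.50),
    },
)


@dataclass(frozen=True)
class TrafficLightLabel:
    """Four coloured lights plus an uncoloured energy figure."""

    colors: dict[Nutrient, Color]
    energy_kj_display: float
    basis: str  # "per100g_food" | "per100ml_drink"
    portion_red_applied: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if set(self.colors) != set(Nutrient):
            raise ValueError("label must colour exactly the four signpost nutrients")

    def as_dict(self) -> dict:
        return {
            "colors": {n.value: c.value for n, c in self.colors.items()},
            "energy_kj_display": self.energy_kj_display,
            "basis": self.basis,
            "portion_red_applied": sorted(n.value for n in self.portion_red_applied),
        }


def thresholds_from_dict(d: dict) -> TrafficLightThresholds:
    """Build a threshold set from a plain mapping (parsed YAML/JSON).

    Expected shape::

        food:
          total_fat: {green_max: 3.0, red_exceeds: 20.0, portion_red_exceeds: 21.0}
          ...
        drink:
          total_fat: {green_max: 1.5, red_exceeds: 10.0}
          ...
    """
    def table(section: dict) -> dict[Nutrient, NutrientCutoffs]:
        return {Nutrient(name): NutrientCutoffs(
                    green_max=float(c["green_max"]),
                    red_exceeds=float(c["red_exceeds"]),
                    portion_red_exceeds=(None if c.get("portion_red_exceeds") is None
                                         else float(c["portion_red_exceeds"])))
                for name, c in section.items()}
    return TrafficLightThresholds(food=table(d["food"]), drink=table(d["drink"]))


def classify_nutrient(value_per_100: float, nutrient: Nutrient, is_drink: bool,
                      thresholds: TrafficLightThresholds = DEFAULT_THRESHOLDS) -> Color:
    """Colour for one nutrient amount on its per-100 basis."""
    if value_per_100 < 0:
        raise ValueError(f"nutrient value must be >= 0, got {value_per_100}")
    c = thresholds.cutoffs(Nutrient(nutrient), is_drink)
    if value_per_100 <= c.green_max:
        return Color.GREEN
    if value_per_100 > c.red_exceeds:
        return Color.RED
    return Color.AMBER


def _panel_values(record: FoodRecord) -> dict[Nutrient, float]:
    p = record.panel
    return {
        Nutrient.TOTAL_FAT: p.total_fat_g,
        Nutrient.SATURATED_FAT: p.saturated_fat_g,
        Nutrient.SUGARS: p.sugars_g,
        Nutrient.SALT: salt_from_sodium(p.sodium_mg),
    }


def label_record(record: FoodRecord,
                 thresholds: TrafficLightThresholds = DEFAULT_THRESHOLDS,
                 apply_portion_criteria: bool = True) -> TrafficLightLabel:
    """Traffic-light label for one record.

    Each nutrient is classified on the per-100 basis. For foods with a known
    serving size, a nutrient is upgraded to red when its per-portion amount
    strictly exceeds the portion threshold — the override only ever moves a
    colour toward red, never away.
    """
    values = _panel_values(record)
    colors = {n: classify_nutrient(v, n, record.is_beverage, thresholds)
              for n, v in values.items()}

    portion_red: set[Nutrient] = set()
    if (apply_portion_criteria and not record.is_beverage
            and record.serving_size_g is not None):
        for n, v in values.items():
            cut = thresholds.cutoffs(n, is_drink=False)
            # single division keeps e.g. 10 g/100 g at a 210 g serving at exactly 21 g
            per_portion = v * record.serving_size_g / 100.0
            if cut.portion_red_exceeds is not None and per_portion > cut.portion_red_exceeds:
                if colors[n] is not Color.RED:
                    portion_red.add(n)
                colors[n] = Color.RED

    return TrafficLightLabel(
        colors=colors,
        energy_kj_display=record.panel.energy_kj,
        basis="per100ml_drink" if record.is_beverage else "per100g_food",
        portion_red_applied=frozenset(portion_red),
    )
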