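"""FSANZ-style nutrient profiling score (NPSC).

Foods are scored in three categories: 1 — beverages; 2 — all other foods;
3 — edible oils, oil spreads, margarine, butter, and cheeses with more than
320 mg calcium/100 g. Baseline points accrue for energy, saturated fat,
total sugars and sodium (caps 10/30/10/30); modifying points are subtracted
for fruit/vegetable/nut/legume content (V: one of 0, 1, 2, 5, 8), protein
(P: cap 5) and fiber (F: cap 2):

    final_score = baseline - V - P - F          (lower = healthier)

Point tables are configuration. The shipped defaults use the published
FSANZ increments (energy 335 kJ, saturated fat 1 g, sugars 4.5 g, sodium
90 mg, protein 1.6 g, fiber 0.9 g per point) with strict-exceed semantics:
a point is awarded for each table threshold the amount strictly exceeds.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

from .food_db import Category, FoodDatabase, FoodRecord, FvnlComposition, NutrientPanel

__all__ = [
    "NpscCategory",
    "StepTable",
    "FvnlLookup",
    "PointTables",
    "BaselineBreakdown",
    "NPSCScore",
    "default_point_tables",
    "determine_category",
    "baseline_points",
    "fvnl_percent",
    "modifying_points",
    "score_record",
]

#: calcium cutoff (mg/100 g) above which cheese scores in category 3
CHEESE_CALCIUM_CUTOFF_MG = 320.0


class NpscCategory(IntEnum):
    BEVERAGES = 1
    OTHER_FOODS = 2
    OILS_SPREADS_CHEESE = 3


@dataclass(frozen=True)
class StepTable:
    """Monotone point table: points = number of thresholds strictly exceeded."""

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("step-table thresholds must be strictly increasing")

    @property
    def cap(self) -> int:
        return len(self.thresholds)

    def points(self, value: float) -> int:
        if value < 0:
            raise ValueError(f"nutrient amount must be >= 0, got {value}")
        # bisect_left counts thresholds strictly below value: equality with a
        # threshold does not award its point
        return bisect_left(self.thresholds, value)

    @staticmethod
    def uniform(increment: float, cap: int) -> "StepTable":
        return StepTable(tuple(increment * i for i in range(1, cap + 1)))


@dataclass(frozen=True)
class FvnlLookup:
    """fvnl% -> V points; values restricted to {0, 1, 2, 5, 8}."""

    steps: tuple[tuple[float, int], ...] = ((40.0, 1), (60.0, 2), (67.0, 5), (80.0, 8))

    def __post_init__(self) -> None:
        allowed = {0, 1, 2, 5, 8}
        if any(p not in allowed for _, p in self.steps):
            raise ValueError("V points must lie in {0, 1, 2, 5, 8}")
        pairs = list(self.steps)
        if any(b[0] <= a[0] or b[1] <= a[1] for a, b in zip(pairs, pairs[1:])):
            raise ValueError("fvnl lookup must be strictly increasing in both columns")

    def points(self, fvnl_pct: float) -> int:
        pts = 0
        for threshold, p in self.steps:
            if fvnl_pct > threshold:
                pts = p
        return pts


@dataclass(frozen=True)
class PointTables:
    """Full scoring configuration: baseline and modifying point tables."""

    energy: StepTable = field(default_factory=lambda: StepTable.uniform(335.0, 10))
    saturated_fat: StepTable = field(default_factory=lambda: StepTable.uniform(1.0, 30))
    sugars: StepTable = field(default_factory=lambda: StepTable.uniform(4.5, 10))
    sodium: StepTable = field(default_factory=lambda: StepTable.uniform(90.0, 30))
    protein: StepTable = field(default_factory=lambda: StepTable.uniform(1.6, 5))
    fiber: StepTable = field(default_factory=lambda: StepTable.uniform(0.9, 2))
    fvnl: FvnlLookup = field(default_factory=FvnlLookup)
    # FSANZ withholds protein points from high-baseline foods without high V
    protein_cap_rule_enabled: bool = False
    protein_cap_baseline_threshold: int = 13
    protein_cap_min_v_points: int = 5


def default_point_tables() -> PointTables:
    return PointTables()


def point_tables_from_dict(d: dict) -> PointTables:
    """Build point tables from a plain mapping (parsed YAML/JSON).

    Each baseline/modifying component takes either an explicit threshold list
    (``thresholds: [335, 670, ...]``) or a uniform rule
    (``increment: 335, cap: 10``); the V lookup takes
    ``fvnl: {steps: [[40, 1], [60, 2], [67, 5], [80, 8]]}``.
    """
    kwargs: dict = {}
    for name in ("energy", "saturated_fat", "sugars", "sodium", "protein", "fiber"):
        if name not in d:
            continue
        spec = d[name]
        if "thresholds" in spec:
            kwargs[name] = StepTable(tuple(float(t) for t in spec["thresholds"]))
        else:
            kwargs[name] = StepTable.uniform(float(spec["increment"]), int(spec["cap"]))
    if "fvnl" in d:
        kwargs["fvnl"] = FvnlLookup(tuple((float(t), int(p)) for t, p in d["fvnl"]["steps"]))
    for flag in ("protein_cap_rule_enabled", "protein_cap_baseline_threshold",
                 "protein_cap_min_v_points"):
        if flag in d:
            kwargs[flag] = d[flag]
    return PointTables(**kwargs)


@dataclass(frozen=True)
class BaselineBreakdown:
    energy: int
    saturated_fat: int
    sugars: int
    sodium: int

    @property
    def total(self) -> int:
        return self.energy + self.saturated_fat + self.sugars + self.sodium


@dataclass(frozen=True)
class NPSCScore:
    npsc_category: NpscCategory
    baseline: BaselineBreakdown
    v_points: int
    p_points: int
    f_points: int
    final_score: int
    imputed_inputs: frozenset = frozenset()

    def __post_init__(self) -> None:
        identity = self.baseline.total - self.v_points - self.p_points - self.f_points
        if self.final_score != identity:
            raise ValueError(f"final_score {self.final_score} != baseline - V - P - F = {identity}")

    def as_dict(self) -> dict:
        return {
            "npsc_category": int(self.npsc_category),
            "baseline_points": {
                "energy": self.baseline.energy,
                "saturated_fat": self.baseline.saturated_fat,
                "sugars": self.baseline.sugars,
                "sodium": self.baseline.sodium,
                "total": self.baseline.total,
            },
            "v_points": self.v_points,
            "p_points": self.p_points,
            "f_points": self.f_points,
            "final_score": self.final_score,
            "imputed_inputs": sorted(self.imputed_inputs),
        }


def determine_category(record: FoodRecord, categories: dict[str, Category]) -> NpscCategory:
    """Scoring category: beverages -> 1; oils/spreads and high-calcium cheese -> 3.

    Cheese needs a calcium value (observed or imputed); the cutoff is strict:
    calcium must exceed 320 mg/100 g for category 3.
    """
    cat = categories[record.category_id]
    if record.is_beverage or cat.is_beverage:
        return NpscCategory.BEVERAGES
    if cat.npsc_category3_member:
        if not cat.is_cheese:
            return NpscCategory.OILS_SPREADS_CHEESE
        calcium = record.panel.calcium_mg
        if calcium is None:
            raise ValueError(
                f"cheese record {record.upc} has no calcium value; impute before scoring")
        if calcium > CHEESE_CALCIUM_CUTOFF_MG:
            return NpscCategory.OILS_SPREADS_CHEESE
    return NpscCategory.OTHER_FOODS


def baseline_points(panel: NutrientPanel, npsc_category: NpscCategory,
                    tables: PointTables = PointTables()) -> BaselineBreakdown:
    """Energy / saturated fat / sugars / sodium points, each capped by its table."""
    return BaselineBreakdown(
        energy=tables.energy.points(panel.energy_kj),
        saturated_fat=tables.saturated_fat.points(panel.saturated_fat_g),
        sugars=tables.sugars.points(panel.sugars_g),
        sodium=tables.sodium.points(panel.sodium_mg),
    )


def fvnl_percent(c: FvnlComposition) -> float:
    """Overall fvnl percentage with concentrated components double-weighted:

        100 * (nonconc + 2*conc) / (nonconc + 2*conc + non_fvnl)
    """
    weighted = c.pct_nonconcentrated_fvnl + 2.0 * c.pct_concentrated_fvnl
    denom = weighted + c.pct_non_fvnl
    if denom == 0:
        raise ValueError("fvnl composition is all zero; percentage undefined")
    return 100.0 * weighted / denom


def modifying_points(panel: NutrientPanel, fvnl_pct: Optional[float],
                     npsc_category: NpscCategory,
                     tables: PointTables = PointTables(),
                     baseline_total: Optional[int] = None) -> tuple[int, int, int]:
    """(V, P, F) modifying points.

    When the protein-cap rule is enabled, P points are withheld if the
    baseline total exceeds the configured threshold and V points fall short.
    """
    v = tables.fvnl.points(fvnl_pct) if fvnl_pct is not None else 0
    p = tables.protein.points(panel.protein_g)
    if (tables.protein_cap_rule_enabled and baseline_total is not None
            and baseline_total > tables.protein_cap_baseline_threshold
            and v < tables.protein_cap_min_v_points):
        p = 0
    f = tables.fiber.points(panel.fiber_g) if panel.fiber_g is not None else 0
    return v, p, f


def score_record(record: FoodRecord, db: FoodDatabase,
                 tables: PointTables = PointTables()) -> NPSCScore:
    """Full score for one record; imputation must already have been applied.

    A record whose optional inputs are absent is treated conservatively:
    absent fiber and absent fvnl contribute zero modifying points (the
    imputation step makes missing values explicit and flags them first).
    """
    cat = determine_category(record, db.categories)
    base = baseline_points(record.panel, cat, tables)
    fvnl_pct: Optional[float] = None
    if record.panel.fvnl is not None:
        try:
            fvnl_pct = fvnl_percent(record.panel.fvnl)
        except ValueError:
            fvnl_pct = None
    v, p, f = modifying_points(record.panel, fvnl_pct, cat, tables,
                               baseline_total=base.total)
    return NPSCScore(
        npsc_category=cat,
        baseline=base,
        v_points=v,
        p_points=p,
        f_points=f,
        final_score=base.total - v - p - f,
        imputed_inputs=frozenset(record.imputed_fields),
    )
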