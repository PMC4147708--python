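"""Seeded synthetic food-composition databases for testing and demos.

The generator emulates the structure of a branded supermarket database —
category-organised SKUs with per-100 g/ml nutrient panels, barcode keys with
valid check digits, and the real missingness pattern of Australian labels:
fiber and calcium declared only on part of the range, fvnl composition never
declared (it is imputed from category defaults downstream). Category
profiles loosely mimic common supermarket shelves (bread, cheese, oils,
soft drinks, cereals ...) so that all three profiling categories and the
switch-excluded path are exercised. It makes no attempt to reproduce any
real market's nutrient distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .food_db import (Category, FoodDatabase, FoodRecord, FvnlComposition,
                      NutrientPanel, compute_check_digit)

__all__ = ["NutrientRanges", "CategoryProfile", "GeneratorConfig",
           "generate_database", "DEFAULT_PROFILES"]

SOFT_DRINK_MESSAGE = "Sugar-free drinks and water are healthier choices"


@dataclass(frozen=True)
class NutrientRanges:
    """Uniform (low, high) sampling bounds per nutrient, per 100 g/ml."""

    energy_kj: tuple[float, float]
    protein_g: tuple[float, float]
    total_fat_g: tuple[float, float]
    satfat_fraction: tuple[float, float]  # saturated fat as a fraction of total fat
    carbohydrate_g: tuple[float, float]
    sugars_fraction: tuple[float, float]  # sugars as a fraction of carbohydrate
    sodium_mg: tuple[float, float]
    fiber_g: tuple[float, float] = (0.0, 0.0)
    calcium_mg: Optional[tuple[float, float]] = None
    serving_size_g: tuple[float, float] = (30.0, 250.0)


@dataclass(frozen=True)
class CategoryProfile:
    """Template for one supermarket-style category."""

    name: str
    ranges: NutrientRanges
    is_beverage: bool = False
    fiber_possible: bool = True
    fvnl_possible: bool = False
    default_fvnl_pct: Optional[float] = None
    npsc_category3_member: bool = False
    is_cheese: bool = False
    switch_excluded: bool = False
    standard_message: Optional[str] = None


DEFAULT_PROFILES: tuple[CategoryProfile, ...] = (
    CategoryProfile(
        "bread", NutrientRanges((900, 1250), (7, 12), (1, 6), (0.15, 0.4),
                                (38, 55), (0.04, 0.15), (300, 600), (2, 8),
                                serving_size_g=(35, 90))),
    CategoryProfile(
        "breakfast-cereal", NutrientRanges((1400, 1700), (6, 12), (1, 10), (0.15, 0.5),
                                           (60, 85), (0.08, 0.45), (100, 600), (3, 12),
                                           serving_size_g=(30, 60)),
        fvnl_possible=True, default_fvnl_pct=5.0),
    CategoryProfile(
        "cheese", NutrientRanges((1200, 1800), (20, 28), (20, 35), (0.55, 0.72),
                                 (0.5, 5), (0.3, 0.9), (500, 1200), (0, 0),
                                 calcium_mg=(200, 900), serving_size_g=(20, 40)),
        fiber_possible=False, npsc_category3_member=True, is_cheese=True),
    CategoryProfile(
        "edible-oil", NutrientRanges((3300, 3700), (0, 0.5), (90, 100), (0.08, 0.6),
                                     (0, 0.5), (0, 0.5), (0, 10), (0, 0),
                                     serving_size_g=(10, 20)),
        fiber_possible=False, npsc_category3_member=True),
    CategoryProfile(
        "savoury-snacks", NutrientRanges((1900, 2300), (5, 10), (20, 35), (0.2, 0.5),
                                         (48, 65), (0.02, 0.12), (400, 1000), (2, 7),
                                         serving_size_g=(25, 50)),
        fvnl_possible=True, default_fvnl_pct=10.0),
    CategoryProfile(
        "canned-soup", NutrientRanges((150, 350), (1, 5), (0.5, 5), (0.2, 0.5),
                                      (4, 12), (0.1, 0.6), (250, 450), (0.5, 3),
                                      serving_size_g=(250, 300)),
        fvnl_possible=True, default_fvnl_pct=30.0),
    CategoryProfile(
        "eggs", NutrientRanges((550, 650), (12, 14), (9, 12), (0.28, 0.36),
                               (0.2, 2), (0.2, 0.8), (130, 160), (0, 0),
                               serving_size_g=(50, 60)),
        fiber_possible=False),
    # beverages (per 100 ml)
    CategoryProfile(
        "soft-drink-sugar", NutrientRanges((120, 200), (0, 0.2), (0, 0.2), (0, 0.5),
                                           (7, 12), (0.9, 1.0), (5, 40), (0, 0),
                                           serving_size_g=(250, 375)),
        is_beverage=True, fiber_possible=False,
        switch_excluded=True, standard_message=SOFT_DRINK_MESSAGE),
    CategoryProfile(
        "fruit-juice", NutrientRanges((140, 200), (0.2, 1), (0, 0.5), (0, 0.5),
                                      (8, 12), (0.85, 1.0), (2, 20), (0, 0.5),
                                      serving_size_g=(200, 300)),
        is_beverage=True, fvnl_possible=True, default_fvnl_pct=95.0),
    CategoryProfile(
        "milk", NutrientRanges((190, 300), (3.0, 4.0), (1, 4), (0.6, 0.7),
                               (4, 6.5), (0.85, 1.0), (35, 55), (0, 0),
                               calcium_mg=(100, 130), serving_size_g=(250, 300)),
        is_beverage=True, fiber_possible=False),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic database.

    Defaults mirror the real data-availability pattern: fvnl composition is
    never declared (rate 1.0); fiber and calcium are partially declared.
    """

    n_categories: int = 10
    products_per_category: tuple[int, int] = (15, 40)
    beverage_fraction: float = 0.3
    missing_fiber_rate: float = 0.3
    missing_calcium_rate: float = 0.3
    missing_fvnl_rate: float = 1.0
    n_excluded_categories: int = 1
    serving_size_rate: float = 0.8
    seed: int = 0
    profiles: tuple[CategoryProfile, ...] = field(default=DEFAULT_PROFILES)

    def __post_init__(self) -> None:
        for name in ("beverage_fraction", "missing_fiber_rate",
                     "missing_calcium_rate", "missing_fvnl_rate", "serving_size_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.products_per_category
        if self.n_categories < 1 or lo < 1 or hi < lo:
            raise ValueError("need n_categories >= 1 and a valid products_per_category range")
        if self.n_excluded_categories > self.n_categories:
            raise ValueError("more excluded categories requested than categories")


def _make_upc(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        payload = "93" + "".join(str(d) for d in rng.integers(0, 10, size=10))
        upc = payload + str(compute_check_digit(payload))
        if upc not in taken:
            taken.add(upc)
            return upc


def _pick_profiles(cfg: GeneratorConfig) -> list[CategoryProfile]:
    bev = [p for p in cfg.profiles if p.is_beverage]
    food = [p for p in cfg.profiles if not p.is_beverage]
    excluded = [p for p in bev if p.switch_excluded] or bev
    n_bev = int(round(cfg.beverage_fraction * cfg.n_categories))
    n_bev = min(max(n_bev, cfg.n_excluded_categories), cfg.n_categories)
    chosen: list[CategoryProfile] = []
    for i in range(cfg.n_excluded_categories):
        chosen.append(excluded[i % len(excluded)])
    for i in range(n_bev - cfg.n_excluded_categories):
        chosen.append(bev[i % len(bev)])
    for i in range(cfg.n_categories - n_bev):
        chosen.append(food[i % len(food)])
    return chosen


def generate_database(cfg: GeneratorConfig) -> FoodDatabase:
    """Deterministic synthetic database: same config and seed, same output."""
    rng = np.random.default_rng(cfg.seed)
    chosen = _pick_profiles(cfg)

    categories: dict[str, Category] = {}
    records: dict[str, FoodRecord] = {}
    taken: set[str] = set()

    for idx, prof in enumerate(chosen):
        cid = f"C{idx:03d}-{prof.name}"
        categories[cid] = Category(
            category_id=cid, name=prof.name, is_beverage=prof.is_beverage,
            fiber_possible=prof.fiber_possible, fvnl_possible=prof.fvnl_possible,
            default_fvnl_pct=prof.default_fvnl_pct,
            npsc_category3_member=prof.npsc_category3_member,
            is_cheese=prof.is_cheese, switch_excluded=prof.switch_excluded,
            standard_message=prof.standard_message,
        )
        lo, hi = cfg.products_per_category
        n = int(rng.integers(lo, hi + 1))
        r = prof.ranges
        for j in range(n):
            fat = float(rng.uniform(*r.total_fat_g))
            satfat = fat * float(rng.uniform(*r.satfat_fraction))
            carb = float(rng.uniform(*r.carbohydrate_g))
            sugars = carb * float(rng.uniform(*r.sugars_fraction))

            fiber = float(rng.uniform(*r.fiber_g)) if prof.fiber_possible else 0.0
            fiber_missing = rng.random() < cfg.missing_fiber_rate
            calcium = (float(rng.uniform(*r.calcium_mg))
                       if r.calcium_mg is not None else None)
            if calcium is not None and rng.random() < cfg.missing_calcium_rate:
                calcium = None

            fvnl = None
            fvnl_declared = rng.random() >= cfg.missing_fvnl_rate
            if fvnl_declared:
                if prof.fvnl_possible and prof.default_fvnl_pct is not None:
                    pct = float(np.clip(rng.normal(prof.default_fvnl_pct, 5.0), 0, 100))
                else:
                    pct = 0.0
                fvnl = FvnlComposition(pct, 0.0, 100.0 - pct)

            panel = NutrientPanel(
                energy_kj=float(rng.uniform(*r.energy_kj)),
                protein_g=float(rng.uniform(*r.protein_g)),
                total_fat_g=fat, saturated_fat_g=satfat,
                carbohydrate_g=carb, sugars_g=sugars,
                sodium_mg=float(rng.uniform(*r.sodium_mg)),
                fiber_g=None if fiber_missing else fiber,
                calcium_mg=calcium, fvnl=fvnl,
            )
            serving = (float(np.round(rng.uniform(*r.serving_size_g), 1))
                       if rng.random() < cfg.serving_size_rate else None)
            upc = _make_upc(rng, taken)
            records[upc] = FoodRecord(
                upc=upc, name=f"{prof.name} product {j + 1}",
                brand=f"Brand {int(rng.integers(1, 30))}",
                category_id=cid, is_beverage=prof.is_beverage,
                panel=panel, serving_size_g=serving,
            )

    db = FoodDatabase(records=records, categories=categories)
    db.validate()
    return db
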