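"""Fill missing fiber, calcium and fvnl values before profile scoring.

Fiber and calcium declarations are not mandatory on the Australian nutrition
panel, and fvnl composition is never declared, so a branded database has
gaps exactly where the profiling score needs inputs. The rules:

* fiber — categories that cannot contain fiber (eggs, oils, dairy milk) get
  0; otherwise the arithmetic mean of the observed fiber values in the
  record's category.
* calcium — needed only for cheese categories (the category-3 calcium gate);
  missing values get the category mean of observed calcium.
* fvnl — categories without appreciable fruit/vegetable content get 0%;
  otherwise the category's configured default percentage.

Every filled field is flagged; observed values pass through untouched.
Category means are computed once from observed values only — imputed values
never feed back into the means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .food_db import (Category, FoodDatabase, FoodRecord, FvnlComposition,
                      NutrientPanel, with_imputed)

__all__ = [
    "CategoryStats",
    "ImputationError",
    "compute_category_stats",
    "impute_record",
    "impute_database",
]


class ImputationError(Exception):
    """A required value is missing and no rule can supply it."""

    def __init__(self, upc: str, field: str, category_id: str, reason: str):
        self.upc, self.field, self.category_id = upc, field, category_id
        super().__init__(
            f"cannot impute {field} for record {upc} (category {category_id!r}): {reason}")


@dataclass(frozen=True)
class CategoryStats:
    """Per-category means over observed (declared) values only."""

    category_id: str
    fiber_mean: Optional[float]
    calcium_mean: Optional[float]
    n_fiber_observed: int
    n_calcium_observed: int


def compute_category_stats(db: FoodDatabase) -> dict[str, CategoryStats]:
    """Arithmetic means of observed fiber and calcium per category.

    Absent values are never counted as zero; a category with no observations
    for a nutrient has an undefined mean and a zero count.
    """
    stats: dict[str, CategoryStats] = {}
    for cid in db.categories:
        fibers = [r.panel.fiber_g for r in db.records_in_category(cid)
                  if r.panel.fiber_g is not None]
        calciums = [r.panel.calcium_mg for r in db.records_in_category(cid)
                    if r.panel.calcium_mg is not None]
        stats[cid] = CategoryStats(
            category_id=cid,
            fiber_mean=sum(fibers) / len(fibers) if fibers else None,
            calcium_mean=sum(calciums) / len(calciums) if calciums else None,
            n_fiber_observed=len(fibers),
            n_calcium_observed=len(calciums),
        )
    return stats


def impute_record(record: FoodRecord, category: Category,
                  stats: CategoryStats) -> tuple[FoodRecord, frozenset]:
    """Fill the record's missing fields; return it with the imputed-field set.

    Idempotent: a record with no missing fields is returned unchanged with an
    empty imputed set.
    """
    panel = record.panel
    imputed: set[str] = set()
    updates: dict = {}

    if panel.fiber_g is None:
        if not category.fiber_possible:
            updates["fiber_g"] = 0.0
        elif stats.fiber_mean is not None:
            updates["fiber_g"] = stats.fiber_mean
        else:
            raise ImputationError(record.upc, "fiber_g", category.category_id,
                                  "category allows fiber but has no observed values")
        imputed.add("fiber_g")

    if panel.calcium_mg is None and category.is_cheese:
        if stats.calcium_mean is not None:
            updates["calcium_mg"] = stats.calcium_mean
        else:
            raise ImputationError(record.upc, "calcium_mg", category.category_id,
                                  "cheese category has no observed calcium values")
        imputed.add("calcium_mg")

    if panel.fvnl is None:
        if not category.fvnl_possible:
            updates["fvnl"] = FvnlComposition(0.0, 0.0, 100.0)
        elif category.default_fvnl_pct is not None:
            pct = category.default_fvnl_pct
            updates["fvnl"] = FvnlComposition(pct, 0.0, 100.0 - pct)
        else:
            raise ImputationError(record.upc, "fvnl", category.category_id,
                                  "category allows fvnl but has no default percentage")
        imputed.add("fvnl")

    if not updates:
        return record, frozenset()
    new_panel = replace(panel, **updates)
    return with_imputed(record, new_panel, imputed), frozenset(imputed)


def impute_database(db: FoodDatabase) -> tuple[FoodDatabase, list[tuple[str, str, str]]]:
    """Impute every record; return the new database and a report.

    Report rows are (upc, field, source) with source one of
    ``zero-rule``, ``category-mean``, ``category-default``.
    """
    stats = compute_category_stats(db)
    report: list[tuple[str, str, str]] = []
    new_records: dict[str, FoodRecord] = {}
    for upc, rec in db.records.items():
        cat = db.category_of(rec)
        new_rec, imputed = impute_record(rec, cat, stats[cat.category_id])
        new_records[upc] = new_rec
        for f in sorted(imputed):
            if f == "fiber_g":
                source = "zero-rule" if not cat.fiber_possible else "category-mean"
            elif f == "calcium_mg":
                source = "category-mean"
            else:
                source = "zero-rule" if not cat.fvnl_possible else "category-default"
            report.append((upc, f, source))
    return FoodDatabase(records=new_records, categories=dict(db.categories)), report
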