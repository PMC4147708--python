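"""Barcode-keyed food composition database: domain types, validation, I/O.

One record per stock-keeping unit (SKU), keyed by its UPC/GTIN barcode.
Nutrients are stored per 100 g for foods and per 100 ml for beverages;
sodium is stored in mg and salt is derived at the standard factor
``salt_g = sodium_mg * 2.5 / 1000``. Optional nutrients (fiber, calcium,
fvnl composition) carry an explicit absent state (``None``) that is
distinct from zero — the imputation rules depend on that distinction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "NutrientPanel",
    "FvnlComposition",
    "FoodRecord",
    "Category",
    "FoodDatabase",
    "FoodDataError",
    "RowValidationError",
    "load_database",
    "save_database",
    "lookup_upc",
    "validate_check_digit",
    "compute_check_digit",
    "salt_from_sodium",
    "RECORD_COLUMNS",
    "CATEGORY_COLUMNS",
]

#: grams of salt equivalent per mg of sodium, times 1000 (NaCl is 2.5x sodium by mass)
SODIUM_TO_SALT = 2.5

RECORD_COLUMNS = [
    "upc", "name", "brand", "category_id", "is_beverage", "serving_size_g",
    "energy_kj", "protein_g", "total_fat_g", "saturated_fat_g",
    "carbohydrate_g", "sugars_g", "sodium_mg", "fiber_g", "calcium_mg",
    "pct_fvnl_nonconc", "pct_fvnl_conc", "pct_non_fvnl", "provenance",
]

CATEGORY_COLUMNS = [
    "category_id", "name", "is_beverage", "fiber_possible", "fvnl_possible",
    "default_fvnl_pct", "npsc_category3_member", "is_cheese",
    "switch_excluded", "standard_message",
]


class FoodDataError(Exception):
    """Base error for database loading/validation problems."""


class RowValidationError(FoodDataError):
    """A row-level problem, reported with its source row number and field."""

    def __init__(self, row: Optional[int], field_name: Optional[str], message: str):
        self.row = row
        self.field_name = field_name
        loc = f"row {row}" if row is not None else "record"
        if field_name:
            loc += f", field '{field_name}'"
        super().__init__(f"{loc}: {message}")


def salt_from_sodium(sodium_mg: float) -> float:
    """Convert sodium (mg/100 g or ml) to salt equivalent (g/100 g or ml)."""
    return sodium_mg * SODIUM_TO_SALT / 1000.0


@dataclass(frozen=True)
class FvnlComposition:
    """Fruit/vegetable/nut/legume make-up of a product, as percentages.

    Concentrated fvnl ingredients (pastes, dried fruit) are double-weighted
    when the overall fvnl percentage is computed for V points.
    """

    pct_nonconcentrated_fvnl: float
    pct_concentrated_fvnl: float
    pct_non_fvnl: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 100.0):
                raise RowValidationError(None, f.name, f"must be in [0, 100], got {v}")


@dataclass(frozen=True)
class NutrientPanel:
    """Nutrient declaration per 100 g (food) or per 100 ml (beverage).

    ``None`` means the value was not declared; it is never conflated with 0.
    """

    energy_kj: float
    protein_g: float
    total_fat_g: float
    saturated_fat_g: float
    carbohydrate_g: float
    sugars_g: float
    sodium_mg: float
    fiber_g: Optional[float] = None
    calcium_mg: Optional[float] = None
    fvnl: Optional[FvnlComposition] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "fvnl" or v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise RowValidationError(None, f.name, f"must be a finite number >= 0, got {v}")
        if self.saturated_fat_g > self.total_fat_g + 1e-9:
            raise RowValidationError(
                None, "saturated_fat_g",
                f"saturated fat ({self.saturated_fat_g}) exceeds total fat ({self.total_fat_g})")
        if self.sugars_g > self.carbohydrate_g + 1e-9:
            raise RowValidationError(
                None, "sugars_g",
                f"sugars ({self.sugars_g}) exceed carbohydrate ({self.carbohydrate_g})")

    @property
    def salt_g(self) -> float:
        return salt_from_sodium(self.sodium_mg)

    def scaled(self, factor: float) -> "NutrientPanel":
        """Panel scaled by ``factor`` (e.g. serving_size/100 for per-portion)."""
        def s(v: Optional[float]) -> Optional[float]:
            return None if v is None else v * factor
        return NutrientPanel(
            energy_kj=self.energy_kj * factor,
            protein_g=self.protein_g * factor,
            total_fat_g=self.total_fat_g * factor,
            saturated_fat_g=self.saturated_fat_g * factor,
            carbohydrate_g=self.carbohydrate_g * factor,
            sugars_g=self.sugars_g * factor,
            sodium_mg=self.sodium_mg * factor,
            fiber_g=s(self.fiber_g),
            calcium_mg=s(self.calcium_mg),
            fvnl=self.fvnl,  # percentages are scale-invariant
        )


@dataclass(frozen=True)
class FoodRecord:
    """One SKU: identity, category membership, and its nutrient panel."""

    upc: str
    name: str
    brand: str
    category_id: str
    is_beverage: bool
    panel: NutrientPanel
    serving_size_g: Optional[float] = None
    provenance: str = "surveyed"
    imputed_fields: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.upc or not self.upc.isdigit():
            raise RowValidationError(None, "upc", f"must be a non-empty digit string, got {self.upc!r}")
        if self.serving_size_g is not None and self.serving_size_g <= 0:
            raise RowValidationError(None, "serving_size_g", f"must be > 0, got {self.serving_size_g}")
        if self.provenance not in ("surveyed", "crowdsourced"):
            raise RowValidationError(None, "provenance", f"unknown provenance {self.provenance!r}")

    @property
    def per_portion(self) -> Optional[NutrientPanel]:
        """Nutrients for one serving, when a serving size is known."""
        if self.serving_size_g is None:
            return None
        return self.panel.scaled(self.serving_size_g / 100.0)


@dataclass(frozen=True)
class Category:
    """Category-level flags that drive scoring, imputation and switching."""

    category_id: str
    name: str
    is_beverage: bool
    fiber_possible: bool = True
    fvnl_possible: bool = False
    default_fvnl_pct: Optional[float] = None
    npsc_category3_member: bool = False
    is_cheese: bool = False
    switch_excluded: bool = False
    standard_message: Optional[str] = None

    def __post_init__(self) -> None:
        if self.switch_excluded and not self.standard_message:
            raise RowValidationError(
                None, "standard_message",
                f"category {self.category_id!r} is switch_excluded but has no standard_message")
        if self.default_fvnl_pct is not None and not self.fvnl_possible:
            raise RowValidationError(
                None, "default_fvnl_pct",
                f"category {self.category_id!r} has a default fvnl%% but fvnl_possible is false")
        if self.default_fvnl_pct is not None and not (0 <= self.default_fvnl_pct <= 100):
            raise RowValidationError(None, "default_fvnl_pct", "must be in [0, 100]")


@dataclass
class FoodDatabase:
    """Validated record and category collections, keyed by upc / category_id."""

    records: dict[str, FoodRecord] = field(default_factory=dict)
    categories: dict[str, Category] = field(default_factory=dict)

    def validate(self) -> None:
        for upc, rec in self.records.items():
            if upc != rec.upc:
                raise FoodDataError(f"key {upc!r} does not match record upc {rec.upc!r}")
            if rec.category_id not in self.categories:
                raise RowValidationError(None, "category_id",
                                         f"record {upc}: unknown category {rec.category_id!r}")

    def category_of(self, record: FoodRecord) -> Category:
        return self.categories[record.category_id]

    def records_in_category(self, category_id: str) -> list[FoodRecord]:
        return [r for r in self.records.values() if r.category_id == category_id]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# barcode check digits (GTIN mod-10)

_GTIN_LENGTHS = (8, 12, 13, 14)


def compute_check_digit(payload: str) -> int:
    """Mod-10 check digit for the digits preceding it (rightmost weight 3)."""
    total = 0
    for i, ch in enumerate(reversed(payload)):
        weight = 3 if i % 2 == 0 else 1
        total += weight * int(ch)
    return (10 - total % 10) % 10


def validate_check_digit(upc: str) -> bool:
    """True iff the final digit is the GTIN mod-10 check digit of the rest."""
    if not upc.isdigit():
        raise ValueError(f"upc must be digits only, got {upc!r}")
    if len(upc) not in _GTIN_LENGTHS:
        raise ValueError(f"unsupported barcode length {len(upc)} (expected one of {_GTIN_LENGTHS})")
    return compute_check_digit(upc[:-1]) == int(upc[-1])


# ---------------------------------------------------------------------------
# lookup

def lookup_upc(db: FoodDatabase, upc: str) -> Optional[FoodRecord]:
    """Exact-match lookup; ``None`` signals not-found (the crowdsource path)."""
    if not upc or not upc.isdigit():
        raise ValueError(f"upc must be a non-empty digit string, got {upc!r}")
    return db.records.get(upc)


# ---------------------------------------------------------------------------
# CSV / JSON I/O.  Empty CSV cell == absent value, never zero.

def _parse_float(val, row: int, name: str) -> Optional[float]:
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return None
    try:
        return float(val)
    except (TypeError, ValueError):
        raise RowValidationError(row, name, f"not a number: {val!r}") from None


def _parse_bool(val, row: int, name: str) -> bool:
    if isinstance(val, bool):
        return val
    s = str(val).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise RowValidationError(row, name, f"not a boolean: {val!r}")


def _record_from_mapping(m: dict, row: int) -> FoodRecord:
    def num(name, required=False):
        v = _parse_float(m.get(name), row, name)
        if required and v is None:
            raise RowValidationError(row, name, "required nutrient is missing")
        return v

    nonc = num("pct_fvnl_nonconc")
    conc = num("pct_fvnl_conc")
    nonf = num("pct_non_fvnl")
    fvnl = None
    if any(v is not None for v in (nonc, conc, nonf)):
        fvnl = FvnlComposition(nonc or 0.0, conc or 0.0, nonf or 0.0)

    try:
        panel = NutrientPanel(
            energy_kj=num("energy_kj", required=True),
            protein_g=num("protein_g", required=True),
            total_fat_g=num("total_fat_g", required=True),
            saturated_fat_g=num("saturated_fat_g", required=True),
            carbohydrate_g=num("carbohydrate_g", required=True),
            sugars_g=num("sugars_g", required=True),
            sodium_mg=num("sodium_mg", required=True),
            fiber_g=num("fiber_g"),
            calcium_mg=num("calcium_mg"),
            fvnl=fvnl,
        )
        upc = m.get("upc")
        upc = "" if upc is None else str(upc).strip()
        return FoodRecord(
            upc=upc,
            name=str(m.get("name") or ""),
            brand=str(m.get("brand") or ""),
            category_id=str(m.get("category_id") or ""),
            is_beverage=_parse_bool(m.get("is_beverage"), row, "is_beverage"),
            panel=panel,
            serving_size_g=num("serving_size_g"),
            provenance=str(m.get("provenance") or "surveyed"),
        )
    except RowValidationError as e:
        if e.row is None:
            raise RowValidationError(row, e.field_name, str(e).split(": ", 1)[-1]) from None
        raise


def _category_from_mapping(m: dict, row: int) -> Category:
    msg = m.get("standard_message")
    if msg is not None and (msg == "" or (isinstance(msg, float) and math.isnan(msg))):
        msg = None
    try:
        return Category(
            category_id=str(m.get("category_id") or ""),
            name=str(m.get("name") or ""),
            is_beverage=_parse_bool(m.get("is_beverage"), row, "is_beverage"),
            fiber_possible=_parse_bool(m.get("fiber_possible", True), row, "fiber_possible"),
            fvnl_possible=_parse_bool(m.get("fvnl_possible", False), row, "fvnl_possible"),
            default_fvnl_pct=_parse_float(m.get("default_fvnl_pct"), row, "default_fvnl_pct"),
            npsc_category3_member=_parse_bool(m.get("npsc_category3_member", False), row,
                                              "npsc_category3_member"),
            is_cheese=_parse_bool(m.get("is_cheese", False), row, "is_cheese"),
            switch_excluded=_parse_bool(m.get("switch_excluded", False), row, "switch_excluded"),
            standard_message=None if msg is None else str(msg),
        )
    except RowValidationError as e:
        if e.row is None:
            raise RowValidationError(row, e.field_name, str(e).split(": ", 1)[-1]) from None
        raise


def _read_table(path: Path, key: str) -> list[dict]:
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = payload[key] if isinstance(payload, dict) else payload
        return list(rows)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [{k: (None if v == "" else v) for k, v in row.items()}
            for row in df.to_dict(orient="records")]


def load_database(records_path, categories_path) -> FoodDatabase:
    """Load and validate a database from CSV or JSON files.

    Rows violating invariants are rejected with row-level diagnostics
    (1-based data row numbers). Duplicate barcodes name every offending row.
    """
    records_path, categories_path = Path(records_path), Path(categories_path)
    for p in (records_path, categories_path):
        if not p.exists():
            raise FileNotFoundError(p)

    categories: dict[str, Category] = {}
    for i, m in enumerate(_read_table(categories_path, "categories"), start=1):
        cat = _category_from_mapping(m, i)
        if cat.category_id in categories:
            raise RowValidationError(i, "category_id", f"duplicate category_id {cat.category_id!r}")
        categories[cat.category_id] = cat

    records: dict[str, FoodRecord] = {}
    seen_rows: dict[str, int] = {}
    for i, m in enumerate(_read_table(records_path, "records"), start=1):
        rec = _record_from_mapping(m, i)
        if rec.upc in records:
            raise RowValidationError(
                i, "upc",
                f"duplicate upc {rec.upc!r} on rows {seen_rows[rec.upc]} and {i}")
        if rec.category_id not in categories:
            raise RowValidationError(i, "category_id", f"unknown category_id {rec.category_id!r}")
        records[rec.upc] = rec
        seen_rows[rec.upc] = i

    db = FoodDatabase(records=records, categories=categories)
    db.validate()
    return db


def _record_to_mapping(rec: FoodRecord) -> dict:
    p = rec.panel
    fv = p.fvnl
    return {
        "upc": rec.upc, "name": rec.name, "brand": rec.brand,
        "category_id": rec.category_id, "is_beverage": rec.is_beverage,
        "serving_size_g": rec.serving_size_g,
        "energy_kj": p.energy_kj, "protein_g": p.protein_g,
        "total_fat_g": p.total_fat_g, "saturated_fat_g": p.saturated_fat_g,
        "carbohydrate_g": p.carbohydrate_g, "sugars_g": p.sugars_g,
        "sodium_mg": p.sodium_mg, "fiber_g": p.fiber_g, "calcium_mg": p.calcium_mg,
        "pct_fvnl_nonconc": None if fv is None else fv.pct_nonconcentrated_fvnl,
        "pct_fvnl_conc": None if fv is None else fv.pct_concentrated_fvnl,
        "pct_non_fvnl": None if fv is None else fv.pct_non_fvnl,
        "provenance": rec.provenance,
    }


def _category_to_mapping(cat: Category) -> dict:
    return {
        "category_id": cat.category_id, "name": cat.name,
        "is_beverage": cat.is_beverage, "fiber_possible": cat.fiber_possible,
        "fvnl_possible": cat.fvnl_possible, "default_fvnl_pct": cat.default_fvnl_pct,
        "npsc_category3_member": cat.npsc_category3_member, "is_cheese": cat.is_cheese,
        "switch_excluded": cat.switch_excluded, "standard_message": cat.standard_message,
    }


def save_database(db: FoodDatabase, records_path, categories_path,
                  format: str = "csv") -> None:
    """Write the database; a subsequent load reproduces it field-for-field."""
    records_path, categories_path = Path(records_path), Path(categories_path)
    rec_rows = [_record_to_mapping(r) for r in db.records.values()]
    cat_rows = [_category_to_mapping(c) for c in db.categories.values()]
    if format == "json":
        records_path.write_text(json.dumps({"records": rec_rows}, indent=1))
        categories_path.write_text(json.dumps({"categories": cat_rows}, indent=1))
    elif format == "csv":
        pd.DataFrame(rec_rows, columns=RECORD_COLUMNS).to_csv(records_path, index=False)
        pd.DataFrame(cat_rows, columns=CATEGORY_COLUMNS).to_csv(categories_path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def with_imputed(record: FoodRecord, panel: NutrientPanel,
                 imputed: Iterable[str]) -> FoodRecord:
    """Copy of ``record`` with a filled panel and its imputed-field set."""
    return replace(record, panel=panel,
                   imputed_fields=record.imputed_fields | frozenset(imputed))
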