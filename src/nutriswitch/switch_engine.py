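"""Within-category "switch to a healthier product" recommendations.

Given a scanned barcode, the engine lists alternatives from the same food
category with a strictly more favourable key — a lower nutrient-profile
score in the default mode, or strictly less sodium in salt mode (for users
targeting dietary salt; ties broken by profile score). Some categories are
excluded from switching and instead carry a standard advisory message
(e.g. sugar-sweetened soft drinks).

``ScoredDatabase.prepare`` runs imputation and scores/labels every record
once; ``scan`` then composes label + score + switch result for a barcode,
or yields a crowdsource prompt when the barcode is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .food_db import FoodDatabase, FoodRecord, lookup_upc
from .imputation import impute_database
from .npsc import NPSCScore, PointTables, score_record
from .traffic_lights import (DEFAULT_THRESHOLDS, TrafficLightLabel,
                             TrafficLightThresholds, label_record)

__all__ = [
    "Mode",
    "SwitchResult",
    "ScanOutcome",
    "CrowdsourcePrompt",
    "ScoredDatabase",
    "recommend",
    "scan",
]

MODES = ("npsc", "salt")


@dataclass(frozen=True)
class SwitchResult:
    """Ranked healthier alternatives, or a category's standard message."""

    query_upc: str
    mode: str
    alternatives: tuple[tuple[FoodRecord, NPSCScore, TrafficLightLabel], ...]
    standard_message: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "query_upc": self.query_upc,
            "mode": self.mode,
            "standard_message": self.standard_message,
            "alternatives": [
                {"upc": r.upc, "name": r.name, "brand": r.brand,
                 "final_score": s.final_score, "sodium_mg": r.panel.sodium_mg,
                 "label": lab.as_dict()}
                for r, s, lab in self.alternatives
            ],
        }


@dataclass(frozen=True)
class CrowdsourcePrompt:
    """Unknown barcode: ask the user for front-of-pack, panel and ingredient photos."""

    upc: str
    requested_photos: tuple[str, ...] = ("front_of_pack", "nip", "ingredients")


@dataclass(frozen=True)
class ScanOutcome:
    upc: str
    label: TrafficLightLabel
    score: NPSCScore
    switch: SwitchResult


@dataclass
class ScoredDatabase:
    """A database with imputation applied and every record scored and labelled."""

    db: FoodDatabase
    scores: dict[str, NPSCScore]
    labels: dict[str, TrafficLightLabel]
    imputation_report: list = field(default_factory=list)

    @classmethod
    def prepare(cls, db: FoodDatabase, tables: PointTables = PointTables(),
                thresholds: TrafficLightThresholds = DEFAULT_THRESHOLDS) -> "ScoredDatabase":
        imputed_db, report = impute_database(db)
        scores = {upc: score_record(rec, imputed_db, tables)
                  for upc, rec in imputed_db.records.items()}
        labels = {upc: label_record(rec, thresholds)
                  for upc, rec in imputed_db.records.items()}
        return cls(db=imputed_db, scores=scores, labels=labels, imputation_report=report)


def _sort_key(scored: ScoredDatabase, mode: str):
    if mode == "npsc":
        return lambda r: (scored.scores[r.upc].final_score, r.name, r.upc)
    # salt mode ranks primarily by sodium, then profile score
    return lambda r: (r.panel.sodium_mg, scored.scores[r.upc].final_score, r.name, r.upc)


def _strictly_better(scored: ScoredDatabase, candidate: FoodRecord,
                     query: FoodRecord, mode: str) -> bool:
    if mode == "npsc":
        return scored.scores[candidate.upc].final_score < scored.scores[query.upc].final_score
    return candidate.panel.sodium_mg < query.panel.sodium_mg


def recommend(scored: ScoredDatabase, upc: str, mode: str = "npsc",
              max_results: int = 10) -> SwitchResult:
    """Healthier same-category alternatives for a known barcode.

    Returns at most ``max_results`` records with a strictly better key,
    sorted ascending; equal-key products are never offered (a lateral move
    is not a switch). Excluded categories yield the standard message and an
    empty list.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    query = lookup_upc(scored.db, upc)
    if query is None:
        raise KeyError(upc)
    category = scored.db.category_of(query)
    if category.switch_excluded:
        return SwitchResult(query_upc=upc, mode=mode, alternatives=(),
                            standard_message=category.standard_message)

    candidates = [r for r in scored.db.records_in_category(query.category_id)
                  if r.upc != upc and _strictly_better(scored, r, query, mode)]
    candidates.sort(key=_sort_key(scored, mode))
    top = candidates[:max_results]
    return SwitchResult(
        query_upc=upc, mode=mode,
        alternatives=tuple((r, scored.scores[r.upc], scored.labels[r.upc]) for r in top),
    )


def scan(scored: ScoredDatabase, upc: str, mode: str = "npsc",
         max_results: int = 10):
    """Full scan flow: label + score + switch for a known barcode,
    or a :class:`CrowdsourcePrompt` when the barcode is not in the database.
    """
    record = lookup_upc(scored.db, upc)
    if record is None:
        return CrowdsourcePrompt(upc=upc)
    return ScanOutcome(
        upc=upc,
        label=scored.labels[upc],
        score=scored.scores[upc],
        switch=recommend(scored, upc, mode=mode, max_results=max_results),
    )
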