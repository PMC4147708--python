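"""Crowdsourced intake of barcodes missing from the database.

When a scan misses, the user supplies three labelled photographs — front of
pack, the nutrition information panel (NIP), and the ingredients list.
Submissions queue as *pending*; a data-entry step (external to this package,
modelled as attaching a validated record) advances them to *entered*, and a
periodic merge folds entered records into a new database release. A
crowdsourced record colliding with an existing barcode is skipped and
reported, never silently overwritten.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from .food_db import FoodDatabase, FoodRecord, _record_from_mapping, _record_to_mapping

__all__ = [
    "Submission",
    "SubmissionQueue",
    "MergeReport",
    "record_missing_scan",
    "merge_submissions",
]

PHOTO_SLOTS = ("front_of_pack", "nip", "ingredients")
STATUSES = ("pending", "entered", "merged", "rejected")


@dataclass(frozen=True)
class Submission:
    upc: str
    photo_refs: dict[str, str] = field(default_factory=dict)  # slot -> opaque URI
    submitted_at: str = ""
    status: str = "pending"
    entered_record: Optional[FoodRecord] = None

    def __post_init__(self) -> None:
        if not self.upc.isdigit():
            raise ValueError(f"upc must be digits only, got {self.upc!r}")
        unknown = set(self.photo_refs) - set(PHOTO_SLOTS)
        if unknown:
            raise ValueError(f"unknown photo slots {sorted(unknown)}; expected {PHOTO_SLOTS}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "merged" and self.entered_record is None:
            raise ValueError("a merged submission must carry its entered record")


class SubmissionQueue:
    """Ordered queue of submissions, persisted as JSON lines."""

    def __init__(self, submissions: Optional[list[Submission]] = None):
        self.submissions: list[Submission] = list(submissions or [])

    def pending_for(self, upc: str) -> Optional[int]:
        for i, s in enumerate(self.submissions):
            if s.upc == upc and s.status == "pending":
                return i
        return None

    def enter_record(self, upc: str, record: FoodRecord) -> Submission:
        """Attach a transcribed record to the pending submission for ``upc``."""
        if record.upc != upc:
            raise ValueError(f"record upc {record.upc!r} does not match submission {upc!r}")
        i = self.pending_for(upc)
        if i is None:
            raise KeyError(f"no pending submission for upc {upc}")
        entered = replace(self.submissions[i], status="entered",
                          entered_record=replace(record, provenance="crowdsourced"))
        self.submissions[i] = entered
        return entered

    def save(self, path) -> None:
        lines = []
        for s in self.submissions:
            lines.append(json.dumps({
                "upc": s.upc, "photo_refs": s.photo_refs,
                "submitted_at": s.submitted_at, "status": s.status,
                "entered_record": (None if s.entered_record is None
                                   else _record_to_mapping(s.entered_record)),
            }))
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    @classmethod
    def load(cls, path) -> "SubmissionQueue":
        subs = []
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            m = json.loads(line)
            rec = m.get("entered_record")
            subs.append(Submission(
                upc=m["upc"], photo_refs=dict(m.get("photo_refs") or {}),
                submitted_at=m.get("submitted_at", ""), status=m.get("status", "pending"),
                entered_record=None if rec is None else _record_from_mapping(rec, i),
            ))
        return cls(subs)


@dataclass(frozen=True)
class MergeReport:
    added: int
    skipped: int
    skipped_upcs: tuple[str, ...] = ()


def record_missing_scan(queue: SubmissionQueue, db: FoodDatabase, upc: str,
                        photo_refs: Optional[dict[str, str]] = None,
                        now: Optional[str] = None) -> Submission:
    """Queue a submission for an unknown barcode.

    A second scan of the same unknown barcode coalesces into the existing
    pending submission (photo references are unioned). A barcode already in
    the database is rejected.
    """
    if upc in db.records:
        raise ValueError(f"upc {upc} is already in the database; nothing to crowdsource")
    photo_refs = dict(photo_refs or {})
    when = now or datetime.now(timezone.utc).isoformat(timespec="seconds")
    i = queue.pending_for(upc)
    if i is not None:
        existing = queue.submissions[i]
        merged_refs = {**existing.photo_refs, **photo_refs}
        coalesced = replace(existing, photo_refs=merged_refs)
        queue.submissions[i] = coalesced
        return coalesced
    sub = Submission(upc=upc, photo_refs=photo_refs, submitted_at=when)
    queue.submissions.append(sub)
    return sub


def merge_submissions(db: FoodDatabase,
                      queue: SubmissionQueue) -> tuple[FoodDatabase, MergeReport]:
    """Fold entered submissions into a new database release.

    Entered records with fresh barcodes are added and their submissions
    advance to *merged*; collisions with existing barcodes are skipped and
    reported. Idempotent: merging the same queue again changes nothing.
    """
    new_records = dict(db.records)
    added, skipped = 0, []
    for i, sub in enumerate(queue.submissions):
        if sub.status != "entered" or sub.entered_record is None:
            continue
        rec = sub.entered_record
        if rec.upc in new_records:
            skipped.append(rec.upc)
            continue
        if rec.category_id not in db.categories:
            skipped.append(rec.upc)
            continue
        new_records[rec.upc] = rec
        queue.submissions[i] = replace(sub, status="merged")
        added += 1
    new_db = FoodDatabase(records=new_records, categories=dict(db.categories))
    new_db.validate()
    return new_db, MergeReport(added=added, skipped=len(skipped),
                               skipped_upcs=tuple(skipped))
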