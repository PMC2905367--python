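"""Minimotif annotation records, CSV round-trip, cloning, and paper review
status tracking.

A :class:`MinimotifRecord` captures one annotation under the structured
minimotif syntax: the motif itself (a literal peptide or a consensus such
as ``[RK]xx[RK]``), the source protein accession and the 1-based position
of the first motif residue, the activity (GO-style accession + label), the
binding/target partner, an optional post-translational modification
(PSI-MOD-style accession + label), whether the defining experiment used a
peptide or the full-length protein, and supporting metadata.

Review tracking is an append-only history of :class:`ReviewEvent` entries;
each event names the annotator and one of the seven closed paper statuses.
Persistence is flat-file: records as RFC-4180 CSV (and a JSON-lines store),
histories as JSON-lines — the relational layer of the original curation
system is deliberately out of scope, but the data model is preserved so a
database backend could sit behind the same operations.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Sequence

__all__ = [
    "AnnotationError",
    "EXPERIMENT_SOURCES",
    "PAPER_STATUSES",
    "CSV_HEADER",
    "MinimotifRecord",
    "ReviewEvent",
    "clone_record",
    "update_status",
    "latest_status",
    "export_csv",
    "import_csv",
    "sort_records",
    "read_history",
    "write_history",
    "read_records_jsonl",
    "write_records_jsonl",
]


class AnnotationError(ValueError):
    """Invalid annotation content or malformed persisted data."""


#: The two admissible experimental sources of a minimotif definition.
EXPERIMENT_SOURCES = ("peptide", "full-length protein")

#: The closed set of paper tracking statuses.
PAPER_STATUSES = (
    "not reviewed",
    "reviewed no minimotifs",
    "reviewed for some minimotifs",
    "reviewed for all minimotifs",
    "group review",
    "no electronic version",
    "minimotif present but not annotated",
)

#: Default status of a newly added paper.
DEFAULT_STATUS = "not reviewed"

CSV_HEADER = [
    "motif",
    "source_accession",
    "position",
    "activity_id",
    "activity_label",
    "target",
    "modification_id",
    "modification_label",
    "experiment_source",
    "techniques",
    "structure_accessions",
    "comments",
    "pmid",
]

_LIST_SEP = ";"


def _check_list(name: str, items: Sequence[str]) -> tuple[str, ...]:
    for item in items:
        if _LIST_SEP in item:
            raise AnnotationError(
                f"{name} items may not contain {_LIST_SEP!r}: {item!r}"
            )
    return tuple(items)


@dataclass(frozen=True)
class MinimotifRecord:
    """One minimotif annotation.

    ``position`` is the 1-based index of the first minimotif residue in the
    source protein, or ``None`` for consensus-only entries.  Controlled
    vocabulary terms are stored as opaque accession+label pairs, validated
    for prefix format only (``GO:`` / ``MOD:``), never resolved online.
    """

    motif: str
    source_accession: str
    pmid: str
    position: int | None = None
    activity_id: str = ""
    activity_label: str = ""
    target: str = ""
    modification_id: str = ""
    modification_label: str = ""
    experiment_source: str = "peptide"
    techniques: tuple[str, ...] = ()
    structure_accessions: tuple[str, ...] = ()
    comments: str = ""

    def __post_init__(self) -> None:
        if not self.pmid:
            raise AnnotationError("record requires a non-empty pmid")
        if self.position is not None and self.position < 1:
            raise AnnotationError("position must be >= 1 when present")
        if self.experiment_source not in EXPERIMENT_SOURCES:
            raise AnnotationError(
                f"experiment_source must be one of {EXPERIMENT_SOURCES}, "
                f"got {self.experiment_source!r}"
            )
        if self.activity_id and not self.activity_id.startswith("GO:"):
            raise AnnotationError(
                f"activity_id must carry a 'GO:' prefix, got {self.activity_id!r}"
            )
        if self.modification_id and not self.modification_id.startswith("MOD:"):
            raise AnnotationError(
                f"modification_id must carry a 'MOD:' prefix, "
                f"got {self.modification_id!r}"
            )
        object.__setattr__(
            self, "techniques", _check_list("techniques", self.techniques)
        )
        object.__setattr__(
            self,
            "structure_accessions",
            _check_list("structure_accessions", self.structure_accessions),
        )


@dataclass(frozen=True)
class ReviewEvent:
    """One append-only review history entry for a paper."""

    pmid: str
    annotator: str
    status: str
    timestamp: datetime

    def __post_init__(self) -> None:
        if self.status not in PAPER_STATUSES:
            raise AnnotationError(
                f"unknown status {self.status!r}; valid statuses are: "
                + ", ".join(PAPER_STATUSES)
            )


def clone_record(record: MinimotifRecord) -> MinimotifRecord:
    """Copy a record with the motif sequence and position cleared.

    Every other attribute is preserved — the intended use is fast entry of
    families of similar minimotifs from high-throughput papers.  The input
    record is not modified.
    """
    return replace(record, motif="", position=None)


def _normalize_status(status: str) -> str:
    folded = status.strip().lower()
    if folded not in PAPER_STATUSES:
        raise AnnotationError(
            f"unknown status {status!r}; valid statuses are: "
            + ", ".join(PAPER_STATUSES)
        )
    return folded


def update_status(
    history: Sequence[ReviewEvent],
    pmid: str,
    annotator: str,
    status: str,
    timestamp: datetime | None = None,
) -> list[ReviewEvent]:
    """Append one review event; returns a new history, input untouched.

    Status matching is case-insensitive against the closed vocabulary.
    Timestamps must be non-decreasing within a paper's history.
    """
    status = _normalize_status(status)
    if timestamp is None:
        timestamp = datetime.now(timezone.utc)
    last = [e for e in history if e.pmid == pmid]
    if last and timestamp < last[-1].timestamp:
        raise AnnotationError(
            f"timestamp for {pmid} precedes the paper's latest review event"
        )
    return list(history) + [ReviewEvent(pmid, annotator, status, timestamp)]


def latest_status(history: Sequence[ReviewEvent], pmid: str) -> str:
    """Current status of a paper; unreviewed papers report the default."""
    events = [e for e in history if e.pmid == pmid]
    return events[-1].status if events else DEFAULT_STATUS


def export_csv(records: Iterable[MinimotifRecord]) -> str:
    """Serialise records under the documented CSV schema (RFC-4180)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(CSV_HEADER)
    for rec in records:
        writer.writerow(
            [
                rec.motif,
                rec.source_accession,
                "" if rec.position is None else str(rec.position),
                rec.activity_id,
                rec.activity_label,
                rec.target,
                rec.modification_id,
                rec.modification_label,
                rec.experiment_source,
                _LIST_SEP.join(rec.techniques),
                _LIST_SEP.join(rec.structure_accessions),
                rec.comments,
                rec.pmid,
            ]
        )
    return buf.getvalue()


def import_csv(text: str) -> list[MinimotifRecord]:
    """Read records back from the CSV schema; errors name the failing row."""
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise AnnotationError("empty CSV: missing header row") from None
    if header != CSV_HEADER:
        raise AnnotationError(
            f"unexpected CSV header; expected {','.join(CSV_HEADER)}"
        )
    records: list[MinimotifRecord] = []
    for rowno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(CSV_HEADER):
            raise AnnotationError(
                f"row {rowno}: expected {len(CSV_HEADER)} fields, got {len(row)}"
            )
        try:
            position = int(row[2]) if row[2] else None
            records.append(
                MinimotifRecord(
                    motif=row[0],
                    source_accession=row[1],
                    position=position,
                    activity_id=row[3],
                    activity_label=row[4],
                    target=row[5],
                    modification_id=row[6],
                    modification_label=row[7],
                    experiment_source=row[8],
                    techniques=tuple(x for x in row[9].split(_LIST_SEP) if x),
                    structure_accessions=tuple(
                        x for x in row[10].split(_LIST_SEP) if x
                    ),
                    comments=row[11],
                    pmid=row[12],
                )
            )
        except (AnnotationError, ValueError) as exc:
            raise AnnotationError(f"row {rowno}: {exc}") from exc
    return records


_SORT_KEYS = ("pmid", "position", "activity", "target", "source_accession")


def sort_records(
    records: Sequence[MinimotifRecord], key: str
) -> list[MinimotifRecord]:
    """Stable sort by one attribute; records lacking the attribute sort last."""
    if key not in _SORT_KEYS:
        raise AnnotationError(
            f"unknown sort key {key!r}; valid keys are: {', '.join(_SORT_KEYS)}"
        )

    def sort_value(rec: MinimotifRecord):
        if key == "position":
            value = rec.position
        elif key == "activity":
            value = rec.activity_label or None
        elif key == "pmid":
            value = rec.pmid or None
        elif key == "target":
            value = rec.target or None
        else:
            value = rec.source_accession or None
        return (value is None, value)

    return sorted(records, key=sort_value)


def write_history(history: Iterable[ReviewEvent]) -> str:
    """Review history as JSON-lines (pmid, annotator, status, ISO timestamp)."""
    lines = [
        json.dumps(
            {
                "pmid": e.pmid,
                "annotator": e.annotator,
                "status": e.status,
                "timestamp": e.timestamp.isoformat(),
            }
        )
        for e in history
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def read_history(text: str) -> list[ReviewEvent]:
    events: list[ReviewEvent] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            events.append(
                ReviewEvent(
                    pmid=obj["pmid"],
                    annotator=obj["annotator"],
                    status=_normalize_status(obj["status"]),
                    timestamp=datetime.fromisoformat(obj["timestamp"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise AnnotationError(f"history line {lineno}: {exc}") from exc
    return events


def write_records_jsonl(records: Iterable[MinimotifRecord]) -> str:
    """Record store as JSON-lines, one record object per line."""
    lines = []
    for rec in records:
        lines.append(
            json.dumps(
                {
                    "motif": rec.motif,
                    "source_accession": rec.source_accession,
                    "position": rec.position,
                    "activity_id": rec.activity_id,
                    "activity_label": rec.activity_label,
                    "target": rec.target,
                    "modification_id": rec.modification_id,
                    "modification_label": rec.modification_label,
                    "experiment_source": rec.experiment_source,
                    "techniques": list(rec.techniques),
                    "structure_accessions": list(rec.structure_accessions),
                    "comments": rec.comments,
                    "pmid": rec.pmid,
                }
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_records_jsonl(text: str) -> list[MinimotifRecord]:
    records: list[MinimotifRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            records.append(
                MinimotifRecord(
                    motif=obj["motif"],
                    source_accession=obj["source_accession"],
                    position=obj.get("position"),
                    activity_id=obj.get("activity_id", ""),
                    activity_label=obj.get("activity_label", ""),
                    target=obj.get("target", ""),
                    modification_id=obj.get("modification_id", ""),
                    modification_label=obj.get("modification_label", ""),
                    experiment_source=obj.get("experiment_source", "peptide"),
                    techniques=tuple(obj.get("techniques", ())),
                    structure_accessions=tuple(
                        obj.get("structure_accessions", ())
                    ),
                    comments=obj.get("comments", ""),
                    pmid=obj["pmid"],
                )
            )
        except (KeyError, ValueError) as exc:
            raise AnnotationError(f"records line {lineno}: {exc}") from exc
    return records
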