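"""Local, private persistence of calculation records.

Records are stored as JSON lines (one record per line) in a single local
file the user controls.  Nothing in this module performs network I/O: the
privacy contract is that calculation history lives only on the clinician's
machine, keyed by a free-text patient identifier (a pseudonym or patient ID
number is recommended, not a name), and that purging the store deletes it
permanently.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

from .units import ValidationError

__all__ = [
    "CalculationRecord",
    "StorageError",
    "StoreParseError",
    "save_record",
    "list_records",
    "purge_store",
]

APP_VERSION = "1.0.0"


class StorageError(OSError):
    """The history store could not be written."""


class StoreParseError(ValueError):
    """The history store file is corrupt; the message names the file."""


@dataclass(frozen=True)
class CalculationRecord:
    """A persisted snapshot of dosing inputs and the resulting recommendation."""

    patient_id: str
    inputs: dict
    recommendation: dict
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    app_version: str = APP_VERSION
    record_id: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.patient_id, str) or not self.patient_id.strip():
            raise ValidationError("patient_id", "must be non-empty text")
        # must survive a JSON round-trip unchanged
        datetime.fromisoformat(self.timestamp)

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "patient_id": self.patient_id,
            "timestamp": self.timestamp,
            "inputs": self.inputs,
            "recommendation": self.recommendation,
            "app_version": self.app_version,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CalculationRecord":
        return cls(
            patient_id=data["patient_id"],
            inputs=data["inputs"],
            recommendation=data["recommendation"],
            timestamp=data["timestamp"],
            app_version=data.get("app_version", APP_VERSION),
            record_id=data.get("record_id"),
        )


def _read_all(store_path: Path) -> list[CalculationRecord]:
    if not store_path.exists():
        return []
    records = []
    with open(store_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(CalculationRecord.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise StoreParseError(
                    f"corrupt history store {store_path} at line {lineno}: {exc}"
                ) from exc
    return records


def save_record(record: CalculationRecord, store_path: str | Path) -> int:
    """Append *record* to the store, assigning the next monotonically increasing id.

    The record is written as a single line in one write call, so a crash
    cannot interleave two records.  Returns the assigned id.
    """
    store_path = Path(store_path)
    try:
        existing = _read_all(store_path)
    except OSError as exc:
        raise StorageError(f"cannot read history store {store_path}: {exc}") from exc
    next_id = 1 + max((r.record_id or 0 for r in existing), default=0)
    stamped = replace(record, record_id=next_id)
    line = json.dumps(stamped.to_dict(), sort_keys=True) + "\n"
    try:
        store_path.parent.mkdir(parents=True, exist_ok=True)
        with open(store_path, "a") as fh:
            fh.write(line)
            fh.flush()
            os.fsync(fh.fileno())
    except OSError as exc:
        raise StorageError(f"cannot write history store {store_path}: {exc}") from exc
    return next_id


def list_records(store_path: str | Path, patient_id: str | None = None) -> list[CalculationRecord]:
    """Records in the store, newest first, optionally filtered by patient id.

    A missing or empty store yields an empty list; a corrupt store raises
    :class:`StoreParseError`.
    """
    records = _read_all(Path(store_path))
    if patient_id is not None:
        records = [r for r in records if r.patient_id == patient_id]
    return sorted(records, key=lambda r: (r.record_id or 0), reverse=True)


def purge_store(store_path: str | Path) -> int:
    """Permanently delete the store; returns the number of records removed.

    Idempotent: purging a missing or empty store returns 0.
    """
    store_path = Path(store_path)
    if not store_path.exists():
        return 0
    count = len(_read_all(store_path))
    store_path.unlink()
    return count
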