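"""Readers and writers for the formats the toolkit touches.

Supported formats:

* the NCBI-taxonomy ``names.dmp`` dialect — four fields separated by
  ``tab-pipe-tab`` with rows terminated by ``tab-pipe`` — read and
  written with byte-exact round-trips;
* CSV checklists with a header and a scientific-name column (record ids
  are synthesized from the row ordinal when the file has no id column);
* TSV/CSV report writing is handled by the cross-mapper's report helper.

Text is decoded as UTF-8 by default with an explicit Latin-1 fallback
flag.  Mojibake (``BrullÃ©``) is data, not an error: it is surfaced to
the caller untouched, never silently repaired.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

_DMP_SEP = "\t|\t"
_DMP_END = "\t|"


@dataclass(frozen=True)
class DumpRecord:
    """One row of a names.dmp taxonomy dump."""

    tax_id: str
    name_txt: str
    unique_name: str
    name_class: str


@dataclass
class ChecklistRecord:
    record_id: str
    name_string: str
    extra_columns: dict[str, str] = field(default_factory=dict)


def _open_text(source: str | Path | IO[str], latin1: bool = False) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="latin-1" if latin1 else "utf-8", newline="")
    return source


def read_names_dump(
    source: str | Path | IO[str], latin1: bool = False
) -> tuple[list[DumpRecord], list[tuple[int, str]]]:
    """Parse a names.dmp stream.

    Returns ``(records, skipped)`` where *skipped* lists the 1-based line
    numbers and content of malformed rows.
    """
    stream = _open_text(source, latin1)
    records: list[DumpRecord] = []
    skipped: list[tuple[int, str]] = []
    for lineno, line in enumerate(stream, start=1):
        row = line.rstrip("\n")
        if not row.strip():
            continue
        body = row[: -len(_DMP_END)] if row.endswith(_DMP_END) else row
        fields = body.split(_DMP_SEP)
        if len(fields) != 4:
            skipped.append((lineno, row))
            continue
        records.append(DumpRecord(*fields))
    return records, skipped


def write_names_dump(records: Iterable[DumpRecord], sink: str | Path | IO[str]) -> None:
    """Serialize records in the names.dmp dialect (byte-exact round-trip)."""
    own = isinstance(sink, (str, Path))
    stream: IO[str] = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        for rec in records:
            fields = (rec.tax_id, rec.name_txt, rec.unique_name, rec.name_class)
            stream.write(_DMP_SEP.join(fields) + _DMP_END + "\n")
    finally:
        if own:
            stream.close()


def read_checklist(
    source: str | Path | IO[str],
    name_column: str,
    id_column: str | None = None,
    latin1: bool = False,
) -> list[ChecklistRecord]:
    """Read a CSV checklist; quoting and embedded commas follow the CSV standard."""
    stream = _open_text(source, latin1)
    reader = csv.DictReader(stream)
    header = reader.fieldnames or []
    if name_column not in header:
        raise KeyError(
            f"column {name_column!r} not found; available columns: {header}"
        )
    if id_column is not None and id_column not in header:
        raise KeyError(
            f"column {id_column!r} not found; available columns: {header}"
        )
    records = []
    for ordinal, row in enumerate(reader, start=1):
        rid = row[id_column] if id_column else str(ordinal)
        extras = {
            k: v for k, v in row.items() if k not in (name_column, id_column)
        }
        records.append(
            ChecklistRecord(record_id=rid, name_string=row[name_column], extra_columns=extras)
        )
    return records


def checklist_from_lines(lines: Iterable[str]) -> list[ChecklistRecord]:
    """Build checklist records from plain name-per-line input."""
    records = []
    for ordinal, line in enumerate(lines, start=1):
        name = line.rstrip("\n")
        if name.strip():
            records.append(ChecklistRecord(record_id=str(ordinal), name_string=name))
    return records


def dump_to_string(records: Iterable[DumpRecord]) -> str:
    buf = io.StringIO()
    write_names_dump(records, buf)
    return buf.getvalue()
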