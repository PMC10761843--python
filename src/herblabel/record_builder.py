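"""Turn tagged label text into structured specimen occurrence records.

The end product of the pipeline is a database row per specimen: scientific
name, locality hierarchy, ISO collection date, collector list and number,
altitude range, verbatim coordinates.  Span labels map onto record fields;
dates and altitudes are normalized by bounded template-driven parsers (the
same templates the artificial-label generator renders, plus bare ISO), so
generator output always round-trips.  Export is a Darwin-Core-style
occurrence CSV for aggregators plus a lossless JSON alongside.

Coordinates are kept verbatim only: specimen labels frequently carry
degenerate degree/minute fragments that no decimal conversion can interpret
safely.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .corpus_model import AnnotatedDocument, EntityLabel

__all__ = [
    "SpecimenRecord",
    "normalize_date",
    "normalize_altitude",
    "spans_to_record",
    "export_records",
    "read_records_json",
]

_MONTHS = {}
for _m in range(1, 13):
    _full = _dt.date(2000, _m, 1).strftime("%B")
    _abbr = _dt.date(2000, _m, 1).strftime("%b")
    _MONTHS[_full.casefold()] = _m
    _MONTHS[_abbr.casefold()] = _m
_MONTHS["sept"] = 9

# month-first: "March. 13.1988", "Mar. 28. 2009", "December 30, 1988"
_RE_MONTH_FIRST = re.compile(r"^([A-Za-z]+)\.?\s+(\d{1,2})\s*[.,]?\s*(\d{4})$")
# day-first: "10. Oct. 2003", "16. March, 1997", "1. Aug. 2005"
_RE_DAY_FIRST = re.compile(r"^(\d{1,2})\.?\s+([A-Za-z]+)\.?\s*,?\s*(\d{4})$")
_RE_SLASH = re.compile(r"^(\d{4})/(\d{1,2})/(\d{1,2})$")
_RE_ISO = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")


def _month_number(name: str) -> int | None:
    return _MONTHS.get(name.casefold().rstrip("."))


def normalize_date(surface: str) -> str | None:
    """Parse a label date to ISO 8601 (``YYYY-MM-DD``), or None.

    Handles the date shapes seen on specimen labels — month-first with dot or
    comma separators, day-first with abbreviated or full English month names,
    slash-separated numeric — plus bare ISO.  Anything else (including
    impossible calendar dates) yields None; callers keep the verbatim string.
    """
    s = surface.strip()
    year = month = day = None
    if m := _RE_SLASH.match(s) or _RE_ISO.match(s):
        year, month, day = int(m.group(1)), int(m.group(2)), int(m.group(3))
    elif m := _RE_MONTH_FIRST.match(s):
        month = _month_number(m.group(1))
        day, year = int(m.group(2)), int(m.group(3))
    elif m := _RE_DAY_FIRST.match(s):
        day = int(m.group(1))
        month = _month_number(m.group(2))
        year = int(m.group(3))
    if year is None or month is None or day is None:
        return None
    try:
        return _dt.date(year, month, day).isoformat()
    except ValueError:
        return None


_RE_ALT_RANGE = re.compile(r"^(?:alt\.?\s*)?(\d+)\s*(?:[–—-]|to)\s*(\d+)\s*m\.?$", re.IGNORECASE)
_RE_ALT_SINGLE = re.compile(r"^(?:alt\.?\s*)?(\d+)\s*m\.?$", re.IGNORECASE)


def normalize_altitude(surface: str) -> tuple[int, int] | None:
    """Parse "350 m" / "800–1200 m" / "800 to 1200 m" to (min_m, max_m).

    A reversed range is swapped; unparseable input yields None.
    """
    s = surface.strip()
    if m := _RE_ALT_SINGLE.match(s):
        v = int(m.group(1))
        return (v, v)
    if m := _RE_ALT_RANGE.match(s):
        lo, hi = int(m.group(1)), int(m.group(2))
        return (min(lo, hi), max(lo, hi))
    return None


@dataclass
class SpecimenRecord:
    """One structured database row distilled from a tagged label.

    ``provenance`` maps each populated field to the entity label(s) it came
    from, so no exported value is untraceable to a span.
    """

    doc_id: str = ""
    scientific_name: str | None = None
    family_en: str | None = None
    family_jp: str | None = None
    name_jp: str | None = None
    country: str | None = None
    prefecture: str | None = None
    city: str | None = None
    street: str | None = None
    event_date_iso: str | None = None
    verbatim_date: str | None = None
    collectors: list[str] = field(default_factory=list)
    collector_number: int | None = None
    altitude_min_m: int | None = None
    altitude_max_m: int | None = None
    lat_verbatim: str | None = None
    long_verbatim: str | None = None
    memo: str | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.collector_number is not None and self.collector_number < 1:
            raise ValueError(f"collector_number must be >= 1, got {self.collector_number}")
        if (
            self.altitude_min_m is not None
            and self.altitude_max_m is not None
            and self.altitude_min_m > self.altitude_max_m
        ):
            raise ValueError("altitude_min_m exceeds altitude_max_m")


_SINGLE_VALUED = {
    EntityLabel.EN_NAME: "scientific_name",
    EntityLabel.EN_FAMILY_NAME: "family_en",
    EntityLabel.JP_FAMILY_NAME: "family_jp",
    EntityLabel.JP_NAME: "name_jp",
    EntityLabel.COUNTRY: "country",
    EntityLabel.LAT: "lat_verbatim",
    EntityLabel.LONG: "long_verbatim",
    EntityLabel.MEMO: "memo",
}

# English locality populates the exported column; the Japanese variant is
# retained through provenance (international aggregators index the former)
_LOCALITY = {
    "prefecture": (EntityLabel.EN_PREF, EntityLabel.JA_PREF),
    "city": (EntityLabel.EN_CITY, EntityLabel.JA_CITY),
    "street": (EntityLabel.EN_ADDR, EntityLabel.JA_ADDR),
}


def spans_to_record(doc: AnnotatedDocument) -> SpecimenRecord:
    """Map a document's entity spans onto a specimen record.

    First occurrence wins for single-valued fields; every person span joins
    the collectors list in reading order; when a locality level carries both
    Japanese and English spans the English value fills the exported field and
    both are recorded in provenance.
    """
    record = SpecimenRecord(doc_id=doc.doc_id)
    by_label: dict[EntityLabel, list[str]] = {}
    for span in doc.spans:
        by_label.setdefault(span.label, []).append(doc.span_text(span))

    def _note(field_name: str, label: EntityLabel, value: str) -> None:
        key = f"{field_name}"
        prior = record.provenance.get(key)
        entry = f"{label.value}={value}"
        record.provenance[key] = f"{prior}; {entry}" if prior else entry

    for label, field_name in _SINGLE_VALUED.items():
        if label in by_label:
            value = by_label[label][0]
            setattr(record, field_name, value)
            _note(field_name, label, value)

    for field_name, (en_label, ja_label) in _LOCALITY.items():
        value = None
        if en_label in by_label:
            value = by_label[en_label][0]
            _note(field_name, en_label, value)
        if ja_label in by_label:
            _note(field_name, ja_label, by_label[ja_label][0])
            if value is None:
                value = by_label[ja_label][0]
        if value is not None:
            setattr(record, field_name, value)

    if EntityLabel.DATE in by_label:
        verbatim = by_label[EntityLabel.DATE][0]
        record.verbatim_date = verbatim
        record.event_date_iso = normalize_date(verbatim)
        _note("event_date", EntityLabel.DATE, verbatim)

    if EntityLabel.PERSON in by_label:
        record.collectors = list(by_label[EntityLabel.PERSON])
        for person in record.collectors:
            _note("collectors", EntityLabel.PERSON, person)

    if EntityLabel.NUMBER in by_label:
        digits = re.sub(r"\D", "", by_label[EntityLabel.NUMBER][0])
        if digits and int(digits) >= 1:
            record.collector_number = int(digits)
            _note("collector_number", EntityLabel.NUMBER, digits)

    if EntityLabel.ALT in by_label:
        surface = by_label[EntityLabel.ALT][0]
        parsed = normalize_altitude(surface)
        if parsed is not None:
            record.altitude_min_m, record.altitude_max_m = parsed
        _note("altitude", EntityLabel.ALT, surface)

    return record


#: Darwin-Core-style column -> record attribute
DWC_COLUMNS: dict[str, str] = {
    "occurrenceID": "doc_id",
    "scientificName": "scientific_name",
    "family": "family_en",
    "vernacularName": "name_jp",
    "country": "country",
    "stateProvince": "prefecture",
    "county": "city",
    "locality": "street",
    "eventDate": "event_date_iso",
    "verbatimEventDate": "verbatim_date",
    "recordedBy": "collectors",
    "recordNumber": "collector_number",
    "minimumElevationInMeters": "altitude_min_m",
    "maximumElevationInMeters": "altitude_max_m",
    "verbatimLatitude": "lat_verbatim",
    "verbatimLongitude": "long_verbatim",
    "occurrenceRemarks": "memo",
}


def export_records(
    records: Sequence[SpecimenRecord],
    path: str | Path,
    fmt: str = "csv",
) -> Path:
    """Write records as a Darwin-Core-style CSV or lossless JSON.

    CSV export joins multiple collectors with " | " (the aggregator
    convention); JSON preserves every field including provenance, and
    round-trips through :func:`read_records_json`.
    """
    path = Path(path)
    if fmt == "json":
        payload = [asdict(r) for r in records]
        path.write_text(
            json.dumps(payload, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
        )
        return path
    if fmt != "csv":
        raise ValueError(f"unknown export format: {fmt!r}")
    rows = []
    for record in records:
        row = {}
        for column, attr in DWC_COLUMNS.items():
            value = getattr(record, attr)
            if attr == "collectors":
                value = " | ".join(value) if value else None
            row[column] = value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(DWC_COLUMNS))
    frame.to_csv(path, index=False, encoding="utf-8")
    return path


def read_records_json(path: str | Path) -> list[SpecimenRecord]:
    """Reload records from the lossless JSON export."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [SpecimenRecord(**item) for item in payload]
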