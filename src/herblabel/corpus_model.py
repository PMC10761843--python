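"""Core data model for annotated specimen-label corpora.

Herbarium specimen labels carry a handful of recurring fields — taxon names
(scientific, Japanese, family), collecting locality in Japanese and/or
English, collection date, collector name(s), collector number, coordinates,
altitude.  This module defines the closed 18-label vocabulary used to tag
those fields, character-offset entity spans, the annotated-document
container, and corpus I/O in the common JSON / JSON-Lines span-annotation
dialect.

All offsets are 0-based, half-open and counted in Unicode code points:
Japanese label text makes byte offsets fragile, and half-open intervals keep
span arithmetic simple.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EntityLabel",
    "EntitySpan",
    "AnnotatedDocument",
    "LabelDictionaryEntry",
    "CorpusError",
    "LEGACY_ALIASES",
    "resolve_alias",
    "read_corpus",
    "write_corpus",
    "select_training_candidates",
]


class CorpusError(ValueError):
    """Raised for malformed corpus files or invariant-violating documents."""


class EntityLabel(str, Enum):
    """The closed vocabulary of span labels for specimen-label fields.

    The seven members carrying :attr:`deep_learning_only` are fields that a
    plain gazetteer cannot recover (free-form numerals, coordinates,
    sub-city addresses, memos) and are only ever produced by a trained
    tagger.
    """

    EN_FAMILY_NAME = "en_family_name"
    JP_FAMILY_NAME = "jp_family_name"
    EN_NAME = "en_name"
    JP_NAME = "jp_name"
    JA_PREF = "ja_pref"
    JA_CITY = "ja_city"
    JA_ADDR = "ja_addr"
    EN_PREF = "en_pref"
    EN_CITY = "en_city"
    EN_ADDR = "en_addr"
    DATE = "date"
    PERSON = "person"
    NUMBER = "number"
    COUNTRY = "country"
    LAT = "lat"
    LONG = "long"
    ALT = "alt"
    MEMO = "memo"

    @property
    def deep_learning_only(self) -> bool:
        return self in _DEEP_LEARNING_ONLY

    @classmethod
    def from_string(cls, name: str) -> "EntityLabel":
        try:
            return cls(name)
        except ValueError:
            raise CorpusError(f"unknown entity label: {name!r}") from None


_DEEP_LEARNING_ONLY = frozenset(
    {
        EntityLabel.JA_PREF,
        EntityLabel.JA_CITY,
        EntityLabel.JA_ADDR,
        EntityLabel.LAT,
        EntityLabel.LONG,
        EntityLabel.ALT,
        EntityLabel.MEMO,
    }
)

#: Legacy reporting names -> canonical members.  The older naming scheme did
#: not distinguish Japanese from English locality fields, so the locality
#: aliases resolve to a pair reported jointly.
LEGACY_ALIASES: dict[str, tuple[EntityLabel, ...]] = {
    "collect_pref": (EntityLabel.JA_PREF, EntityLabel.EN_PREF),
    "collect_city": (EntityLabel.JA_CITY, EntityLabel.EN_CITY),
    "collect_addr": (EntityLabel.JA_ADDR, EntityLabel.EN_ADDR),
    "collect_date": (EntityLabel.DATE,),
    "collect_person": (EntityLabel.PERSON,),
    "collect_number": (EntityLabel.NUMBER,),
    "collect_country": (EntityLabel.COUNTRY,),
}


def resolve_alias(name: str) -> tuple[EntityLabel, ...]:
    """Resolve a label name, legacy or canonical, to canonical members.

    Raises :class:`CorpusError` for names in neither scheme.
    """
    if name in LEGACY_ALIASES:
        return LEGACY_ALIASES[name]
    return (EntityLabel.from_string(name),)


VALID_SOURCES = ("manual", "artificial", "predicted")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed span: 0-based, half-open, in Unicode code points."""

    start: int
    end: int
    label: EntityLabel

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"invalid span offsets ({self.start}, {self.end}): "
                "need 0 <= start < end"
            )


@dataclass
class AnnotatedDocument:
    """One label text with its (gold or predicted) entity spans.

    ``source`` records provenance — manually annotated, rule-generated
    artificial, or tagger-predicted — which the three-regime evaluation
    partitions on.  ``collector`` is the grouping key for training-candidate
    selection; documents without one are pooled under "unknown".
    """

    doc_id: str
    text: str
    spans: tuple[EntitySpan, ...] = ()
    source: str = "manual"
    collector: str | None = None

    def __post_init__(self) -> None:
        self.spans = tuple(sorted(self.spans, key=lambda s: (s.start, s.end)))
        self.validate()

    def validate(self) -> None:
        if self.source not in VALID_SOURCES:
            raise CorpusError(
                f"doc {self.doc_id!r}: source must be one of {VALID_SOURCES}, "
                f"got {self.source!r}"
            )
        n = len(self.text)
        prev_end = -1
        for span in self.spans:
            if span.end > n:
                raise CorpusError(
                    f"doc {self.doc_id!r}: span ({span.start}, {span.end}) "
                    f"exceeds text length {n}"
                )
            if span.start < prev_end:
                raise CorpusError(
                    f"doc {self.doc_id!r}: overlapping spans at offset {span.start}"
                )
            if not self.text[span.start : span.end].strip():
                raise CorpusError(
                    f"doc {self.doc_id!r}: span ({span.start}, {span.end}) "
                    "covers only whitespace"
                )
            prev_end = span.end

    def span_text(self, span: EntitySpan) -> str:
        return self.text[span.start : span.end]

    def with_spans(self, spans: Iterable[EntitySpan], source: str | None = None) -> "AnnotatedDocument":
        return replace(self, spans=tuple(spans), source=source or self.source)


@dataclass(frozen=True)
class LabelDictionaryEntry:
    """One gazetteer row: a surface form, its label, and its source table."""

    surface: str
    label: EntityLabel
    source: str = ""

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise CorpusError("dictionary surface is empty")


# ---------------------------------------------------------------------------
# Corpus I/O — JSON array or JSON-Lines of
#   {"id", "text", "entities": [[start, end, label], ...],
#    "meta": {"collector", "source"}}


def _doc_from_record(record: dict) -> AnnotatedDocument:
    doc_id = str(record.get("id", ""))
    try:
        text = record["text"]
        if not isinstance(text, str):
            raise CorpusError(f"doc {doc_id!r}: field 'text' must be a string")
        spans = []
        for ent in record.get("entities", []):
            if not (isinstance(ent, (list, tuple)) and len(ent) == 3):
                raise CorpusError(
                    f"doc {doc_id!r}: field 'entities' entries must be "
                    "[start, end, label] triples"
                )
            start, end, label = ent
            spans.append(EntitySpan(int(start), int(end), EntityLabel.from_string(label)))
        meta = record.get("meta", {}) or {}
        return AnnotatedDocument(
            doc_id=doc_id,
            text=text,
            spans=tuple(spans),
            source=meta.get("source", "manual"),
            collector=meta.get("collector"),
        )
    except KeyError as exc:
        raise CorpusError(f"doc {doc_id!r}: missing field {exc.args[0]!r}") from None


def _doc_to_record(doc: AnnotatedDocument) -> dict:
    meta: dict = {"source": doc.source}
    if doc.collector is not None:
        meta["collector"] = doc.collector
    return {
        "id": doc.doc_id,
        "text": doc.text,
        "entities": [[s.start, s.end, s.label.value] for s in doc.spans],
        "meta": meta,
    }


def read_corpus(path: str | Path) -> list[AnnotatedDocument]:
    """Read an annotated corpus from a JSON array or JSON-Lines file."""
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    stripped = raw.lstrip()
    if not stripped:
        return []
    if stripped[0] == "[":
        records = json.loads(raw)
    else:
        records = []
        for lineno, line in enumerate(raw.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from None
    return [_doc_from_record(r) for r in records]


def write_corpus(docs: Sequence[AnnotatedDocument], path: str | Path) -> Path:
    """Write docs as JSON-Lines (``.jsonl``) or a JSON array (otherwise)."""
    path = Path(path)
    records = [_doc_to_record(d) for d in docs]
    if path.suffix == ".jsonl":
        body = "".join(json.dumps(r, ensure_ascii=False) + "\n" for r in records)
    else:
        body = json.dumps(records, ensure_ascii=False, indent=1) + "\n"
    path.write_text(body, encoding="utf-8")
    return path


def select_training_candidates(
    docs: Sequence[AnnotatedDocument],
    per_group: int = 3,
    seed: int = 0,
) -> list[AnnotatedDocument]:
    """Pick up to ``per_group`` documents per collector for annotation.

    Collectors tend to reuse one label format, so a corpus that samples a few
    labels from every collector covers most format variation at a fraction of
    the annotation cost.  Documents are grouped by collector (missing
    collector -> "unknown"), ranked randomly within each group, and the top
    ``per_group`` (between 1 and 3) of each group are returned, ordered by
    collector key then rank.  Reproducible for a fixed seed.
    """
    if not 1 <= per_group <= 3:
        raise ValueError(f"per_group must be in [1, 3], got {per_group}")
    groups: dict[str, list[AnnotatedDocument]] = {}
    for doc in docs:
        groups.setdefault(doc.collector or "unknown", []).append(doc)
    rng = random.Random(seed)
    selected: list[AnnotatedDocument] = []
    for key in sorted(groups):
        members = list(groups[key])
        rng.shuffle(members)
        selected.extend(members[:per_group])
    return selected
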