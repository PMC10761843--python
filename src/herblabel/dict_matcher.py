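"""Dictionary-based (gazetteer) named-entity extraction.

Before any machine learning, the cheapest way to tag specimen-label OCR text
is exact lookup against curated term lists: a botanical-name table (family
names, scientific names, Japanese names) and an address table (prefecture,
city, street).  This module builds a normalized gazetteer from such CSV
tables, runs a greedy leftmost-longest non-overlapping scan over text, and
produces the per-label coverage report (how many documents had at least one
match for each label) that motivates moving to a trained tagger when
coverage is poor.

Normalization is Unicode NFKC with case folding applied per code point, so
that full-width/half-width variants and Latin case differences (both common
in OCR output) unify while character offsets into the original text remain
recoverable.
"""

from __future__ import annotations

import csv
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_model import (
    AnnotatedDocument,
    CorpusError,
    EntityLabel,
    EntitySpan,
    LabelDictionaryEntry,
    LEGACY_ALIASES,
)

__all__ = [
    "LabelDictionary",
    "CoverageReport",
    "normalize",
    "build_dictionary",
    "match",
    "coverage_report",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SURFACE_LEN = 2  # 1-char Japanese surfaces flood the matcher


def _norm_char(ch: str) -> str:
    """NFKC + casefold one code point (may expand, e.g. ligatures)."""
    return unicodedata.normalize("NFKC", ch).casefold()


def normalize(text: str) -> str:
    """Normalize a string the way the matcher compares surfaces."""
    return "".join(_norm_char(ch) for ch in text)


def _normalize_with_map(text: str) -> tuple[str, list[int]]:
    """Normalize, returning for each normalized char its original index."""
    out: list[str] = []
    idx_map: list[int] = []
    for i, ch in enumerate(text):
        norm = _norm_char(ch)
        out.append(norm)
        idx_map.extend([i] * len(norm))
    return "".join(out), idx_map


@dataclass
class LabelDictionary:
    """Normalized surface form -> entity label gazetteer.

    One surface may carry labels from several source tables; ``priority``
    orders sources for tie-breaking (first listed wins).  Within one source a
    surface is unique.
    """

    entries: dict[str, dict[str, EntityLabel]] = field(default_factory=dict)
    priority: tuple[str, ...] = ()
    min_surface_len: int = DEFAULT_MIN_SURFACE_LEN
    #: normalized surface -> first original spelling seen (for display/sampling)
    originals: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    @property
    def max_surface_len(self) -> int:
        return max((len(s) for s in self.entries), default=0)

    def add(self, entry: LabelDictionaryEntry) -> bool:
        """Add one entry; returns False when dropped as too short."""
        surface = normalize(entry.surface).strip()
        if len(surface) < self.min_surface_len:
            return False
        by_source = self.entries.setdefault(surface, {})
        if entry.source in by_source and by_source[entry.source] != entry.label:
            raise CorpusError(
                f"duplicate surface {entry.surface!r} with conflicting labels "
                f"within source {entry.source!r}"
            )
        by_source[entry.source] = entry.label
        self.originals.setdefault(surface, entry.surface.strip())
        if entry.source not in self.priority:
            self.priority = self.priority + (entry.source,)
        return True

    def lookup(self, normalized_surface: str) -> EntityLabel | None:
        """Resolve a normalized surface to its highest-priority label."""
        by_source = self.entries.get(normalized_surface)
        if not by_source:
            return None
        for source in self.priority:
            if source in by_source:
                return by_source[source]
        return next(iter(by_source.values()))

    def surfaces(self, label: EntityLabel | None = None) -> list[str]:
        if label is None:
            return list(self.entries)
        return [s for s in self.entries if label in self.entries[s].values()]

    def original_surfaces(self, label: EntityLabel | None = None) -> list[str]:
        """Original (pre-normalization) spellings, for sampling/display."""
        return [self.originals[s] for s in self.surfaces(label)]


def build_dictionary(
    tables: Iterable[str | Path],
    min_surface_len: int = DEFAULT_MIN_SURFACE_LEN,
    priority: Sequence[str] | None = None,
) -> LabelDictionary:
    """Build a gazetteer from one or more ``surface,label[,source]`` CSVs.

    Surfaces are normalized; entries shorter than ``min_surface_len`` code
    points after normalization are dropped (count logged).  An unknown label
    string raises, naming the offending row.
    """
    dictionary = LabelDictionary(
        priority=tuple(priority or ()), min_surface_len=min_surface_len
    )
    dropped = 0
    for table in tables:
        table = Path(table)
        default_source = table.stem
        with table.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "surface" not in reader.fieldnames:
                raise CorpusError(f"{table}: expected a header with a 'surface' column")
            for rownum, row in enumerate(reader, start=2):
                surface = (row.get("surface") or "").strip()
                if not surface:
                    continue
                try:
                    label = EntityLabel.from_string((row.get("label") or "").strip())
                except CorpusError:
                    raise CorpusError(
                        f"{table}:{rownum}: unknown label {row.get('label')!r}"
                    ) from None
                entry = LabelDictionaryEntry(
                    surface=surface,
                    label=label,
                    source=(row.get("source") or default_source).strip(),
                )
                if not dictionary.add(entry):
                    dropped += 1
    if dropped:
        logger.info("dropped %d surfaces shorter than %d code points", dropped, min_surface_len)
    return dictionary


def match(text: str, dictionary: LabelDictionary) -> list[EntitySpan]:
    """Extract all gazetteer hits as non-overlapping leftmost-longest spans.

    The scan walks the normalized text; at each position the longest
    dictionary surface anchored there wins and the scan resumes after it.
    Returned offsets index the *original* text in code points.
    """
    if not text or not dictionary.entries:
        return []
    norm, idx_map = _normalize_with_map(text)
    max_len = min(dictionary.max_surface_len, len(norm))
    spans: list[EntitySpan] = []
    i = 0
    n = len(norm)
    while i < n:
        best_len = 0
        best_label: EntityLabel | None = None
        upper = min(max_len, n - i)
        for length in range(upper, dictionary.min_surface_len - 1, -1):
            label = dictionary.lookup(norm[i : i + length])
            if label is not None:
                best_len, best_label = length, label
                break
        if best_label is not None:
            start = idx_map[i]
            end = idx_map[i + best_len - 1] + 1
            spans.append(EntitySpan(start, end, best_label))
            i += best_len
        else:
            i += 1
    return spans


@dataclass
class CoverageReport:
    """Per-label count of documents with at least one gazetteer match."""

    matched_docs: dict[str, int]
    total_docs: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": label, "matched_docs": count, "total_docs": self.total_docs}
            for label, count in self.matched_docs.items()
        ]
        return pd.DataFrame(rows, columns=["label", "matched_docs", "total_docs"])


def coverage_report(
    docs: Sequence[AnnotatedDocument],
    dictionary: LabelDictionary,
    legacy_names: bool = False,
) -> CoverageReport:
    """Count, per label, how many documents contain >= 1 match of that label.

    With ``legacy_names=True`` the locality/date/person/number/country rows
    are reported under the older ``collect_*`` names, each aggregating its
    canonical members (a document counts when any member matched).
    """
    doc_hits = [{span.label for span in match(doc.text, dictionary)} for doc in docs]
    per_label = {
        label: sum(1 for hit in doc_hits if label in hit) for label in EntityLabel
    }
    if not legacy_names:
        matched = {label.value: per_label[label] for label in EntityLabel}
    else:
        matched = {}
        for label in (
            EntityLabel.EN_FAMILY_NAME,
            EntityLabel.JP_FAMILY_NAME,
            EntityLabel.EN_NAME,
            EntityLabel.JP_NAME,
        ):
            matched[label.value] = per_label[label]
        for alias, members in LEGACY_ALIASES.items():
            # a document counts once per alias even when several members hit
            member_set = set(members)
            matched[alias] = sum(1 for hit in doc_hits if hit & member_set)
    return CoverageReport(matched_docs=matched, total_docs=len(docs))
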