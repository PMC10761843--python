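"""Rule-based artificial specimen-label generator.

Hand-annotating herbarium labels is slow; a few hundred gold documents are
nowhere near enough for a span tagger.  This module supplements a small
manual corpus with arbitrarily many artificial annotated labels: each field
value is drawn from the same resources a real label draws from — a
botanical-name gazetteer, an address gazetteer, a collector-name pool — and
volatile fields are synthesized by rule:

* dates in the ten messy formats observed on real labels ("March. 13.1988",
  "10. Oct. 2003", "1979/4/1", ...);
* collector numbers uniform in [1, 999999];
* altitudes in [0, 8000] m, as a single value or a low–high range;
* latitude/longitude fragments in ten degenerate degree/minute/second
  shapes ("− 15° 03′ 1.6", "− 131′ 21", ...).

Field order, separators and optional cue prefixes ("No. ", "alt. ") are
randomized per document, emulating the observation that label layout varies
by collector while each collector is internally consistent.  Every inserted
value is delimited exactly by a gold entity span, and generation is fully
deterministic for a fixed (config, resources, seed).  Memo fields are never
generated: free-form habitat remarks are too diverse to synthesize honestly.
"""

from __future__ import annotations

import datetime as _dt
import random
import re
from dataclasses import dataclass, field, asdict
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Sequence

import yaml

from .corpus_model import AnnotatedDocument, EntityLabel, EntitySpan
from .dict_matcher import LabelDictionary, build_dictionary

__all__ = [
    "AugmentationConfig",
    "ResourcePack",
    "ConfigurationError",
    "DATE_TEMPLATES",
    "LATLONG_TEMPLATES",
    "latlong_template_regex",
    "render_date",
    "sample_date",
    "sample_collector_number",
    "sample_altitude",
    "sample_latlong",
    "generate_document",
    "generate_dataset",
]


class ConfigurationError(ValueError):
    """Raised when generation is requested with unusable configuration."""


#: The ten date templates.  Tokens: {YYYY} 4-digit year, {M}/{D} unpadded
#: month/day, {MONTH} full English month name, {MON} 3-letter abbreviation.
#: Rendered on their exemplar dates these give exactly:
#: March. 13.1988 | 10. Oct. 2003 | 16. March, 1997 | May. 16.1972 |
#: 1979/4/1 | 1. Aug. 2005 | 24. May, 2013 | 12. January, 1975 |
#: Mar. 28. 2009 | December 30, 1988
DATE_TEMPLATES: tuple[str, ...] = (
    "{MONTH}. {D}.{YYYY}",
    "{D}. {MON}. {YYYY}",
    "{D}. {MONTH}, {YYYY}",
    "{MONTH}. {D}.{YYYY}",
    "{YYYY}/{M}/{D}",
    "{D}. {MON}. {YYYY}",
    "{D}. {MONTH}, {YYYY}",
    "{D}. {MONTH}, {YYYY}",
    "{MON}. {D}. {YYYY}",
    "{MONTH} {D}, {YYYY}",
)

#: The ten coordinate-fragment templates (axis-agnostic).  Tokens: {DEG}
#: 0–179 unpadded, {MIN} 0–59 unpadded, {MIN2} 0–59 zero-padded, {SEC}
#: 0–59 unpadded, {SEC2} zero-padded, {SECF} seconds with one decimal.
#: "−" is U+2212, "′" U+2032, as printed on labels.
LATLONG_TEMPLATES: tuple[str, ...] = (
    "− {DEG}° {MIN2}′ {SECF}",
    "− {DEG}° {MIN}'",
    "{DEG}′ {MIN2}′ {SEC}",
    "− {DEG} {MIN}",
    "{DEG}° {MIN2}′ {SEC2}",
    "{DEG}° {MIN}'",
    "{DEG}° {MIN}",
    "− {DEG}′ {MIN}",
    "− {DEG}′ {MIN2}′ {SEC}",
    "{DEG}′ {MIN2}′ {SEC}",
)

_LATLONG_TOKEN_RE = {
    "{DEG}": r"\d{1,3}",
    "{MIN}": r"\d{1,2}",
    "{MIN2}": r"\d{2}",
    "{SEC}": r"\d{1,2}",
    "{SEC2}": r"\d{2}",
    "{SECF}": r"\d{1,2}\.\d",
}


def latlong_template_regex(template: str) -> re.Pattern[str]:
    """Compile the validation regex a coordinate template induces."""
    pattern = ""
    i = 0
    while i < len(template):
        for token, token_re in _LATLONG_TOKEN_RE.items():
            if template.startswith(token, i):
                pattern += token_re
                i += len(token)
                break
        else:
            pattern += re.escape(template[i])
            i += 1
    return re.compile(f"^{pattern}$")


_DEFAULT_FIELD_PROBS: dict[str, float] = {
    "en_family_name": 0.45,
    "jp_family_name": 0.45,
    "en_name": 0.90,
    "jp_name": 0.70,
    "ja_pref": 0.80,
    "ja_city": 0.70,
    "ja_addr": 0.50,
    "en_pref": 0.40,
    "en_city": 0.30,
    "en_addr": 0.20,
    "date": 0.90,
    "person": 0.90,
    "number": 0.80,
    "country": 0.30,
    "lat": 0.20,
    "long": 0.20,
    "alt": 0.30,
    "memo": 0.0,
}

#: Cue words occasionally printed before a field; never part of the gold span.
_DEFAULT_FIELD_PREFIXES: dict[str, tuple[str, ...]] = {
    "number": ("No. ", "no. ", "# "),
    "alt": ("alt. ", "Alt. ", "elev. "),
    "person": ("Coll. ", "leg. "),
    "date": ("Date: ",),
    "lat": ("Lat. ",),
    "long": ("Long. ",),
}

_DEFAULT_LAYOUTS: tuple[dict, ...] = (
    {"order": "random", "separators": ["\n"]},
    {"order": "random", "separators": [", "]},
    {"order": "random", "separators": ["  ", " "]},
    {"order": "random", "separators": ["\n", ", "]},
)


@dataclass
class AugmentationConfig:
    """Knobs of the artificial-label generator.

    Defaults encode the generation conditions of the augmentation procedure:
    10,000 records, collector numbers uniform in [1, 999999], altitudes in
    [0, 8000] m with a range emitted about a third of the time, a 0.5 mix
    between address-table and corpus-derived place names, and the ten date
    and coordinate templates above.
    """

    n_records: int = 10_000
    seed: int = 42
    date_formats: tuple[str, ...] = DATE_TEMPLATES
    latlong_formats: tuple[str, ...] = LATLONG_TEMPLATES
    date_year_range: tuple[int, int] = (1950, 2020)
    altitude_range: tuple[int, int] = (0, 8000)
    altitude_range_prob: float = 0.35
    altitude_range_style: str = "endash"  # "endash" -> "800–1200 m", "to" -> "800 to 1200 m"
    collector_number_range: tuple[int, int] = (1, 999_999)
    place_source_mix: float = 0.5
    field_inclusion_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FIELD_PROBS)
    )
    field_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_FIELD_PREFIXES)
    )
    prefix_prob: float = 0.4
    layout_templates: tuple[dict, ...] = _DEFAULT_LAYOUTS
    on_empty: str = "regenerate"  # or "error"

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ConfigurationError("n_records must be >= 0")
        for name, p in {
            "altitude_range_prob": self.altitude_range_prob,
            "place_source_mix": self.place_source_mix,
            "prefix_prob": self.prefix_prob,
            **self.field_inclusion_probs,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {name}={p} outside [0, 1]")
        for name, (lo, hi) in {
            "altitude_range": self.altitude_range,
            "collector_number_range": self.collector_number_range,
            "date_year_range": self.date_year_range,
        }.items():
            if lo > hi:
                raise ConfigurationError(f"{name} is empty: ({lo}, {hi})")
        if self.field_inclusion_probs.get("memo", 0.0) != 0.0:
            raise ConfigurationError("memo fields are never generated")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AugmentationConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("date_formats", "latlong_formats", "layout_templates"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("altitude_range", "collector_number_range", "date_year_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "field_prefixes" in data:
            data["field_prefixes"] = {
                k: tuple(v) for k, v in data["field_prefixes"].items()
            }
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


_PLANT_LABELS = (
    EntityLabel.EN_FAMILY_NAME,
    EntityLabel.JP_FAMILY_NAME,
    EntityLabel.EN_NAME,
    EntityLabel.JP_NAME,
)
_PLACE_LABELS = (
    EntityLabel.JA_PREF,
    EntityLabel.JA_CITY,
    EntityLabel.JA_ADDR,
    EntityLabel.EN_PREF,
    EntityLabel.EN_CITY,
    EntityLabel.EN_ADDR,
    EntityLabel.COUNTRY,
)


@dataclass
class ResourcePack:
    """Value pools generation draws from.

    ``plant_dictionary`` supplies taxon-name surfaces, ``address_dictionary``
    locality surfaces, ``collector_name_pool`` person names.  An optional
    ``place_gazetteer`` (label value -> surfaces), e.g. harvested from an
    annotated corpus, is mixed with the address table at
    ``place_source_mix``; without one, place names come from the address
    table alone.
    """

    plant_dictionary: LabelDictionary
    address_dictionary: LabelDictionary
    collector_name_pool: tuple[str, ...]
    place_gazetteer: dict[str, tuple[str, ...]] | None = None
    _pools: dict[EntityLabel, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for label in _PLANT_LABELS:
            self._pools[label] = self._original_surfaces(self.plant_dictionary, label)
        for label in _PLACE_LABELS:
            self._pools[label] = self._original_surfaces(self.address_dictionary, label)

    @staticmethod
    def _original_surfaces(dictionary: LabelDictionary, label: EntityLabel) -> list[str]:
        return sorted(dictionary.original_surfaces(label))

    def pool(self, label: EntityLabel) -> list[str]:
        return self._pools.get(label, [])

    @classmethod
    def builtin(cls) -> "ResourcePack":
        """Load the synthetic fixture resources shipped with the package."""
        data = _importlib_resources.files("herblabel") / "data"
        plant = build_dictionary([str(data / "plant_dict_synthetic.csv")])
        address = build_dictionary([str(data / "address_dict_synthetic.csv")])
        names = tuple(
            line.strip()
            for line in (data / "collector_names_synthetic.txt")
            .read_text(encoding="utf-8")
            .splitlines()
            if line.strip()
        )
        return cls(plant_dictionary=plant, address_dictionary=address, collector_name_pool=names)

    @classmethod
    def from_paths(
        cls,
        plant_dict: str | Path,
        address_dict: str | Path,
        names_file: str | Path | None = None,
    ) -> "ResourcePack":
        plant = build_dictionary([plant_dict])
        address = build_dictionary([address_dict])
        if names_file is None:
            names = cls.builtin().collector_name_pool
        else:
            names = tuple(
                line.strip()
                for line in Path(names_file).read_text(encoding="utf-8").splitlines()
                if line.strip()
            )
        return cls(plant_dictionary=plant, address_dictionary=address, collector_name_pool=names)


# ---------------------------------------------------------------------------
# Field samplers


def render_date(template: str, date: _dt.date) -> str:
    return (
        template.replace("{YYYY}", f"{date.year:04d}")
        .replace("{MONTH}", date.strftime("%B"))
        .replace("{MON}", date.strftime("%b"))
        .replace("{M}", str(date.month))
        .replace("{D}", str(date.day))
    )


def sample_date(
    rng: random.Random,
    templates: Sequence[str] = DATE_TEMPLATES,
    year_range: tuple[int, int] = (1950, 2020),
) -> tuple[str, str]:
    """Draw a random calendar date and render it with a random template.

    Returns ``(surface, iso)``; the surface always parses back to ``iso``
    via :func:`herblabel.record_builder.normalize_date`.
    """
    lo = _dt.date(year_range[0], 1, 1).toordinal()
    hi = _dt.date(year_range[1], 12, 31).toordinal()
    date = _dt.date.fromordinal(rng.randint(lo, hi))
    template = rng.choice(list(templates))
    return render_date(template, date), date.isoformat()


def sample_collector_number(
    rng: random.Random, bounds: tuple[int, int] = (1, 999_999)
) -> int:
    """Uniform collector number in the configured bounds."""
    return rng.randint(bounds[0], bounds[1])


def sample_altitude(
    rng: random.Random,
    bounds: tuple[int, int] = (0, 8000),
    range_prob: float = 0.35,
    range_style: str = "endash",
) -> tuple[str, int, int]:
    """Altitude in meters: single value or a low–high range within bounds."""
    if rng.random() < range_prob:
        a = rng.randint(bounds[0], bounds[1])
        b = rng.randint(bounds[0], bounds[1])
        lo, hi = min(a, b), max(a, b)
        joiner = " to " if range_style == "to" else "–"
        return f"{lo}{joiner}{hi} m", lo, hi
    v = rng.randint(bounds[0], bounds[1])
    return f"{v} m", v, v


def sample_latlong(
    rng: random.Random, templates: Sequence[str] = LATLONG_TEMPLATES
) -> str:
    """One coordinate fragment in a random degenerate label shape."""
    template = rng.choice(list(templates))
    deg = rng.randint(0, 179)
    minute = rng.randint(0, 59)
    sec = rng.randint(0, 59)
    secf = rng.randint(0, 599) / 10
    return (
        template.replace("{DEG}", str(deg))
        .replace("{MIN2}", f"{minute:02d}")
        .replace("{MIN}", str(minute))
        .replace("{SEC2}", f"{sec:02d}")
        .replace("{SECF}", f"{secf:.1f}")
        .replace("{SEC}", str(sec))
    )


# ---------------------------------------------------------------------------
# Document assembly


def _sample_field_value(
    label: EntityLabel,
    config: AugmentationConfig,
    resources: ResourcePack,
    rng: random.Random,
) -> str:
    if label is EntityLabel.DATE:
        return sample_date(rng, config.date_formats, config.date_year_range)[0]
    if label is EntityLabel.NUMBER:
        return str(sample_collector_number(rng, config.collector_number_range))
    if label is EntityLabel.ALT:
        return sample_altitude(
            rng,
            config.altitude_range,
            config.altitude_range_prob,
            config.altitude_range_style,
        )[0]
    if label in (EntityLabel.LAT, EntityLabel.LONG):
        return sample_latlong(rng, config.latlong_formats)
    if label is EntityLabel.PERSON:
        if not resources.collector_name_pool:
            raise ConfigurationError("collector name pool is empty")
        return rng.choice(list(resources.collector_name_pool))
    pool = resources.pool(label)
    if label in _PLACE_LABELS and resources.place_gazetteer is not None:
        alt_pool = resources.place_gazetteer.get(label.value)
        if alt_pool and rng.random() >= config.place_source_mix:
            pool = list(alt_pool)
    if not pool:
        raise ConfigurationError(f"no resource pool for required field {label.value}")
    return rng.choice(pool)


def generate_document(
    config: AugmentationConfig,
    resources: ResourcePack,
    rng: random.Random,
    doc_id: str = "art-000000",
) -> AnnotatedDocument:
    """Assemble one artificial annotated label.

    Fields are included independently per ``field_inclusion_probs``, ordered
    and separated per a randomly chosen layout template, optionally preceded
    by a cue prefix; each value's exact position becomes its gold span.
    """
    max_attempts = 100
    for _ in range(max_attempts):
        included = [
            EntityLabel(name)
            for name, p in config.field_inclusion_probs.items()
            if rng.random() < p
        ]
        if included:
            break
        if config.on_empty == "error":
            raise ConfigurationError("no fields included and on_empty='error'")
    else:
        raise ConfigurationError(
            "no fields included after 100 attempts; raise field_inclusion_probs"
        )

    layout = rng.choice(list(config.layout_templates))
    order = layout.get("order", "random")
    if order == "random":
        rng.shuffle(included)
    else:
        rank = {name: i for i, name in enumerate(order)}
        included.sort(key=lambda lab: (rank.get(lab.value, len(rank)), lab.value))
    separator = rng.choice(list(layout.get("separators", ["\n"])))

    parts: list[str] = []
    spans: list[EntitySpan] = []
    cursor = 0
    person_value: str | None = None
    for i, label in enumerate(included):
        if i > 0:
            parts.append(separator)
            cursor += len(separator)
        prefixes = config.field_prefixes.get(label.value)
        if prefixes and rng.random() < config.prefix_prob:
            prefix = rng.choice(list(prefixes))
            parts.append(prefix)
            cursor += len(prefix)
        value = _sample_field_value(label, config, resources, rng)
        if label is EntityLabel.PERSON:
            person_value = value
        spans.append(EntitySpan(cursor, cursor + len(value), label))
        parts.append(value)
        cursor += len(value)

    text = "".join(parts)
    return AnnotatedDocument(
        doc_id=doc_id,
        text=text,
        spans=tuple(spans),
        source="artificial",
        collector=person_value,
    )


def generate_dataset(
    config: AugmentationConfig, resources: ResourcePack
) -> list[AnnotatedDocument]:
    """Generate ``config.n_records`` artificial labels, seed-deterministic."""
    rng = random.Random(config.seed)
    return [
        generate_document(config, resources, rng, doc_id=f"art-{i:06d}")
        for i in range(config.n_records)
    ]
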