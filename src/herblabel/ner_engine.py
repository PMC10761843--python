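"""Trainable span tagger: tokenizer, BIO codec, averaged perceptron.

The tagging problem — locate and type taxon names, localities, dates,
collectors, numbers, coordinates and altitudes in short multilingual
(Japanese/English/Latin) label texts — is framed as per-token BIO
classification.  The built-in model is an averaged perceptron over sparse
window features (surface, shape, script class, affixes, and optional
gazetteer-membership flags), decoded greedily token by token.  It is small,
dependency-free, fully deterministic for a fixed seed, and serializes to a
single JSON archive, making experiments reproducible on any desktop.

Heavier backends (transformer or CNN pipelines) plug in through the same
train/predict seam: the cross-validation harness accepts any object exposing
``train(docs) -> model`` where the model has ``predict(text) -> spans``.

Tokenization splits Latin/digit runs on whitespace and punctuation and
Japanese text at script-class boundaries (kanji / hiragana / katakana), each
punctuation mark its own token.  Entity spans produced by the generator
always begin and end on these boundaries; hand annotations that do not are
snapped outward to the enclosing tokens rather than dropped.
"""

from __future__ import annotations

import json
import logging
import random
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .corpus_model import AnnotatedDocument, EntityLabel, EntitySpan
from .dict_matcher import LabelDictionary, match as dict_match

__all__ = [
    "Token",
    "TokenizedDocument",
    "TrainConfig",
    "TaggerModel",
    "PerceptronBackend",
    "NERBackend",
    "tokenize",
    "spans_to_bio",
    "bio_to_spans",
    "train",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


@dataclass
class TokenizedDocument:
    """Tokens (with offsets into the source text) plus optional BIO tags."""

    text: str
    tokens: tuple[Token, ...]
    tags: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.tags is not None and len(self.tags) != len(self.tokens):
            raise ValueError("tags length must equal tokens length")


def _script_class(ch: str) -> str:
    code = ord(ch)
    if ch.isspace():
        return "space"
    if 0x3040 <= code <= 0x309F:
        return "hiragana"
    if 0x30A0 <= code <= 0x30FF or code == 0x31F0:
        return "katakana"
    if 0x4E00 <= code <= 0x9FFF or 0x3400 <= code <= 0x4DBF:
        return "kanji"
    if ch.isdigit():
        return "digit"
    if unicodedata.category(ch).startswith("L"):
        return "latin"
    return "punct"


def tokenize(text: str) -> TokenizedDocument:
    """Segment text into offset-bearing tokens.

    Maximal runs of one script class form a token; whitespace separates and
    is skipped; punctuation marks are emitted one per character (so "1979/4"
    gives three tokens).  Concatenating token surfaces and the skipped gaps
    reconstructs the text exactly.
    """
    tokens: list[Token] = []
    i = 0
    n = len(text)
    while i < n:
        cls = _script_class(text[i])
        if cls == "space":
            i += 1
            continue
        if cls == "punct":
            tokens.append(Token(text[i], i, i + 1))
            i += 1
            continue
        j = i + 1
        while j < n and _script_class(text[j]) == cls:
            j += 1
        tokens.append(Token(text[i:j], i, j))
        i = j
    return TokenizedDocument(text=text, tokens=tuple(tokens))


def spans_to_bio(doc: AnnotatedDocument) -> TokenizedDocument:
    """Project a document's spans onto its tokens as BIO tags.

    A span whose boundary falls inside a token is snapped outward to cover
    the whole token (logged); a span overlapping no token at all is dropped
    with a warning.
    """
    tdoc = tokenize(doc.text)
    tags = ["O"] * len(tdoc.tokens)
    for span in doc.spans:
        covered = [
            k
            for k, tok in enumerate(tdoc.tokens)
            if tok.start < span.end and tok.end > span.start
        ]
        if not covered:
            logger.warning(
                "doc %s: span (%d, %d) overlaps no token; dropped",
                doc.doc_id,
                span.start,
                span.end,
            )
            continue
        first, last = covered[0], covered[-1]
        if tdoc.tokens[first].start < span.start or tdoc.tokens[last].end > span.end:
            logger.debug(
                "doc %s: span (%d, %d) snapped to token boundaries (%d, %d)",
                doc.doc_id,
                span.start,
                span.end,
                tdoc.tokens[first].start,
                tdoc.tokens[last].end,
            )
        tags[first] = f"B-{span.label.value}"
        for k in covered[1:]:
            tags[k] = f"I-{span.label.value}"
    return TokenizedDocument(text=tdoc.text, tokens=tdoc.tokens, tags=tuple(tags))


def bio_to_spans(tdoc: TokenizedDocument) -> list[EntitySpan]:
    """Decode BIO tags back to character spans (lenient: a dangling I opens
    a new span)."""
    if tdoc.tags is None:
        raise ValueError("TokenizedDocument has no tags to decode")
    spans: list[EntitySpan] = []
    open_label: str | None = None
    open_start = open_end = 0
    for tok, tag in zip(tdoc.tokens, tdoc.tags):
        if tag == "O":
            prefix, label = "O", None
        else:
            prefix, label = tag.split("-", 1)
        if label is not None and prefix == "I" and label == open_label:
            open_end = tok.end
            continue
        if open_label is not None:
            spans.append(EntitySpan(open_start, open_end, EntityLabel(open_label)))
            open_label = None
        if label is not None:  # B-x, or dangling I-x treated as B-x
            open_label = label
            open_start, open_end = tok.start, tok.end
    if open_label is not None:
        spans.append(EntitySpan(open_start, open_end, EntityLabel(open_label)))
    return spans


# ---------------------------------------------------------------------------
# Features


def _shape(surface: str) -> str:
    out = []
    for ch in surface[:8]:
        if ch.isdigit():
            out.append("d")
        elif ch.isupper():
            out.append("X")
        elif ch.islower():
            out.append("x")
        else:
            out.append(ch)
    return "".join(out)


def _token_features(
    tdoc: TokenizedDocument, dict_flags: Sequence[frozenset[str]] | None
) -> list[list[str]]:
    tokens = tdoc.tokens
    n = len(tokens)
    lowers = [t.surface.casefold() for t in tokens]
    shapes = [_shape(t.surface) for t in tokens]
    scripts = [_script_class(t.surface[0]) for t in tokens]
    feats: list[list[str]] = []
    for i in range(n):
        f = [
            "bias",
            f"w0={lowers[i]}",
            f"s0={shapes[i]}",
            f"c0={scripts[i]}",
            f"p2={lowers[i][:2]}",
            f"p3={lowers[i][:3]}",
            f"f2={lowers[i][-2:]}",
            f"f3={lowers[i][-3:]}",
        ]
        for off in (-2, -1, 1, 2):
            j = i + off
            if 0 <= j < n:
                f.append(f"w{off}={lowers[j]}")
                if off in (-1, 1):
                    f.append(f"s{off}={shapes[j]}")
                    f.append(f"c{off}={scripts[j]}")
            else:
                f.append(f"w{off}=<pad>")
        if dict_flags is not None:
            for flag in dict_flags[i]:
                f.append(f"dict={flag}")
            j = i - 1
            if j >= 0:
                for flag in dict_flags[j]:
                    f.append(f"dict-1={flag}")
        feats.append(f)
    return feats


def _dict_flags_for(
    tdoc: TokenizedDocument, dictionary: LabelDictionary | None
) -> list[frozenset[str]] | None:
    if dictionary is None:
        return None
    hits = dict_match(tdoc.text, dictionary)
    flags: list[set[str]] = [set() for _ in tdoc.tokens]
    for span in hits:
        for k, tok in enumerate(tdoc.tokens):
            if tok.start < span.end and tok.end > span.start:
                flags[k].add(span.label.value)
    return [frozenset(s) for s in flags]


# ---------------------------------------------------------------------------
# Averaged perceptron


@dataclass
class TrainConfig:
    epochs: int = 10
    seed: int = 0
    dictionary: LabelDictionary | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class _AveragedPerceptron:
    """Sparse multiclass perceptron with lazy weight averaging."""

    def __init__(self, tags: Sequence[str]):
        self.tags = list(tags)
        self.weights: dict[str, dict[str, float]] = {}
        self._totals: dict[tuple[str, str], float] = {}
        self._tstamps: dict[tuple[str, str], int] = {}
        self.i = 0

    def score(self, features: Sequence[str]) -> dict[str, float]:
        scores: dict[str, float] = {}
        for f in features:
            by_tag = self.weights.get(f)
            if not by_tag:
                continue
            for tag, w in by_tag.items():
                scores[tag] = scores.get(tag, 0.0) + w
        return scores

    def predict(self, features: Sequence[str]) -> str:
        scores = self.score(features)
        if not scores:
            return "O"
        # deterministic: highest score, ties broken by tag name
        return max(sorted(scores), key=lambda t: scores[t])

    def update(self, truth: str, guess: str, features: Sequence[str]) -> None:
        self.i += 1
        if truth == guess:
            return
        for f in features:
            by_tag = self.weights.setdefault(f, {})
            for tag, delta in ((truth, 1.0), (guess, -1.0)):
                key = (f, tag)
                w = by_tag.get(tag, 0.0)
                self._totals[key] = (
                    self._totals.get(key, 0.0) + (self.i - self._tstamps.get(key, 0)) * w
                )
                self._tstamps[key] = self.i
                by_tag[tag] = w + delta

    def average(self) -> dict[str, dict[str, float]]:
        averaged: dict[str, dict[str, float]] = {}
        for f, by_tag in self.weights.items():
            out = {}
            for tag, w in by_tag.items():
                key = (f, tag)
                total = self._totals.get(key, 0.0) + (self.i - self._tstamps.get(key, 0)) * w
                if self.i:
                    value = round(total / self.i, 6)
                else:
                    value = w
                if value:
                    out[tag] = value
            if out:
                averaged[f] = out
        return averaged


@dataclass
class TaggerModel:
    """A trained, serializable BIO tagger.

    Prediction is deterministic given the archive: greedy per-token argmax
    over averaged weights with lexicographic tie-breaking, followed by
    lenient BIO decoding.  Gazetteer surfaces used as features at training
    time are embedded in the archive so prediction sees identical flags.
    """

    weights: dict[str, dict[str, float]]
    tags: tuple[str, ...]
    epochs: int
    seed: int
    dictionary: LabelDictionary | None = None
    version: int = MODEL_FORMAT_VERSION

    def predict_tags(self, tdoc: TokenizedDocument) -> tuple[str, ...]:
        flags = _dict_flags_for(tdoc, self.dictionary)
        feats = _token_features(tdoc, flags)
        out = []
        for f in feats:
            scores: dict[str, float] = {}
            for feat in f:
                by_tag = self.weights.get(feat)
                if not by_tag:
                    continue
                for tag, w in by_tag.items():
                    scores[tag] = scores.get(tag, 0.0) + w
            out.append(max(sorted(scores), key=lambda t: scores[t]) if scores else "O")
        return tuple(out)

    def predict(self, text: str) -> list[EntitySpan]:
        if not text:
            return []
        tdoc = tokenize(text)
        if not tdoc.tokens:
            return []
        tags = self.predict_tags(tdoc)
        return bio_to_spans(
            TokenizedDocument(text=text, tokens=tdoc.tokens, tags=tags)
        )

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload: dict = {
            "format": "herblabel-tagger",
            "version": self.version,
            "epochs": self.epochs,
            "seed": self.seed,
            "tags": list(self.tags),
            "weights": self.weights,
        }
        if self.dictionary is not None:
            payload["dictionary"] = {
                "min_surface_len": self.dictionary.min_surface_len,
                "priority": list(self.dictionary.priority),
                "entries": {
                    surface: {src: lab.value for src, lab in by_source.items()}
                    for surface, by_source in self.dictionary.entries.items()
                },
                "originals": self.dictionary.originals,
            }
        path.write_text(json.dumps(payload, ensure_ascii=False), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "herblabel-tagger":
            raise ValueError(f"{path}: not a herblabel tagger archive")
        dictionary = None
        if "dictionary" in payload:
            d = payload["dictionary"]
            dictionary = LabelDictionary(
                entries={
                    surface: {src: EntityLabel(lab) for src, lab in by_source.items()}
                    for surface, by_source in d["entries"].items()
                },
                priority=tuple(d["priority"]),
                min_surface_len=d["min_surface_len"],
                originals=dict(d.get("originals", {})),
            )
        return cls(
            weights=payload["weights"],
            tags=tuple(payload["tags"]),
            epochs=payload["epochs"],
            seed=payload["seed"],
            dictionary=dictionary,
            version=payload["version"],
        )


def train(corpus: Sequence[AnnotatedDocument], config: TrainConfig | None = None) -> TaggerModel:
    """Train the built-in tagger on an annotated corpus.

    Examples are shuffled each epoch with the configured seed; mistakes
    trigger the standard +1/−1 perceptron update and final weights are the
    average over all updates, which damps oscillation on small corpora.
    Deterministic for a fixed (corpus order, config).
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    config = config or TrainConfig()
    prepared: list[tuple[list[list[str]], tuple[str, ...]]] = []
    tagset: set[str] = {"O"}
    for doc in corpus:
        tdoc = spans_to_bio(doc)
        if not tdoc.tokens:
            continue
        flags = _dict_flags_for(tdoc, config.dictionary)
        prepared.append((_token_features(tdoc, flags), tdoc.tags))
        tagset.update(tdoc.tags)
    if not prepared:
        raise ValueError("training corpus contains no tokens")
    model = _AveragedPerceptron(sorted(tagset))
    rng = random.Random(config.seed)
    order = list(range(len(prepared)))
    for _ in range(config.epochs):
        rng.shuffle(order)
        for idx in order:
            feats, tags = prepared[idx]
            for f, truth in zip(feats, tags):
                guess = model.predict(f)
                model.update(truth, guess, f)
    return TaggerModel(
        weights=model.average(),
        tags=tuple(sorted(tagset)),
        epochs=config.epochs,
        seed=config.seed,
        dictionary=config.dictionary,
    )


class NERBackend(Protocol):
    """The pluggable training seam the evaluator accepts."""

    def train(self, corpus: Sequence[AnnotatedDocument]) -> "Predictor": ...


class Predictor(Protocol):
    def predict(self, text: str) -> list[EntitySpan]: ...


@dataclass
class PerceptronBackend:
    """The built-in backend: averaged-perceptron BIO tagging."""

    config: TrainConfig = field(default_factory=TrainConfig)

    def train(self, corpus: Sequence[AnnotatedDocument]) -> TaggerModel:
        return train(corpus, self.config)
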