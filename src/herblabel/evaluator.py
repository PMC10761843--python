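"""Entity-level scoring and k-fold cross-validation.

Scoring is strict: a predicted span counts as correct only when its start,
end and label all equal a gold span, each gold span consumed at most once.
Per fold the report carries the pooled gold count (Num_entities), prediction
count (Num_predictions), strict-match count (Num_correct) and the derived
precision C/P, recall C/E and F-value 2C/(P+E) — the harmonic mean of
precision and recall whenever both denominators are positive.  Across folds
the report adds per-column means and sample (n−1) standard deviations.

The three-regime comparison quantifies what rule-generated artificial
training data buys: train on the manual folds alone, on manual folds plus
the artificial pool, or on the artificial pool alone — the held-out test
fold is always manually annotated documents, because the question is
generalization to real labels, not to more synthetic ones.
"""

from __future__ import annotations

import math
import random
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .corpus_model import AnnotatedDocument, EntitySpan
from .ner_engine import NERBackend

__all__ = [
    "FoldMetrics",
    "CVReport",
    "Regime",
    "count_correct",
    "compute_metrics",
    "kfold_split",
    "cross_validate",
    "render_report",
]

Regime = Literal["manual", "manual+artificial", "artificial_only"]
REGIME_ORDER: tuple[str, ...] = ("manual", "manual+artificial", "artificial_only")

_COLUMNS = (
    "num_entities",
    "num_predictions",
    "num_correct",
    "precision",
    "recall",
    "f_value",
)


@dataclass(frozen=True)
class FoldMetrics:
    """Strict entity-level counts and ratios for one evaluation set."""

    num_entities: float
    num_predictions: float
    num_correct: float
    precision: float
    recall: float
    f_value: float
    degenerate: bool = False  # a zero denominator was conventionally scored 0

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, c) for c in _COLUMNS)


def count_correct(
    gold: Sequence[EntitySpan], predicted: Sequence[EntitySpan]
) -> int:
    """Number of predictions exactly matching a gold span (start, end,
    label), with each gold span matched at most once."""
    gold_counter = Counter((s.start, s.end, s.label) for s in gold)
    correct = 0
    for span in predicted:
        key = (span.start, span.end, span.label)
        if gold_counter.get(key, 0) > 0:
            gold_counter[key] -= 1
            correct += 1
    return correct


def compute_metrics(
    num_entities: float, num_predictions: float, num_correct: float
) -> FoldMetrics:
    """Derive precision/recall/F from counts (fractional fold-mean counts
    are accepted).  Zero denominators score 0 and set ``degenerate``."""
    if num_correct > min(num_entities, num_predictions) + 1e-9:
        raise ValueError(
            f"num_correct={num_correct} exceeds "
            f"min(num_entities={num_entities}, num_predictions={num_predictions})"
        )
    if min(num_entities, num_predictions, num_correct) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = num_predictions == 0 or num_entities == 0
    precision = num_correct / num_predictions if num_predictions else 0.0
    recall = num_correct / num_entities if num_entities else 0.0
    denom = num_predictions + num_entities
    f_value = 2 * num_correct / denom if denom else 0.0
    return FoldMetrics(
        num_entities=num_entities,
        num_predictions=num_predictions,
        num_correct=num_correct,
        precision=precision,
        recall=recall,
        f_value=f_value,
        degenerate=degenerate,
    )


def kfold_split(
    corpus: Sequence[AnnotatedDocument], k: int, seed: int = 0
) -> list[list[AnnotatedDocument]]:
    """Shuffle-partition the corpus into k folds with sizes differing by at
    most one; reproducible for a fixed seed."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(corpus):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
    indices = list(range(len(corpus)))
    random.Random(seed).shuffle(indices)
    base, extra = divmod(len(indices), k)
    folds: list[list[AnnotatedDocument]] = []
    pos = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append([corpus[j] for j in indices[pos : pos + size]])
        pos += size
    return folds


def _evaluate_fold(
    predictor, test_docs: Sequence[AnnotatedDocument]
) -> FoldMetrics:
    E = P = C = 0
    for doc in test_docs:
        predicted = predictor.predict(doc.text)
        E += len(doc.spans)
        P += len(predicted)
        C += count_correct(doc.spans, predicted)
    return compute_metrics(E, P, C)


@dataclass
class CVReport:
    """k-fold results for one (regime, k): per-fold metrics plus summary."""

    k: int
    regime: str
    folds: list[FoldMetrics]
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.folds) != self.k:
            raise ValueError("folds length must equal k")
        values = {c: [getattr(f, c) for f in self.folds] for c in _COLUMNS}
        self.mean = {c: statistics.fmean(v) for c, v in values.items()}
        self.sd = {
            c: (statistics.stdev(v) if len(v) > 1 else math.nan)
            for c, v in values.items()
        }

    def micro(self) -> FoldMetrics:
        """Metrics from counts pooled over all folds (ratio-of-sums)."""
        return compute_metrics(
            sum(f.num_entities for f in self.folds),
            sum(f.num_predictions for f in self.folds),
            sum(f.num_correct for f in self.folds),
        )


def cross_validate(
    corpus: Sequence[AnnotatedDocument],
    backend: NERBackend,
    k: int,
    seed: int = 0,
    regime: str = "manual",
    augment_pool: Sequence[AnnotatedDocument] | None = None,
) -> CVReport:
    """k-fold cross-validation of a backend under one training regime.

    ``manual``: train on the k−1 training folds only.
    ``manual+artificial``: training folds plus the whole artificial pool.
    ``artificial_only``: the artificial pool only (folds still rotate the
    test set).

    When an ``augment_pool`` is supplied the run is a regime comparison and
    the corpus must consist of manually annotated documents — testing on
    artificial data would measure recall of the generator's own rules, not
    generalization to real labels.
    """
    if regime not in REGIME_ORDER:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIME_ORDER}")
    if regime in ("manual+artificial", "artificial_only") and not augment_pool:
        raise ValueError(f"regime {regime!r} requires a non-empty augment_pool")
    if augment_pool is not None:
        bad = [d.doc_id for d in corpus if d.source != "manual"]
        if bad:
            raise ValueError(
                "regime comparison requires manual-source test documents; "
                f"offending ids: {bad[:5]}"
            )
    folds = kfold_split(corpus, k, seed)
    metrics: list[FoldMetrics] = []
    for i in range(k):
        test_docs = folds[i]
        train_docs = [d for j in range(k) if j != i for d in folds[j]]
        if regime == "manual":
            regime_train = train_docs
        elif regime == "manual+artificial":
            regime_train = train_docs + list(augment_pool)
        else:
            regime_train = list(augment_pool)
        predictor = backend.train(regime_train)
        metrics.append(_evaluate_fold(predictor, test_docs))
    return CVReport(k=k, regime=regime, folds=metrics)


def render_report(reports: Sequence[CVReport]) -> pd.DataFrame:
    """Lay out reports as the conventional comparison table.

    One Mean and one S.D. row per (regime, k), regimes in fixed order
    (manual, manual+artificial, artificial_only), counts printed to 1
    decimal place and ratios to 3.
    """
    if not reports:
        raise ValueError("no reports to render")
    ordered = sorted(
        reports, key=lambda r: (REGIME_ORDER.index(r.regime), r.k)
    )
    rows = []
    for report in ordered:
        for stat, values in (("Mean", report.mean), ("S.D.", report.sd)):
            row: dict[str, object] = {
                "regime": report.regime,
                "k": report.k,
                "stat": stat,
            }
            for column in _COLUMNS:
                v = values[column]
                if column.startswith("num_"):
                    row[column] = round(v, 1) if not math.isnan(v) else v
                else:
                    row[column] = round(v, 3) if not math.isnan(v) else v
            rows.append(row)
    return pd.DataFrame(rows, columns=["regime", "k", "stat", *_COLUMNS])
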