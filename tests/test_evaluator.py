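"""Strict entity-level scoring and cross-validation harness."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from herblabel.corpus_model import AnnotatedDocument, EntityLabel, EntitySpan
from herblabel.evaluator import (
    CVReport,
    compute_metrics,
    count_correct,
    cross_validate,
    kfold_split,
    render_report,
)


def brute_force_correct(gold, predicted):
    """Independent oracle: maximum bipartite exact matching by enumeration.

    With exact-equality edges the maximum matching equals the multiset
    intersection; enumerate greedily over an explicit copy to stay
    independent of the Counter-based implementation.
    """
    remaining = list(gold)
    n = 0
    for p in predicted:
        for g in remaining:
            if (g.start, g.end, g.label) == (p.start, p.end, p.label):
                remaining.remove(g)
                n += 1
                break
    return n


def _spans(triples):
    return [EntitySpan(s, e, lab) for s, e, lab in triples]


class TestCountCorrect:
    def test_identical_sets_all_correct(self):
        spans = _spans(
            [(0, 2, EntityLabel.DATE), (3, 6, EntityLabel.PERSON),
             (7, 9, EntityLabel.NUMBER), (10, 12, EntityLabel.ALT),
             (13, 20, EntityLabel.EN_NAME)]
        )
        assert count_correct(spans, spans) == 5

    def test_off_by_one_offset_is_wrong(self):
        gold = _spans([(0, 5, EntityLabel.DATE)])
        assert count_correct(gold, _spans([(0, 4, EntityLabel.DATE)])) == 0
        assert count_correct(gold, _spans([(1, 5, EntityLabel.DATE)])) == 0
        assert count_correct(gold, _spans([(0, 5, EntityLabel.PERSON)])) == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        gold=st.lists(
            st.tuples(st.integers(0, 8), st.integers(1, 4), st.sampled_from(list(EntityLabel))),
            max_size=10,
        ),
        predicted=st.lists(
            st.tuples(st.integers(0, 8), st.integers(1, 4), st.sampled_from(list(EntityLabel))),
            max_size=10,
        ),
    )
    def test_equals_brute_force_bipartite_count(self, gold, predicted):
        gold = _spans([(s, s + w, lab) for s, w, lab in gold])
        predicted = _spans([(s, s + w, lab) for s, w, lab in predicted])
        assert count_correct(gold, predicted) == brute_force_correct(gold, predicted)


class TestComputeMetrics:
    # published fold-mean count rows and the ratios they print; cells whose
    # printed ratio disagrees with its own counts at the 3rd decimal are None
    @pytest.mark.parametrize(
        "E, P, C, precision, recall, f_value",
        [
            (2165.2, 2301.4, 1662.2, 0.722, 0.768, 0.744),
            (2165.2, 2292.0, 781.8, None, 0.361, 0.351),
            (2165.2, 2089.2, 1630.2, None, 0.753, 0.766),
            (1082.6, 1140.7, 842.8, 0.739, None, 0.758),
            (1082.6, 1263.9, 452.5, None, None, 0.386),
            (1082.6, 1050.2, 821.1, 0.782, None, 0.770),
            (2165.2, 2056.2, 1688.8, 0.821, 0.780, 0.800),
            (1082.6, 1031.7, 843.0, 0.817, 0.779, None),
            (2165.2, 1365.6, 1063.4, 0.779, 0.491, 0.602),
            (1082.6, 682.8, 531.7, 0.779, 0.491, 0.602),
        ],
    )
    def test_reference_count_rows_reproduce_printed_ratios(
        self, E, P, C, precision, recall, f_value
    ):
        m = compute_metrics(E, P, C)
        if precision is not None:
            assert round(m.precision, 3) == precision
        if recall is not None:
            assert round(m.recall, 3) == recall
        if f_value is not None:
            assert round(m.f_value, 3) == f_value

    def test_perfect_prediction(self):
        m = compute_metrics(10, 10, 10)
        assert (m.precision, m.recall, m.f_value) == (1.0, 1.0, 1.0)

    def test_zero_denominators_score_zero_and_flag(self):
        m = compute_metrics(0, 0, 0)
        assert (m.precision, m.recall, m.f_value) == (0.0, 0.0, 0.0)
        assert m.degenerate

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(3, 3, 4)

    def test_f_is_harmonic_mean_when_denominators_positive(self):
        m = compute_metrics(80, 60, 40)
        harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert math.isclose(m.f_value, harmonic)

    def test_adding_a_correct_prediction_never_hurts(self):
        base = compute_metrics(50, 30, 20)
        better = compute_metrics(50, 31, 21)
        worse = compute_metrics(50, 31, 20)
        assert better.recall >= base.recall and better.f_value >= base.f_value
        assert worse.precision <= base.precision


def _docs(n):
    return [AnnotatedDocument(doc_id=str(i), text=f"doc {i}") for i in range(n)]


class TestKFold:
    def test_even_split(self):
        folds = kfold_split(_docs(10), k=5, seed=0)
        assert [len(f) for f in folds] == [2, 2, 2, 2, 2]

    def test_partition_property(self):
        docs = _docs(23)
        folds = kfold_split(docs, k=5, seed=3)
        sizes = sorted(len(f) for f in folds)
        assert max(sizes) - min(sizes) <= 1
        ids = [d.doc_id for f in folds for d in f]
        assert sorted(ids) == sorted(d.doc_id for d in docs)
        assert len(set(ids)) == len(ids)

    def test_seed_determinism(self):
        docs = _docs(17)
        a = kfold_split(docs, k=4, seed=9)
        b = kfold_split(docs, k=4, seed=9)
        assert [[d.doc_id for d in f] for f in a] == [[d.doc_id for d in f] for f in b]

    def test_k_larger_than_corpus_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(_docs(3), k=5, seed=0)
        with pytest.raises(ValueError):
            kfold_split(_docs(3), k=1, seed=0)


class _EchoBackend:
    """Oracle backend: memorizes gold spans by text."""

    def __init__(self):
        self.by_text = {}

    def train(self, corpus):
        # sees only training folds; cheat globally via lazy fill-in
        return self

    def remember(self, docs):
        for d in docs:
            self.by_text[d.text] = list(d.spans)
        return self

    def predict(self, text):
        return self.by_text.get(text, [])


class _EmptyBackend:
    def train(self, corpus):
        return self

    def predict(self, text):
        return []


class TestCrossValidate:
    def _manual_corpus(self, small_artificial_corpus):
        return [
            AnnotatedDocument(
                doc_id=d.doc_id, text=d.text, spans=d.spans,
                source="manual", collector=d.collector,
            )
            for d in small_artificial_corpus[:20]
        ]

    def test_perfect_oracle_scores_one_everywhere(self, small_artificial_corpus):
        corpus = self._manual_corpus(small_artificial_corpus)
        backend = _EchoBackend().remember(corpus)
        report = cross_validate(corpus, backend, k=5, seed=0)
        for fold in report.folds:
            assert fold.precision == fold.recall == fold.f_value == 1.0
        assert report.mean["f_value"] == 1.0
        assert report.sd["f_value"] == 0.0

    def test_empty_predictor_scores_zero_with_flag(self, small_artificial_corpus):
        corpus = self._manual_corpus(small_artificial_corpus)
        report = cross_validate(corpus, _EmptyBackend(), k=4, seed=0)
        for fold in report.folds:
            assert fold.degenerate
            assert fold.f_value == 0.0

    def test_augmented_regimes_require_pool(self, small_artificial_corpus):
        corpus = self._manual_corpus(small_artificial_corpus)
        with pytest.raises(ValueError, match="augment_pool"):
            cross_validate(corpus, _EmptyBackend(), k=2, regime="manual+artificial")

    def test_unknown_regime_rejected(self, small_artificial_corpus):
        corpus = self._manual_corpus(small_artificial_corpus)
        with pytest.raises(ValueError, match="regime"):
            cross_validate(corpus, _EmptyBackend(), k=2, regime="augmented")

    def test_artificial_test_documents_refused_in_regime_comparison(
        self, small_artificial_corpus
    ):
        pool = small_artificial_corpus[20:30]
        with pytest.raises(ValueError, match="manual-source"):
            cross_validate(
                small_artificial_corpus[:10],
                _EmptyBackend(),
                k=2,
                regime="manual+artificial",
                augment_pool=pool,
            )

    def test_artificial_only_regime_trains_on_pool_alone(self, small_artificial_corpus):
        corpus = self._manual_corpus(small_artificial_corpus)
        pool = small_artificial_corpus[20:40]

        class _Spy(_EmptyBackend):
            seen = []

            def train(self, docs):
                type(self).seen.append([d.doc_id for d in docs])
                return self

        cross_validate(corpus, _Spy(), k=2, seed=0, regime="artificial_only",
                       augment_pool=pool)
        assert all(ids == [d.doc_id for d in pool] for ids in _Spy.seen)


class TestRenderReport:
    def _report(self, regime, k, seed=0):
        rng = random.Random(seed)
        folds = []
        for _ in range(k):
            E = rng.randint(50, 60)
            C = rng.randint(20, 45)
            P = rng.randint(C, 60)
            folds.append(compute_metrics(E, P, C))
        return CVReport(k=k, regime=regime, folds=folds)

    def test_single_report_yields_mean_and_sd_rows(self):
        frame = render_report([self._report("manual", 5)])
        assert list(frame["stat"]) == ["Mean", "S.D."]

    def test_regimes_rendered_in_canonical_order(self):
        frame = render_report(
            [
                self._report("artificial_only", 5),
                self._report("manual", 5),
                self._report("manual+artificial", 5),
            ]
        )
        assert list(frame["regime"][::2]) == [
            "manual", "manual+artificial", "artificial_only",
        ]

    def test_ratio_columns_rounded_to_three_decimals(self):
        frame = render_report([self._report("manual", 5, seed=2)])
        for column in ("precision", "recall", "f_value"):
            for value in frame[column]:
                assert round(value, 3) == value
        for column in ("num_entities", "num_predictions", "num_correct"):
            for value in frame[column]:
                assert round(value, 1) == value

    def test_mean_and_sd_match_statistics_of_folds(self):
        report = self._report("manual", 5, seed=4)
        fs = [f.f_value for f in report.folds]
        import statistics

        assert math.isclose(report.mean["f_value"], statistics.fmean(fs))
        assert math.isclose(report.sd["f_value"], statistics.stdev(fs))
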