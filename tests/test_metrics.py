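import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headct_nlp.decoder import InjuryStatus, ReportSummary
from headct_nlp.lexicon import DECODER_CATEGORIES
from headct_nlp.metrics import (
    ConfusionCounts,
    bootstrap_ci,
    collapse_status,
    decoder_metrics,
    f_score,
    kfold,
    ner_metrics,
    prf,
    score_decoder,
    score_ner,
    score_ner_per_entity,
    split_corpus,
)
from headct_nlp.tagger import EntitySpan


def span(report_id="r1", idx=0, start=0, end=5, entity="edema", surface="edema"):
    return EntitySpan(report_id, idx, start, end, surface, entity, "INJURY")


class TestPRF:
    def test_published_row_reproduced(self):
        """F = 2PR/(P+R) on precision 97.50% and recall 99.32% gives 98.40%."""
        f = f_score(0.9750, 0.9932)
        assert round(100 * f, 2) == 98.40

    def test_perfect(self):
        assert prf(ConfusionCounts(tp=5)) == (1.0, 1.0, 1.0)

    def test_all_wrong(self):
        assert prf(ConfusionCounts(tp=0, fp=3, fn=2)) == (0.0, 0.0, 0.0)

    def test_undefined_precision_warns(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            prf(ConfusionCounts(tp=0, fp=0, fn=2))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    def test_harmonic_mean_identity(self, tp, fp, fn):
        p, r, f = prf(ConfusionCounts(tp, fp, fn))
        assert abs(f - f_score(p, r)) < 1e-12
        if p == r:
            assert abs(f - p) < 1e-12


class TestScoreNER:
    def test_identical(self):
        spans = [span(start=i * 10) for i in range(5)]
        assert score_ner(spans, spans) == ConfusionCounts(5, 0, 0)

    def test_wrong_entity_is_fp_plus_fn(self):
        pred = [span(entity="edema")]
        gold = [span(entity="hemorrhage")]
        assert score_ner(pred, gold) == ConfusionCounts(0, 1, 1)

    def test_empty_prediction(self):
        gold = [span(start=i) for i in range(3)]
        assert score_ner([], gold) == ConfusionCounts(0, 0, 3)

    def test_offset_shift_not_matched(self):
        assert score_ner([span(start=1, end=6)], [span(start=0, end=5)]) == (
            ConfusionCounts(0, 1, 1)
        )

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 8), max_size=8), st.lists(st.integers(0, 8), max_size=8))
    def test_symmetry(self, a_starts, b_starts):
        a = [span(start=s, end=s + 1) for s in a_starts]
        b = [span(start=s, end=s + 1) for s in b_starts]
        ab, ba = score_ner(a, b), score_ner(b, a)
        assert ab.tp == ba.tp and ab.fp == ba.fn and ab.fn == ba.fp

    def test_per_entity_breakdown(self):
        pred = [span(entity="edema"), span(start=10, end=15, entity="hemorrhage")]
        gold = [span(entity="edema")]
        per = score_ner_per_entity(pred, gold)
        assert per["edema"] == ConfusionCounts(1, 0, 0)
        assert per["hemorrhage"] == ConfusionCounts(0, 1, 0)


def summary(report_id, **labels):
    s = ReportSummary(report_id=report_id)
    for cat, status in labels.items():
        s.labels[cat] = status
    return s


class TestScoreDecoder:
    def test_identical_tables(self):
        a = [summary("r1", edema=InjuryStatus.POSITIVE)]
        pooled, _ = score_decoder(a, a)
        assert pooled.fp == 0 and pooled.fn == 0
        assert pooled.tp == len(DECODER_CATEGORIES)

    def test_negative_equals_not_mentioned(self):
        pred = [summary("r1", edema=InjuryStatus.NOT_MENTIONED)]
        gold = [summary("r1", edema=InjuryStatus.NEGATIVE)]
        pooled, _ = score_decoder(pred, gold)
        assert pooled.fp == 0 and pooled.fn == 0

    def test_possible_vs_positive_is_error(self):
        pred = [summary("r1", edema=InjuryStatus.POSSIBLE)]
        gold = [summary("r1", edema=InjuryStatus.POSITIVE)]
        pooled, per = score_decoder(pred, gold)
        assert pooled.fp == 1 and pooled.fn == 1
        assert per["edema"] == ConfusionCounts(12, 1, 1) or per["edema"].fp == 1

    def test_mismatched_report_sets_rejected(self):
        with pytest.raises(ValueError):
            score_decoder([summary("r1")], [summary("r2")])

    def test_sklearn_micro_cross_check(self):
        """Micro-averaged one-vs-rest P/R over the collapsed 3-class labels
        equals sklearn's micro precision/recall on the same label pairs."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        statuses = list(InjuryStatus)
        pred, gold = [], []
        for i in range(40):
            pred.append(
                summary(f"r{i}", **{c: statuses[rng.integers(0, 4)] for c in DECODER_CATEGORIES})
            )
            gold.append(
                summary(f"r{i}", **{c: statuses[rng.integers(0, 4)] for c in DECODER_CATEGORIES})
            )
        pooled, _ = score_decoder(pred, gold)
        p, r, f = prf(pooled)
        y_pred = [collapse_status(s.labels[c]) for s in pred for c in DECODER_CATEGORIES]
        y_gold = [collapse_status(s.labels[c]) for s in gold for c in DECODER_CATEGORIES]
        sp, sr, sf, _ = sklearn_metrics.precision_recall_fscore_support(
            y_gold, y_pred, average="micro"
        )
        assert abs(p - sp) < 1e-12 and abs(r - sr) < 1e-12 and abs(f - sf) < 1e-12


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        lo, hi = bootstrap_ci([1.0] * 50, np.mean, n_iter=100, seed=0)
        assert lo == hi == 1.0

    def test_seed_reproducibility(self):
        items = list(np.random.default_rng(1).normal(size=200))
        a = bootstrap_ci(items, np.mean, n_iter=200, seed=7)
        b = bootstrap_ci(items, np.mean, n_iter=200, seed=7)
        assert a == b

    def test_empty_items_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([], np.mean)

    def test_bernoulli_interval_matches_closed_form(self):
        """For a mean of n=5000 Bernoulli(0.5) draws the 95% percentile
        interval should approximate p-hat +/- 1.96*sqrt(p(1-p)/n), a
        half-width of about 0.0139."""
        rng = np.random.default_rng(2024)
        items = list((rng.random(5000) < 0.5).astype(float))
        p_hat = float(np.mean(items))
        lo, hi = bootstrap_ci(items, np.mean, n_iter=1000, resample_size=5000, seed=9)
        assert lo <= p_hat <= hi
        half = (hi - lo) / 2
        assert 0.0139 * 0.7 < half < 0.0139 * 1.3


class TestAggregateMetrics:
    def test_perfect_ner_metrics(self):
        spans = [span(idx=i, start=0, end=5) for i in range(30)]
        res = ner_metrics(spans, spans, n_iter=50, resample_size=30, seed=0)
        assert res.precision == res.recall == res.f_score == 1.0
        assert res.ci["f_score"] == (1.0, 1.0)
        assert res.resample_unit == "sentence"

    def test_perfect_decoder_metrics(self):
        cohort = [summary(f"r{i}", edema=InjuryStatus.POSITIVE) for i in range(20)]
        res = decoder_metrics(cohort, cohort, n_iter=50, resample_size=20, seed=0)
        assert res.f_score == 1.0
        assert res.resample_unit == "report"

    def test_percent_rendering(self):
        spans = [span(idx=i) for i in range(10)]
        res = ner_metrics(spans, spans, n_iter=10, resample_size=10, seed=0)
        d = res.as_percent_dict()
        assert d["precision"] == 100.0 and d["f_score_ci_high"] == 100.0


class TestSplit:
    def test_published_corpus_arithmetic(self):
        """3361 single-report patients at 75% train: 2521 train, 840 test."""
        plan = split_corpus({f"r{i}": f"p{i}" for i in range(3361)}, 0.75, seed=0)
        assert len(plan.train_report_ids) == 2521
        assert len(plan.test_report_ids) == 840

    def test_four_reports(self):
        plan = split_corpus({c: c for c in "abcd"}, 0.75, seed=1)
        assert len(plan.train_report_ids) == 3

    def test_patients_not_split(self):
        mapping = {"r1": "pA", "r2": "pA", "r3": "pB", "r4": "pB"}
        plan = split_corpus(mapping, 0.5, seed=3)
        for pid in ("pA", "pB"):
            sides = {plan.assignment[r] for r, p in mapping.items() if p == pid}
            assert len(sides) == 1

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_corpus({"r": "p"}, 1.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation(self, seed):
        mapping = {f"r{i}": f"p{i // 3}" for i in range(100)}
        plan = split_corpus(mapping, 0.75, seed=seed)
        assert len(plan.train_report_ids) + len(plan.test_report_ids) == 100

    def test_seed_changes_assignment(self):
        mapping = {f"r{i}": f"p{i}" for i in range(50)}
        a = split_corpus(mapping, 0.5, seed=0).assignment
        b = split_corpus(mapping, 0.5, seed=1).assignment
        assert a != b


class TestKFold:
    def test_singleton_folds(self):
        folds = kfold([f"p{i}" for i in range(10)], k=10, seed=0)
        assert sorted(folds.values()) == list(range(10))

    def test_balanced_partition(self):
        folds = kfold([f"p{i}" for i in range(25)], k=10, seed=0)
        sizes = sorted(
            sum(1 for f in folds.values() if f == i) for i in range(10)
        )
        assert sizes == [2] * 5 + [3] * 5

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            kfold(["p1"], k=10)

    def test_every_patient_exactly_one_fold(self):
        patients = [f"p{i}" for i in range(33)]
        folds = kfold(patients, k=10, seed=4)
        assert set(folds) == set(patients)
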