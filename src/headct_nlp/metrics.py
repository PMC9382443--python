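"""Evaluation harness: P/R/F, bootstrap CIs, patient-level splits, k-fold.

Precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R).  Confidence
intervals are percentile bootstrap (2.5th/97.5th percentiles of the
statistic over seeded resamples drawn with replacement); defaults follow
the evaluation configuration this harness reproduces: 1000 iterations,
resampling 5000 sentences for NER scoring and 100 reports for decoder
scoring.

Corpus splitting is per patient: all reports of one patient land on the
same side of the train/test split and in the same cross-validation fold,
avoiding within-person correlation between partitions.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .decoder import InjuryStatus, ReportSummary
from .lexicon import DECODER_CATEGORIES
from .tagger import EntitySpan

NER_RESAMPLE_SIZE = 5000  # sentences per bootstrap resample
DECODER_RESAMPLE_SIZE = 100  # reports per bootstrap resample
BOOTSTRAP_ITERATIONS = 1000


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricResult:
    """Point estimates (fractions in [0, 1]) with percentile-bootstrap CIs."""

    precision: float
    recall: float
    f_score: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_resamples: int = 0
    resample_unit: str = ""
    resample_size: int = 0
    seed: Optional[int] = None

    def as_percent_dict(self, decimals: int = 2) -> dict[str, float]:
        out = {
            "precision": round(100 * self.precision, decimals),
            "recall": round(100 * self.recall, decimals),
            "f_score": round(100 * self.f_score, decimals),
        }
        for name, (lo, hi) in self.ci.items():
            out[f"{name}_ci_low"] = round(100 * lo, decimals)
            out[f"{name}_ci_high"] = round(100 * hi, decimals)
        return out


def prf(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F score from TP/FP/FN counts.

    Degenerate denominators (no predicted positives, or no gold positives)
    yield 0.0 with a warning rather than an error, so pooled evaluations
    over sparse categories stay total.
    """
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined (tp+fp=0); reporting 0", stacklevel=2)
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("recall undefined (tp+fn=0); reporting 0", stacklevel=2)
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------

def _span_key(s: EntitySpan) -> tuple:
    return (s.report_id, s.sentence_index, s.start, s.end, s.entity)


def score_ner(
    predicted: Iterable[EntitySpan], gold: Iterable[EntitySpan]
) -> ConfusionCounts:
    """Strict span-level scoring: a true positive needs exact agreement on
    sentence, character offsets, and entity; anything else is one FP (the
    prediction) and/or one FN (the gold span)."""
    pred_counts = Counter(_span_key(s) for s in predicted)
    gold_counts = Counter(_span_key(s) for s in gold)
    tp = sum((pred_counts & gold_counts).values())
    fp = sum((pred_counts - gold_counts).values())
    fn = sum((gold_counts - pred_counts).values())
    return ConfusionCounts(tp, fp, fn)


def score_ner_per_entity(
    predicted: Iterable[EntitySpan], gold: Iterable[EntitySpan]
) -> dict[str, ConfusionCounts]:
    """Strict scoring broken down by entity name."""
    out: dict[str, ConfusionCounts] = {}
    entities = {s.entity for s in predicted} | {s.entity for s in gold}
    predicted = list(predicted)
    gold = list(gold)
    for e in sorted(entities):
        out[e] = score_ner(
            (s for s in predicted if s.entity == e),
            (s for s in gold if s.entity == e),
        )
    return out


#: Evaluation collapses NEGATIVE and NOT_MENTIONED: a pertinent negative and
#: a non-mention count as the same (absent) class.
_COLLAPSE = {
    InjuryStatus.POSITIVE: "POSITIVE",
    InjuryStatus.POSSIBLE: "POSSIBLE",
    InjuryStatus.NEGATIVE: "ABSENT",
    InjuryStatus.NOT_MENTIONED: "ABSENT",
}
EVAL_CLASSES = ("POSITIVE", "POSSIBLE", "ABSENT")


def collapse_status(status: InjuryStatus) -> str:
    return _COLLAPSE[status]


def score_decoder(
    predicted: Sequence[ReportSummary],
    gold: Sequence[ReportSummary],
    categories: Sequence[str] = DECODER_CATEGORIES,
) -> tuple[ConfusionCounts, dict[str, ConfusionCounts]]:
    """Report-level decoder scoring.

    Statuses collapse to three classes (POSITIVE, POSSIBLE, ABSENT); TP/FP/FN
    are tallied one-vs-rest per class and micro-pooled, both per category and
    overall.  Returns ``(pooled, per_category)``.
    """
    pred_by_id = {s.report_id: s for s in predicted}
    gold_by_id = {s.report_id: s for s in gold}
    if set(pred_by_id) != set(gold_by_id):
        raise ValueError("predicted and gold summaries cover different report sets")
    per_category: dict[str, ConfusionCounts] = {}
    pooled = ConfusionCounts()
    for cat in categories:
        counts = ConfusionCounts()
        for rid, g in gold_by_id.items():
            gc = collapse_status(g.labels[cat])
            pc = collapse_status(pred_by_id[rid].labels[cat])
            if gc == pc:
                counts += ConfusionCounts(tp=1)
            else:
                counts += ConfusionCounts(fp=1, fn=1)
        per_category[cat] = counts
        pooled += counts
    return pooled, per_category


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

def bootstrap_ci(
    items: Sequence,
    statistic: Callable[[Sequence], float],
    n_iter: int = BOOTSTRAP_ITERATIONS,
    resample_size: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Percentile-bootstrap 95% interval of ``statistic`` over ``items``.

    Each of ``n_iter`` iterations draws ``resample_size`` items with
    replacement (default: len(items)) and recomputes the statistic; the
    interval is the 2.5th/97.5th percentile of the resulting distribution.
    """
    items = list(items)
    if not items:
        raise ValueError("cannot bootstrap an empty item list")
    if resample_size is None:
        resample_size = len(items)
    rng = np.random.default_rng(seed)
    values = np.empty(n_iter)
    n = len(items)
    # Numeric items resample via array fancy-indexing; arbitrary objects
    # (e.g. per-unit confusion counts) go through plain lists.
    arr = np.asarray(items)
    numeric = arr.dtype != object
    for i in range(n_iter):
        idx = rng.integers(0, n, size=resample_size)
        if numeric:
            values[i] = statistic(arr[idx])
        else:
            values[i] = statistic([items[j] for j in idx])
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def _grouped(items: Sequence, key: Callable) -> dict[Hashable, list]:
    groups: dict[Hashable, list] = {}
    for it in items:
        groups.setdefault(key(it), []).append(it)
    return groups


def ner_metrics(
    predicted: Sequence[EntitySpan],
    gold: Sequence[EntitySpan],
    n_iter: int = BOOTSTRAP_ITERATIONS,
    resample_size: int = NER_RESAMPLE_SIZE,
    seed: Optional[int] = None,
) -> MetricResult:
    """Micro-averaged strict NER P/R/F with sentence-resampled bootstrap CIs.

    The bootstrap unit is the sentence: each resample draws sentences with
    replacement and re-pools their span confusion counts.
    """
    key = lambda s: (s.report_id, s.sentence_index)  # noqa: E731
    pred_groups = _grouped(predicted, key)
    gold_groups = _grouped(gold, key)
    sentences = sorted(set(pred_groups) | set(gold_groups))
    per_sentence = [
        score_ner(pred_groups.get(k, []), gold_groups.get(k, [])) for k in sentences
    ]
    return _metric_result_from_units(
        per_sentence, "sentence", n_iter, resample_size, seed
    )


def decoder_metrics(
    predicted: Sequence[ReportSummary],
    gold: Sequence[ReportSummary],
    n_iter: int = BOOTSTRAP_ITERATIONS,
    resample_size: int = DECODER_RESAMPLE_SIZE,
    seed: Optional[int] = None,
) -> MetricResult:
    """Pooled decoder P/R/F with report-resampled bootstrap CIs."""
    gold_by_id = {s.report_id: s for s in gold}
    per_report = [
        score_decoder([p], [gold_by_id[p.report_id]])[0] for p in predicted
    ]
    return _metric_result_from_units(per_report, "report", n_iter, resample_size, seed)


def _metric_result_from_units(
    units: Sequence[ConfusionCounts],
    unit_name: str,
    n_iter: int,
    resample_size: int,
    seed: Optional[int],
) -> MetricResult:
    pooled = sum(units, ConfusionCounts())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f = prf(pooled)
    result = MetricResult(
        precision=p,
        recall=r,
        f_score=f,
        n_resamples=n_iter,
        resample_unit=unit_name,
        resample_size=resample_size,
        seed=seed,
    )
    if units and n_iter > 0:
        arr = np.array([[c.tp, c.fp, c.fn] for c in units])
        rng = np.random.default_rng(seed)
        stats = {"precision": np.empty(n_iter), "recall": np.empty(n_iter),
                 "f_score": np.empty(n_iter)}
        n = len(units)
        for i in range(n_iter):
            idx = rng.integers(0, n, size=resample_size)
            tp, fp, fn = arr[idx].sum(axis=0)
            pp = tp / (tp + fp) if tp + fp else 0.0
            rr = tp / (tp + fn) if tp + fn else 0.0
            stats["precision"][i] = pp
            stats["recall"][i] = rr
            stats["f_score"][i] = f_score(pp, rr)
        for name, vals in stats.items():
            lo, hi = np.percentile(vals, [2.5, 97.5])
            result.ci[name] = (float(lo), float(hi))
    return result


# --------------------------------------------------------------------------
# Corpus splitting
# --------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Patient-level train/test assignment with optional k-fold folds."""

    assignment: dict[str, str]  # report_id -> TRAIN | TEST
    patient_of: dict[str, str]  # report_id -> patient_id
    folds: dict[str, int] = field(default_factory=dict)  # patient_id -> fold
    train_fraction: float = 0.75
    seed: Optional[int] = None

    @property
    def train_report_ids(self) -> list[str]:
        return [r for r, a in self.assignment.items() if a == "TRAIN"]

    @property
    def test_report_ids(self) -> list[str]:
        return [r for r, a in self.assignment.items() if a == "TEST"]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


def split_corpus(
    report_patients: Mapping[str, str],
    train_fraction: float = 0.75,
    seed: Optional[int] = None,
) -> SplitPlan:
    """Assign reports to TRAIN/TEST at the patient level.

    Patients are shuffled by ``seed`` and assigned to TRAIN, whole patients
    at a time, until the training report count first reaches
    round-half-up(train_fraction * N); all remaining patients go to TEST.
    All of one patient's reports always share an assignment.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_reports = len(report_patients)
    target = round_half_up(train_fraction * n_reports)
    by_patient: dict[str, list[str]] = {}
    for rid, pid in report_patients.items():
        by_patient.setdefault(pid, []).append(rid)
    patients = sorted(by_patient)
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    assignment: dict[str, str] = {}
    n_train = 0
    for pid in patients:
        side = "TRAIN" if n_train < target else "TEST"
        for rid in by_patient[pid]:
            assignment[rid] = side
        if side == "TRAIN":
            n_train += len(by_patient[pid])
    return SplitPlan(
        assignment=assignment,
        patient_of=dict(report_patients),
        train_fraction=train_fraction,
        seed=seed,
    )


def kfold(
    patients: Sequence[str], k: int = 10, seed: Optional[int] = None
) -> dict[str, int]:
    """Partition patients into ``k`` folds whose sizes differ by at most 1."""
    patients = list(dict.fromkeys(patients))
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = sorted(patients)
    rng.shuffle(order)
    return {pid: i % k for i, pid in enumerate(order)}
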