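"""Post-level evaluation: confusion counts, the nine-metric suite, Cohen's
kappa inter-annotator agreement, and gold-set splitting.

The evaluation unit is the post x class binary decision: a class is
"predicted" for a post when the mention table contains at least one mention
of any of its attributes, and "gold" when the gold annotation does.
Negatives (and hence specificity, NPV, FPR) are only definable at this
level; span-overlap scoring is out of scope. Ratios with a zero denominator
are reported as ``None`` (not available), never coerced to 0.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "GoldAnnotation",
    "ConfusionCounts",
    "MetricSet",
    "AgreementResult",
    "METRIC_ORDER",
    "split_gold",
    "confusion",
    "metrics",
    "f1_score",
    "cohen_kappa",
    "kappa_for_class",
    "evaluate_all",
    "EvaluationReport",
]

METRIC_ORDER = (
    "sensitivity",
    "specificity",
    "precision",
    "npv",
    "fpr",
    "fdr",
    "fnr",
    "accuracy",
    "f1",
)


@dataclass(frozen=True)
class GoldAnnotation:
    """Gold labels for one post: a set of (class_id, attribute_id) pairs."""

    post_id: str
    labels: frozenset
    spans: tuple = ()

    def classes(self) -> set[str]:
        return {class_id for class_id, _ in self.labels}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class MetricSet:
    """The nine per-class performance statistics; ``None`` marks an
    undefined (zero-denominator) ratio."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    npv: Optional[float]
    fpr: Optional[float]
    fdr: Optional[float]
    fnr: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_ORDER}


@dataclass(frozen=True)
class AgreementResult:
    observed_agreement: float
    expected_agreement: float
    kappa: Optional[float]


def split_gold(
    gold: Sequence[GoldAnnotation],
    n_train: int,
    n_test: int,
    n_valid: int,
    seed: int,
) -> tuple[list[GoldAnnotation], list[GoldAnnotation], list[GoldAnnotation]]:
    """Seeded random partition into disjoint train/test/validation subsets
    of exactly the requested sizes."""
    if min(n_train, n_test, n_valid) < 0:
        raise ValueError("subset sizes must be non-negative")
    if n_train + n_test + n_valid > len(gold):
        raise ValueError(
            f"requested {n_train + n_test + n_valid} posts from a gold set of {len(gold)}"
        )
    indices = list(range(len(gold)))
    random.Random(seed).shuffle(indices)
    train_idx = indices[:n_train]
    test_idx = indices[n_train : n_train + n_test]
    valid_idx = indices[n_train + n_test : n_train + n_test + n_valid]
    return (
        [gold[i] for i in train_idx],
        [gold[i] for i in test_idx],
        [gold[i] for i in valid_idx],
    )


def _predicted_classes(predicted) -> dict[str, set[str]]:
    """Accept a mention table (objects with post_id/class_id) or a mapping
    post_id -> iterable of class ids."""
    if isinstance(predicted, Mapping):
        return {pid: set(classes) for pid, classes in predicted.items()}
    by_post: dict[str, set[str]] = {}
    for m in predicted:
        by_post.setdefault(m.post_id, set()).add(m.class_id)
    return by_post


def confusion(gold: Sequence[GoldAnnotation], predicted, class_id: str) -> ConfusionCounts:
    """Post-level binary confusion counts for one class.

    The post universe is the gold annotation set; a prediction for a post
    outside it is an input error.
    """
    universe = {g.post_id for g in gold}
    if len(universe) != len(gold):
        raise ValueError("duplicate post_id in gold annotations")
    pred = _predicted_classes(predicted)
    unknown = set(pred) - universe
    if unknown:
        raise ValueError(f"predictions for posts absent from gold universe: {sorted(unknown)[:5]}")
    tp = fp = fn = tn = 0
    for g in gold:
        in_gold = class_id in g.classes()
        in_pred = class_id in pred.get(g.post_id, set())
        if in_gold and in_pred:
            tp += 1
        elif in_pred:
            fp += 1
        elif in_gold:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def f1_score(precision: float, recall: float) -> Optional[float]:
    """Harmonic mean of precision and recall; None when both are zero."""
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Compute the nine-metric suite from post-level confusion counts."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    precision = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    fpr = _ratio(c.fp, c.fp + c.tn)
    fdr = _ratio(c.fp, c.fp + c.tp)
    fnr = _ratio(c.fn, c.fn + c.tp)
    accuracy = (c.tp + c.tn) / c.total
    f1 = (
        f1_score(precision, sensitivity)
        if precision is not None and sensitivity is not None
        else None
    )
    return MetricSet(
        sensitivity=sensitivity, specificity=specificity, precision=precision,
        npv=npv, fpr=fpr, fdr=fdr, fnr=fnr, accuracy=accuracy, f1=f1,
    )


def cohen_kappa(a: Sequence[Hashable], b: Sequence[Hashable]) -> AgreementResult:
    """Cohen's kappa between two aligned annotation sequences.

    ``p_o`` is the fraction of items with identical labels; ``p_e`` sums the
    products of the two annotators' marginal label frequencies. When
    ``p_e = 1`` (degenerate single-category marginals) kappa is reported as
    not available.
    """
    if len(a) != len(b):
        raise ValueError("annotation sequences must label the same items")
    n = len(a)
    if n == 0:
        raise ValueError("empty annotation sequences")
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    marg_a = Counter(a)
    marg_b = Counter(b)
    p_e = sum(
        (marg_a[cat] / n) * (marg_b.get(cat, 0) / n) for cat in marg_a
    )
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else None
    return AgreementResult(observed_agreement=p_o, expected_agreement=p_e, kappa=kappa)


def kappa_for_class(
    a: Sequence[GoldAnnotation], b: Sequence[GoldAnnotation], class_id: str
) -> AgreementResult:
    """Per-class kappa: restrict both annotation sets to presence/absence of
    one class, aligned on post_id."""
    by_id_b = {g.post_id: g for g in b}
    if set(by_id_b) != {g.post_id for g in a}:
        raise ValueError("annotation sets must cover the same posts")
    seq_a = [class_id in g.classes() for g in a]
    seq_b = [class_id in by_id_b[g.post_id].classes() for g in a]
    return cohen_kappa(seq_a, seq_b)


@dataclass
class EvaluationReport:
    """Per-class metric sets plus pooled (micro) and macro overall columns,
    ordered by the lexicon's class order."""

    per_class: dict[str, MetricSet]
    per_class_counts: dict[str, ConfusionCounts]
    overall: MetricSet
    overall_counts: ConfusionCounts
    macro: MetricSet

    def to_frame(self):
        import pandas as pd

        columns = {"Overall": self.overall.as_dict()}
        for class_id, ms in self.per_class.items():
            columns[class_id] = ms.as_dict()
        columns["Macro"] = self.macro.as_dict()
        return pd.DataFrame(columns, index=list(METRIC_ORDER))


def _macro(per_class: dict[str, MetricSet]) -> MetricSet:
    values = {}
    for name in METRIC_ORDER:
        defined = [getattr(ms, name) for ms in per_class.values() if getattr(ms, name) is not None]
        values[name] = sum(defined) / len(defined) if defined else None
    return MetricSet(**values)


def evaluate_all(gold: Sequence[GoldAnnotation], predicted, lex) -> EvaluationReport:
    """Table-shaped report: one metric column per lexicon class plus an
    Overall column obtained by micro-averaging (pooling confusion counts
    over classes) and a macro average for transparency."""
    per_class_counts: dict[str, ConfusionCounts] = {}
    per_class: dict[str, MetricSet] = {}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for class_id in lex.class_ids():
        c = confusion(gold, predicted, class_id)
        per_class_counts[class_id] = c
        per_class[class_id] = metrics(c)
        pooled = pooled + c
    return EvaluationReport(
        per_class=per_class,
        per_class_counts=per_class_counts,
        overall=metrics(pooled),
        overall_counts=pooled,
        macro=_macro(per_class),
    )
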