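import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlner import (
    ConfusionCounts,
    GoldAnnotation,
    cohen_kappa,
    confusion,
    evaluate_all,
    f1_score,
    metrics,
    split_gold,
)
from hlner.evaluation import METRIC_ORDER, kappa_for_class

counts_st = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 500), fp=st.integers(0, 500),
    fn=st.integers(0, 500), tn=st.integers(0, 500),
).filter(lambda c: c.total > 0)


def _gold(pid, *pairs):
    return GoldAnnotation(post_id=pid, labels=frozenset(pairs))


class TestSplitGold:
    def _gold_set(self, n):
        return [_gold(f"p{i}") for i in range(n)]

    def test_paper_sizes(self):
        gold = self._gold_set(2000)
        train, test, valid = split_gold(gold, 1200, 300, 500, seed=42)
        assert (len(train), len(test), len(valid)) == (1200, 300, 500)
        ids = [g.post_id for g in train + test + valid]
        assert len(set(ids)) == 2000

    def test_all_in_validation(self):
        gold = self._gold_set(10)
        train, test, valid = split_gold(gold, 0, 0, 10, seed=1)
        assert train == [] and test == [] and len(valid) == 10

    def test_deterministic(self):
        gold = self._gold_set(50)
        assert split_gold(gold, 20, 10, 10, seed=7) == split_gold(gold, 20, 10, 10, seed=7)

    def test_oversubscription_rejected(self):
        with pytest.raises(ValueError):
            split_gold(self._gold_set(5), 3, 2, 1, seed=0)


class TestConfusion:
    def test_minimal(self):
        gold = [_gold("p1", ("A", "a1")), _gold("p2")]
        c = confusion(gold, {"p1": {"A"}}, "A")
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 1)

    def test_twenty_post_fixture(self):
        # 8 true positives, 2 false positives, 1 false negative, 9 true negatives
        gold, pred = [], {}
        for i in range(8):
            gold.append(_gold(f"tp{i}", ("A", "x")))
            pred[f"tp{i}"] = {"A"}
        for i in range(2):
            gold.append(_gold(f"fp{i}"))
            pred[f"fp{i}"] = {"A"}
        gold.append(_gold("fn0", ("A", "x")))
        for i in range(9):
            gold.append(_gold(f"tn{i}"))
        c = confusion(gold, pred, "A")
        assert (c.tp, c.fp, c.fn, c.tn) == (8, 2, 1, 9)
        assert c.total == 20

    def test_empty_predictions(self):
        gold = [_gold("p1", ("A", "a")), _gold("p2")]
        c = confusion(gold, {}, "A")
        assert (c.tp, c.fp) == (0, 0)
        assert (c.fn, c.tn) == (1, 1)

    def test_prediction_outside_universe(self):
        with pytest.raises(ValueError, match="absent from gold"):
            confusion([_gold("p1")], {"ghost": {"A"}}, "A")

    def test_accepts_mention_table(self, lex):
        from hlner.matcher import Mention

        gold = [_gold("p1", ("treatment", "chemotherapy")), _gold("p2")]
        table = [Mention("p1", "treatment", "chemotherapy", 0, 5, "chemo", "chemo", 0)]
        c = confusion(gold, table, "treatment")
        assert (c.tp, c.tn) == (1, 1)


class TestMetrics:
    def test_hand_computed(self):
        ms = metrics(ConfusionCounts(tp=8, fp=2, fn=1, tn=9))
        assert ms.precision == pytest.approx(0.8)
        assert ms.sensitivity == pytest.approx(8 / 9)
        assert ms.accuracy == pytest.approx(0.85)

    def test_perfect(self):
        ms = metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=0))
        assert ms.sensitivity == ms.precision == ms.accuracy == ms.f1 == 1.0
        assert ms.fdr == ms.fnr == 0.0
        assert ms.specificity is None  # no negatives -> undefined, not 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_undefined_reported_as_none(self):
        ms = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert ms.sensitivity is None
        assert ms.precision is None
        assert ms.specificity == 1.0

    def test_f1_harmonic_mean(self):
        assert f1_score(0.97, 0.93) == pytest.approx(2 * 0.97 * 0.93 / (0.97 + 0.93))
        assert f1_score(0.0, 0.0) is None

    @given(counts_st)
    @settings(max_examples=1000, deadline=None)
    def test_identity_suite(self, c):
        ms = metrics(c)
        if ms.precision is not None:
            assert ms.precision + ms.fdr == pytest.approx(1.0)
        if ms.sensitivity is not None:
            assert ms.sensitivity + ms.fnr == pytest.approx(1.0)
        if ms.specificity is not None:
            assert ms.specificity + ms.fpr == pytest.approx(1.0)
        if ms.f1 is not None and ms.precision and ms.sensitivity:
            assert min(ms.precision, ms.sensitivity) <= ms.f1 + 1e-12
            assert ms.f1 <= max(ms.precision, ms.sensitivity) + 1e-12
            harmonic = 2 / (1 / ms.precision + 1 / ms.sensitivity)
            assert ms.f1 == pytest.approx(harmonic)

    def test_f1_monotone_in_tp(self):
        f1s = [metrics(ConfusionCounts(tp=tp, fp=3, fn=2, tn=5)).f1 for tp in range(1, 30)]
        assert all(a <= b + 1e-12 for a, b in zip(f1s, f1s[1:]))


class TestCohenKappa:
    def test_identical_annotators(self):
        labels = ["x", "y", "x", "z", "y", "x"]
        res = cohen_kappa(labels, labels)
        assert res.kappa == pytest.approx(1.0)
        assert res.observed_agreement == 1.0

    def test_hand_computed_2x2(self):
        # a=20 both yes, b=5 yes/no, c=10 no/yes, d=15 both no
        a = [True] * 25 + [False] * 25
        b = [True] * 20 + [False] * 5 + [True] * 10 + [False] * 15
        res = cohen_kappa(a, b)
        assert res.observed_agreement == pytest.approx(0.7)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.4)

    def test_independent_annotators_near_zero(self):
        rng = random.Random(99)
        n = 10_000
        a = [rng.random() < 0.5 for _ in range(n)]
        b = [rng.random() < 0.5 for _ in range(n)]
        res = cohen_kappa(a, b)
        assert abs(res.kappa) < 0.05

    def test_symmetric(self):
        rng = random.Random(3)
        a = [rng.choice("xyz") for _ in range(200)]
        b = [rng.choice("xyz") for _ in range(200)]
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa(b, a).kappa)

    def test_relabel_invariant(self):
        rng = random.Random(4)
        a = [rng.choice("xy") for _ in range(300)]
        b = [rng.choice("xy") for _ in range(300)]
        mapping = {"x": "blue", "y": "red"}
        res1 = cohen_kappa(a, b)
        res2 = cohen_kappa([mapping[v] for v in a], [mapping[v] for v in b])
        assert res1.kappa == pytest.approx(res2.kappa)

    def test_degenerate_marginals(self):
        res = cohen_kappa(["x"] * 5, ["x"] * 5)
        assert res.kappa is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 2], [1])

    def test_per_class_restriction(self):
        a = [_gold("p1", ("A", "x")), _gold("p2"), _gold("p3", ("A", "y"))]
        b = [_gold("p1", ("A", "z")), _gold("p2"), _gold("p3")]
        res = kappa_for_class(a, b, "A")
        assert res.observed_agreement == pytest.approx(2 / 3)


class TestEvaluateAll:
    def test_single_class_equals_overall(self, lex):
        gold = [_gold("p1", ("treatment", "chemotherapy")), _gold("p2")]
        pred = {"p1": {"treatment"}}
        report = evaluate_all(gold, pred, lex)
        assert report.overall.accuracy == report.per_class["treatment"].accuracy == 1.0

    def test_perfect_predictions(self, lex):
        gold = [
            _gold("p1", ("treatment", "chemotherapy"), ("symptoms", "fever")),
            _gold("p2", ("etiopathology", "ebv")),
            _gold("p3"),
        ]
        pred = {"p1": {"treatment", "symptoms"}, "p2": {"etiopathology"}}
        report = evaluate_all(gold, pred, lex)
        assert report.overall.accuracy == 1.0
        assert report.overall.fpr == 0.0

    def test_overall_is_pooled_counts(self, lex):
        from hlner.evaluation import metrics as compute

        rng = random.Random(11)
        classes = lex.class_ids()
        gold, pred = [], {}
        for i in range(60):
            g = {(c, "any") for c in classes if rng.random() < 0.3}
            p = {c for c in classes if rng.random() < 0.3}
            gold.append(GoldAnnotation(post_id=f"p{i}", labels=frozenset(g)))
            pred[f"p{i}"] = p
        report = evaluate_all(gold, pred, lex)
        pooled = sum(report.per_class_counts.values(), ConfusionCounts(0, 0, 0, 0))
        assert report.overall == compute(pooled)
        assert pooled.total == 60 * len(classes)

    def test_frame_layout(self, lex):
        gold = [_gold("p1", ("treatment", "chemotherapy")), _gold("p2")]
        frame = evaluate_all(gold, {"p1": {"treatment"}}, lex).to_frame()
        assert list(frame.index) == list(METRIC_ORDER)
        assert frame.columns[0] == "Overall"
        assert set(lex.class_ids()) <= set(frame.columns)
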