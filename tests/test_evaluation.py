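import random

import pytest

from stroketext import (
    ConfusionMatrix,
    Report,
    STROKE_SCHEMA,
    binary_metrics,
    categorical_metrics,
    confusion,
    discrepancy_report,
    load_default_rules,
    percent_agreement,
    predict_corpus,
    prevalence,
    split_corpus,
    validate_labels,
)
from stroketext.evaluation import (
    EmptyEvaluationError,
    PairingError,
    round1,
)

P, A = "present", "absent"


class TestConfusion:
    def test_enumerated_four_items(self):
        cm = confusion([P, P, A, A], [P, A, A, P], P)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        cm = confusion([P, A, P], [P, A, P], P)
        assert cm.fp == cm.fn == 0

    def test_all_negative(self):
        cm = confusion([A] * 10, [A] * 10, P)
        assert (cm.tn, cm.tp, cm.fp, cm.fn) == (10, 0, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            confusion([P], [P, A], P)


class TestBinaryMetrics:
    def test_hand_computed_matrix(self):
        # tp=45 fn=5 tn=340 fp=9: all five metrics recomputed by hand
        row = binary_metrics(ConfusionMatrix(tp=45, fp=9, tn=340, fn=5)).rows[0]
        assert round1(row.sensitivity) == 90.0  # 45/50
        assert round1(row.specificity) == 97.4  # 340/349
        assert round1(row.ppv) == 83.3  # 45/54
        assert round1(row.npv) == 98.6  # 340/345
        assert round1(row.accuracy) == 96.5  # 385/399
        assert row.prevalence_n == 50
        assert round1(row.prevalence_pct) == 12.5

    def test_zero_denominator_is_undefined_not_exception(self):
        row = binary_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0)).rows[0]
        assert row.sensitivity is None
        assert row.ppv is None
        assert row.specificity == 100.0

    def test_perfect_matrix(self):
        row = binary_metrics(ConfusionMatrix(tp=3, fp=0, tn=7, fn=0)).rows[0]
        assert (
            row.sensitivity, row.specificity, row.ppv, row.npv, row.accuracy
        ) == (100.0, 100.0, 100.0, 100.0, 100.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyEvaluationError):
            binary_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_oracle_equivalence_sklearn(self):
        """Counts and metrics agree with scikit-learn's confusion matrix
        on 1000 random gold/prediction pairs."""
        from sklearn.metrics import confusion_matrix as sk_cm

        rng = random.Random(20240)
        gold = [rng.choice([P, A]) for _ in range(1000)]
        pred = [rng.choice([P, A]) for _ in range(1000)]
        cm = confusion(gold, pred, P)
        tn, fp, fn, tp = sk_cm(gold, pred, labels=[A, P]).ravel()
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)
        row = binary_metrics(cm).rows[0]
        assert row.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert row.specificity == pytest.approx(100 * tn / (tn + fp))
        assert row.accuracy == pytest.approx(100 * (tp + tn) / 1000)

    def test_accuracy_decomposes_over_prevalence(self):
        rng = random.Random(5)
        for _ in range(50):
            tp, fp, tn, fn = (rng.randint(1, 40) for _ in range(4))
            row = binary_metrics(ConfusionMatrix(tp, fp, tn, fn)).rows[0]
            n = tp + fp + tn + fn
            prev = (tp + fn) / n
            expected = row.sensitivity * prev + row.specificity * (1 - prev)
            assert row.accuracy == pytest.approx(expected)


class TestCategoricalMetrics:
    def test_perfect_three_class(self):
        report = categorical_metrics(
            ["lt5", "ge5", "not_reported"],
            ["lt5", "ge5", "not_reported"],
            STROKE_SCHEMA["aspects"],
        )
        assert report.overall_accuracy == 100.0
        for row in report.rows:
            assert row.accuracy == 100.0

    def test_two_of_three(self):
        report = categorical_metrics(
            ["not_reported", "lt5", "ge5"],
            ["not_reported", "lt5", "lt5"],
            STROKE_SCHEMA["aspects"],
        )
        assert round1(report.overall_accuracy) == 66.7

    def test_one_vs_rest_equals_brute_force_relabel(self):
        """Each class row equals relabelling to positive/rest and running
        the binary confusion — the brute-force oracle."""
        rng = random.Random(99)
        attr = STROKE_SCHEMA["collaterals"]
        gold = [rng.choice(attr.classes) for _ in range(300)]
        pred = [rng.choice(attr.classes) for _ in range(300)]
        report = categorical_metrics(gold, pred, attr)
        for row in report.rows:
            g = ["pos" if x == row.class_label else "rest" for x in gold]
            p = ["pos" if x == row.class_label else "rest" for x in pred]
            assert row.cm == confusion(g, p, "pos")

    def test_overall_accuracy_invariant_under_relabeling(self):
        rng = random.Random(13)
        attr = STROKE_SCHEMA["aspects"]
        gold = [rng.choice(attr.classes) for _ in range(200)]
        pred = [rng.choice(attr.classes) for _ in range(200)]
        base = categorical_metrics(gold, pred, attr).overall_accuracy
        mapping = dict(zip(attr.classes, ("ge5", "not_reported", "lt5")))
        remapped = categorical_metrics(
            [mapping[g] for g in gold], [mapping[p] for p in pred], attr
        ).overall_accuracy
        assert base == remapped


class TestPrevalenceAndAgreement:
    @pytest.mark.parametrize(
        "count, n, pct",
        [(161, 1320, 12.2), (384, 1320, 29.1), (0, 10, 0.0)],
    )
    def test_prevalence(self, count, n, pct):
        labels = [P] * count + [A] * (n - count)
        assert prevalence(labels, P) == (count, pct)

    def test_agreement_examples(self):
        assert percent_agreement([P, A, A], [P, A, A]) == 100.0
        assert percent_agreement([P, A, A, A, A], [A, A, A, A, A]) == 80.0

    def test_agreement_symmetric(self):
        rng = random.Random(3)
        a = [rng.choice([P, A]) for _ in range(100)]
        b = [rng.choice([P, A]) for _ in range(100)]
        assert percent_agreement(a, b) == percent_agreement(b, a)


class TestDiscrepancies:
    def test_perfect_predictions_give_no_records(self, small_corpus):
        rules = load_default_rules()
        preds = predict_corpus(small_corpus, rules)
        # clean synthetic corpus: engine recovers gold exactly
        assert discrepancy_report(small_corpus, preds) == []

    def test_figure_style_false_positive_traced(self, default_rules):
        report = Report(
            "fp1",
            "Near-occlusion of the cavernous internal carotid artery with "
            "reconstitution of flow in the M1 segment.",
            labels=validate_labels({"lvo": "absent"}),
        )
        preds = predict_corpus([report], default_rules)
        records = discrepancy_report([report], preds)
        assert len(records) == 1
        rec = records[0]
        assert (rec.attribute, rec.gold, rec.predicted) == ("lvo", A, P)
        assert any(t["rule_id"] == "lvo_occl_proximal" for t in rec.trace)
        assert rec.resolution == "unresolved"

    def test_record_count_equals_fp_plus_fn(self, default_rules):
        """Cross-check against the confusion matrices of a corpus with
        injected errors."""
        from stroketext import SimConfig, generate_corpus

        corpus = generate_corpus(
            SimConfig(
                n_reports=150,
                seed=11,
                hard_rates={
                    "ica_to_m2_extension": 0.2,
                    "cavernous_reconstitution": 0.2,
                },
            )
        )
        preds = predict_corpus(corpus, default_rules)
        records = discrepancy_report(corpus, preds)
        total = 0
        for attr in STROKE_SCHEMA:
            gold = [r.labels[attr] for r in corpus]
            pred = [p.classes[attr] for p in preds]
            total += sum(g != p for g, p in zip(gold, pred))
        assert len(records) == total


class TestSplit:
    def test_published_cohort_sizes(self):
        corpus = [Report(str(i), "") for i in range(1320)]
        train, valid = split_corpus(corpus, 921 / 1320, seed=1)
        assert (len(train), len(valid)) == (921, 399)
        assert {r.id for r in train} | {r.id for r in valid} == {
            r.id for r in corpus
        }
        assert not ({r.id for r in train} & {r.id for r in valid})

    def test_same_seed_same_partition(self):
        corpus = [Report(str(i), "") for i in range(100)]
        a = split_corpus(corpus, 0.7, seed=9)
        b = split_corpus(corpus, 0.7, seed=9)
        assert a == b

    def test_different_seeds_differ(self):
        corpus = [Report(str(i), "") for i in range(1320)]
        partitions = {
            tuple(r.id for r in split_corpus(corpus, 921 / 1320, seed=s)[0])
            for s in range(10)
        }
        assert len(partitions) >= 9

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_corpus([Report("a", "")], 1.0, seed=0)
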