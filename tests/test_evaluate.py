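import numpy as np
import pytest

import renalflow as rf
from renalflow import cnn, dataset as dsm, evaluate as ev
from renalflow import waveform_synth as ws
from renalflow.errors import ConfigurationError, DataError


class TestConfusion:
    def test_enumerated_counts(self):
        cm = ev.confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0, 1])
        cm = ev.confusion(y, y)
        assert cm.fp == cm.fn == 0
        assert cm.tp + cm.tn == 5

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        cm = ev.confusion(y, p)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for yi, pi in zip(y, p):
            key = ("t" if yi == pi else "f") + ("p" if pi == 1 else "n")
            tally[key] += 1
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"],
        )

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            ev.confusion([1, 0], [1])


class TestMetrics:
    def test_symmetric_case(self):
        m = ev.metrics(ev.ConfusionMatrix(tp=9, fp=1, fn=1, tn=9))
        for v in (m.accuracy, m.precision, m.recall, m.specificity, m.f1):
            assert v == pytest.approx(0.9)

    def test_undefined_precision_reported_as_none(self):
        m = ev.metrics(ev.ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert m.precision is None
        assert m.recall == 0.0

    def test_matches_formula_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 50, 4))
            if tp + fp + fn + tn == 0:
                continue
            m = ev.metrics(ev.ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
            total = tp + fp + fn + tn
            assert m.accuracy == pytest.approx((tp + tn) / total, abs=1e-12)
            if tp + fp > 0:
                assert m.precision == pytest.approx(tp / (tp + fp), abs=1e-12)
            if tp + fn > 0:
                assert m.recall == pytest.approx(tp / (tp + fn), abs=1e-12)
            if tn + fp > 0:
                assert m.specificity == pytest.approx(tn / (tn + fp), abs=1e-12)
            if m.precision and m.recall:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall), abs=1e-12
                )


def mann_whitney_auc(labels, scores):
    """Brute-force pairwise-comparison AUC oracle (half credit for ties)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    u = 0.0
    for a in pos:
        for b in neg:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        curve = ev.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert curve.auc == pytest.approx(1.0)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0

    def test_all_tied_scores_give_diagonal(self):
        curve = ev.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert curve.auc == pytest.approx(0.5)

    def test_equals_u_statistic_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 500)
        y[:2] = [0, 1]
        # quantized scores force plenty of ties
        s = np.round(rng.normal(size=500) + y, 1)
        curve = ev.roc_auc(y, s)
        assert curve.auc == pytest.approx(mann_whitney_auc(y, s), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            ev.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestSummarizeFolds:
    def test_published_precision_interval(self):
        s = ev.summarize_from_moments(0.9487, 0.0568, k=5, metric="precision")
        assert round(s.ci_low, 4) == 0.8989
        assert round(s.ci_high, 4) == 0.9985
        assert round(s.variance, 4) == 0.0032

    def test_published_auc_interval_lower_bound(self):
        s = ev.summarize_from_moments(0.9759, 0.0159, k=5, metric="roc_auc")
        assert round(s.ci_low, 4) == 0.9620
        assert round(s.variance, 4) == 0.0003

    def test_identical_values_collapse_interval(self):
        s = ev.summarize_folds([0.8] * 5)
        assert s.sd == 0.0
        assert s.variance == 0.0
        assert (s.ci_low, s.ci_high) == (0.8, 0.8)

    def test_variance_is_squared_sd(self):
        s = ev.summarize_folds([0.9, 0.92, 0.95, 0.91, 0.97])
        assert s.variance == pytest.approx(s.sd**2, abs=1e-15)
        assert s.ci_low <= s.mean <= s.ci_high

    def test_requires_at_least_two_values(self):
        with pytest.raises(ConfigurationError):
            ev.summarize_folds([0.9])


@pytest.fixture(scope="module")
def cv_setup():
    cohort = ws.generate_cohort(15, seed=31)
    ds = rf.Datasheet.from_signals(ws.cohort_signals(cohort))
    split = rf.split_train_test(ds, fraction=0.2, seed=31)
    folds = rf.make_folds(split.train_patients, k=5, seed=31)
    return ds, split, folds


@pytest.fixture(scope="module")
def cv_result(cv_setup):
    ds, split, folds = cv_setup
    return ev.run_cross_validation(
        ds, split, folds, train_cfg=cnn.TrainConfig(epochs=2, seed=31)
    )


class TestCrossValidation:
    def test_every_training_signal_validated_exactly_once(self, cv_setup, cv_result):
        ds, split, folds = cv_setup
        val_ids = [sid for fr in cv_result.fold_results for sid in fr.val_ids]
        assert sorted(val_ids) == sorted(split.train_ids)

    def test_no_patient_straddles_folds_or_split(self, cv_setup):
        ds, split, folds = cv_setup
        assert not set(split.train_patients) & set(split.test_patients)
        seen = set()
        for fold in folds:
            assert not seen & set(fold)
            seen |= set(fold)

    def test_test_rows_untouched_by_cv(self, cv_setup, cv_result):
        ds, split, _ = cv_setup
        assert cv_result.test_checksum == ds.subset_by_signal_ids(split.test_ids).checksum()

    def test_fold_metrics_within_unit_interval(self, cv_result):
        for fr in cv_result.fold_results:
            for name, value in fr.metrics.items():
                if value is not None:
                    assert 0.0 <= value <= 1.0

    def test_consistency_unanimous_for_identical_models(self, cv_setup, toy_training_set):
        ds, split, _ = cv_setup
        x, y = toy_training_set
        tm = cnn.fit(x, y, tcfg=cnn.TrainConfig(epochs=1, seed=0))
        report = ev.consistency_report(
            [tm] * 5, ds.velocities(), ds.signal_ids()
        )
        assert report.unanimous_fraction == 1.0
        assert report.agreement.all()


class TestFinalEvaluation:
    def test_report_reproduces_metric_formulas(self, cv_setup):
        ds, split, _ = cv_setup
        rep = ev.final_evaluation(
            ds, split, train_cfg=cnn.TrainConfig(epochs=2, seed=31)
        )
        recomputed = ev.metrics(ev.confusion(
            ds.subset_by_signal_ids(split.test_ids).labels01(), rep.predictions
        )).as_dict()
        for name, value in recomputed.items():
            assert rep.metrics[name] == value
        assert rep.confusion.total == len(split.test_ids)
        assert rep.test_checksum == ds.subset_by_signal_ids(split.test_ids).checksum()
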