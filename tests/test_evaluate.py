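import numpy as np
import pytest

from dnahyb import evaluate as ev
from _oracles import auroc_pairwise, mcc_formula


class TestBinarise:
    @pytest.mark.parametrize("value,expected", [
        (0.19, "Low"),
        (0.20, "High"),   # the boundary itself is High
        (0.0, "Low"),
        (1.0, "High"),
    ])
    def test_threshold_rule(self, value, expected):
        assert ev.binarise([value]) == [expected]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.binarise([1.5])


class TestClassificationReport:
    def test_perfect_predictor(self):
        truth = [0.05, 0.9, 0.15, 0.95, 0.5]
        report = ev.classification_report(truth, truth)
        assert report.mcc == 1.0
        assert report.auroc == 1.0
        assert report.per_class["High"].f1 == 1.0
        assert report.per_class["Low"].f1 == 1.0
        assert report.mse == 0.0

    def test_inverted_predictor(self):
        truth = [0.0, 1.0, 0.0, 1.0]
        pred = [1.0, 0.0, 1.0, 0.0]
        report = ev.classification_report(truth, pred)
        assert report.mcc == -1.0
        assert report.auroc == 0.0

    def test_contingency_formula(self):
        # TP=90 FP=10 FN=20 TN=80 constructed explicitly
        truth = ["High"] * 110 + ["Low"] * 90
        pred = [1.0] * 90 + [0.0] * 20 + [1.0] * 10 + [0.0] * 80
        report = ev.classification_report(truth, pred)
        assert (report.tp, report.fp, report.fn, report.tn) == (90, 10, 20, 80)
        assert report.mcc == pytest.approx(mcc_formula(90, 10, 20, 80))

    def test_confusion_counts_sum(self, rng):
        truth = rng.random(200)
        scores = rng.random(200)
        report = ev.classification_report(truth, scores)
        assert report.n == 200

    def test_mcc_auroc_agree_with_oracles_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            truth_bits = rng.integers(0, 2, n)
            while truth_bits.sum() in (0, n):
                truth_bits = rng.integers(0, 2, n)
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = ["High" if t else "Low" for t in truth_bits]
            report = ev.classification_report(labels, scores)
            assert report.auroc == pytest.approx(
                auroc_pairwise(truth_bits, scores), abs=1e-12)
            assert report.mcc == pytest.approx(
                mcc_formula(report.tp, report.fp, report.fn, report.tn))

    def test_auroc_invariant_under_monotone_transform(self, rng):
        truth = rng.integers(0, 2, 100)
        truth[0], truth[1] = 0, 1
        scores = rng.random(100)
        labels = ["High" if t else "Low" for t in truth]
        base = ev.classification_report(labels, scores).auroc
        warped = ev.classification_report(labels, scores ** 3).auroc
        assert warped == pytest.approx(base, abs=1e-12)

    def test_single_class_truth_auroc_missing(self):
        report = ev.classification_report(["High"] * 5,
                                          [0.9, 0.8, 0.7, 0.9, 1.0])
        assert report.auroc is None
        assert "both classes" in report.auroc_missing_reason

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import matthews_corrcoef, roc_auc_score
        truth = rng.integers(0, 2, 300)
        truth[:2] = [0, 1]
        scores = rng.random(300)
        labels = ["High" if t else "Low" for t in truth]
        report = ev.classification_report(labels, scores, threshold=0.5)
        assert report.auroc == pytest.approx(roc_auc_score(truth, scores))
        assert report.mcc == pytest.approx(
            matthews_corrcoef(truth, scores >= 0.5))


class TestErrorOverlap:
    def _report(self, truth, pred, ids):
        return ev.classification_report(truth, pred, ids=ids)

    def test_identical_and_disjoint_error_sets(self):
        ids = [f"p{i}" for i in range(6)]
        truth = [1.0, 1.0, 0.0, 0.0, 1.0, 0.0]
        pred_a = [0.0, 1.0, 1.0, 0.0, 1.0, 0.0]  # fn=p0, fp=p2
        same = ev.error_overlap(self._report(truth, pred_a, ids),
                                self._report(truth, pred_a, ids))
        assert same.shared_fp == frozenset({"p2"})
        assert same.shared_fn == frozenset({"p0"})
        assert not same.unique_fp_a and not same.unique_fn_b

        pred_b = [1.0, 0.0, 0.0, 1.0, 1.0, 0.0]  # fn=p1, fp=p3
        disjoint = ev.error_overlap(self._report(truth, pred_a, ids),
                                    self._report(truth, pred_b, ids))
        assert not disjoint.shared_fp and not disjoint.shared_fn
        assert disjoint.unique_fp_a == frozenset({"p2"})
        assert disjoint.unique_fp_b == frozenset({"p3"})

    def test_shared_bounded_by_min(self, rng):
        ids = [f"p{i}" for i in range(50)]
        truth = rng.random(50)
        a = self._report(truth, rng.random(50), ids)
        b = self._report(truth, rng.random(50), ids)
        overlap = ev.error_overlap(a, b)
        assert len(overlap.shared_fp) <= min(len(a.fp_ids), len(b.fp_ids))

    def test_id_mismatch_rejected(self):
        a = self._report([1.0, 0.0], [1.0, 0.0], ["x", "y"])
        b = self._report([1.0, 0.0], [1.0, 0.0], ["x", "z"])
        with pytest.raises(ValueError, match="different id sets"):
            ev.error_overlap(a, b)


class _ConstantPredictor:
    """Predicts the builtin-oracle yield recomputed per pair (perfect)."""

    def __init__(self, temperature=57.0):
        self.temperature = temperature

    def predict(self, pairs, batch_size=512):
        from dnahyb import thermo
        cond = thermo.ThermoConditions(temperature_celsius=self.temperature)
        return np.array([thermo.builtin_yield(a, b, cond).yield_fraction
                         for a, b in pairs])


class TestCrossTemperature:
    def test_report_per_temperature_and_identity_at_training_t(
            self, small_dataset):
        predictor = _ConstantPredictor()
        temps = [37.0, 57.0]
        reports = ev.cross_temperature_eval(predictor, small_dataset, temps)
        assert len(reports) == 2
        at_57 = reports[1]
        assert at_57.temperature == 57.0
        # the oracle predictor reproduces 57C truth exactly
        assert at_57.mse == pytest.approx(0.0, abs=1e-12)
        assert at_57.mcc == 1.0
        # distance from the evaluation temperature raises MSE
        assert reports[0].mse > at_57.mse

    def test_missing_temperature_rejected(self, small_dataset):
        with pytest.raises(KeyError):
            ev.cross_temperature_eval(_ConstantPredictor(), small_dataset,
                                      [99.0])

    def test_empty_temps_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            ev.cross_temperature_eval(_ConstantPredictor(), small_dataset, [])

    def test_report_table_tsv(self, small_dataset, tmp_path):
        reports = ev.cross_temperature_eval(_ConstantPredictor(),
                                            small_dataset, [37.0, 57.0])
        path = tmp_path / "table.tsv"
        ev.write_report_table(reports, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3
        assert lines[0].split("\t")[:6] == ["temperature", "threshold",
                                            "tp", "fp", "fn", "tn"]
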