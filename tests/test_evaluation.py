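"""Confusion counting, metric formulas, kappa, test-set protocol, transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from tilecover.dataset import SourceImage
from tilecover.errors import SamplingError
from tilecover.evaluation import (
    ConfusionCounts,
    build_test_set,
    confusion,
    evaluate_model,
    metrics,
    transferability,
)
from tilecover.tiling import ChopConfig

from conftest import MID_GREEN, PURE_YELLOW, uniform_image


class ColorOracleModel:
    """Stand-in classifier calling any warm-yellow tile positive."""

    def predict(self, tiles):
        tiles = np.asarray(tiles, dtype=np.float64)
        return (tiles[..., 0].mean(axis=(1, 2)) - tiles[..., 2].mean(axis=(1, 2)) > 60).astype(np.int8)


class TestConfusion:
    def test_all_correct_positive(self):
        counts = confusion([1] * 10, [1] * 10)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (10, 0, 0, 0)

    def test_complementary_calls(self):
        labels = [1] * 5 + [0] * 5
        calls = [0] * 5 + [1] * 5
        counts = confusion(calls, labels)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (0, 0, 5, 5)

    def test_random_case_matches_elementwise_tally(self, rng):
        calls = rng.integers(0, 2, 20)
        labels = rng.integers(0, 2, 20)
        counts = confusion(calls, labels)
        tally = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
        for c, l in zip(calls, labels):
            key = ("t" if c == l else "f") + ("p" if c else "n")
            tally[key] += 1
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (
            tally["tp"], tally["fn"], tally["fp"], tally["tn"])
        assert counts.total == 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_worked_confusion_table(self):
        report = metrics(ConfusionCounts(tp=40, fn=10, fp=5, tn=45))
        assert report.accuracy == pytest.approx(0.85)
        assert report.recall == pytest.approx(0.80)
        assert report.precision == pytest.approx(8 / 9)
        assert report.kappa == pytest.approx(0.70)

    def test_perfect_agreement(self):
        report = metrics(ConfusionCounts(tp=50, fn=0, fp=0, tn=50))
        assert report.accuracy == 1.0 and report.kappa == 1.0

    def test_chance_level_agreement(self):
        report = metrics(ConfusionCounts(tp=25, fn=25, fp=25, tn=25))
        assert report.accuracy == 0.5 and report.kappa == 0.0

    def test_undefined_denominators_flagged_not_nan(self):
        no_pos = metrics(ConfusionCounts(tp=0, fn=0, fp=3, tn=7))
        assert no_pos.recall is None  # no true positives in the sample
        no_calls = metrics(ConfusionCounts(tp=0, fn=5, fp=0, tn=5))
        assert no_calls.precision is None
        # chance agreement of 1 forces observed agreement of 1, so the
        # one-class/all-correct tables yield kappa = 1, never 0/0
        all_pos_correct = metrics(ConfusionCounts(tp=10, fn=0, fp=0, tn=0))
        assert all_pos_correct.kappa == 1.0
        all_neg_correct = metrics(ConfusionCounts(tp=0, fn=0, fp=0, tn=10))
        assert all_neg_correct.kappa == 1.0
        # disagreement keeps chance agreement below 1; kappa stays defined
        all_missed = metrics(ConfusionCounts(tp=0, fn=10, fp=0, tn=0))
        assert all_missed.kappa == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_sklearn_on_random_tables(self, rng):
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(0, 40, 4)
            if tp + fn + fp + tn == 0:
                continue
            labels = [1] * tp + [1] * fn + [0] * fp + [0] * tn
            calls = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            report = metrics(ConfusionCounts(tp, fn, fp, tn))
            expected = cohen_kappa_score(labels, calls)
            if report.kappa is None or np.isnan(expected):
                continue
            assert report.kappa == pytest.approx(expected, abs=1e-12)

    @given(tp=st.integers(0, 500), fn=st.integers(0, 500),
           fp=st.integers(0, 500), tn=st.integers(0, 500))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_kappa_bounds_and_perfection(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        report = metrics(ConfusionCounts(tp, fn, fp, tn))
        if report.kappa is not None:
            assert -1.0 - 1e-12 <= report.kappa <= 1.0 + 1e-12
        both_classes = (tp + fn) > 0 and (tn + fp) > 0
        if both_classes:
            assert (report.kappa == 1.0) == (fp == 0 and fn == 0)


class TestBuildTestSet:
    def _images(self, n_pos=2, n_neg=2, hw=120):
        pos = [SourceImage(uniform_image(hw, hw, (230, 210, 40)), f"p{i}") for i in range(n_pos)]
        neg = [SourceImage(uniform_image(hw, hw, MID_GREEN), f"n{i}") for i in range(n_neg)]
        return pos, neg

    def test_default_balance_is_half_positive(self):
        pos, neg = self._images()
        test = build_test_set(pos, neg, ChopConfig(), n_tiles=80, seed=0)
        assert len(test) == 80
        assert int(test.labels.sum()) == 40

    def test_minimal_balanced_pair(self):
        pos, neg = self._images(1, 1, hw=30)
        test = build_test_set(pos, neg, ChopConfig(), n_tiles=2, seed=0)
        assert sorted(test.labels.tolist()) == [0, 1]

    def test_seed_determinism(self):
        pos, neg = self._images()
        a = build_test_set(pos, neg, ChopConfig(), n_tiles=40, seed=7)
        b = build_test_set(pos, neg, ChopConfig(), n_tiles=40, seed=7)
        np.testing.assert_array_equal(a.tiles, b.tiles)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_shortfall_reported(self):
        pos, neg = self._images(1, 1, hw=30)
        with pytest.raises(SamplingError, match="positive"):
            build_test_set(pos, neg, ChopConfig(), n_tiles=10, seed=0)

    def test_count_conservation_through_confusion(self):
        pos, neg = self._images()
        test = build_test_set(pos, neg, ChopConfig(), n_tiles=60, seed=1)
        counts = confusion(ColorOracleModel().predict(test.tiles), test.labels)
        assert counts.tp + counts.fn == int(test.labels.sum())
        assert counts.total == 60


class TestTransferability:
    def test_single_cell_equals_direct_evaluation(self):
        pos = [SourceImage(uniform_image(90, 90, (230, 210, 40)), "p")]
        neg = [SourceImage(uniform_image(90, 90, MID_GREEN), "n")]
        test = build_test_set(pos, neg, ChopConfig(), n_tiles=30, seed=0)
        model = ColorOracleModel()
        matrix = transferability({"m": model}, {"t": test})
        direct = evaluate_model(model, test)
        assert matrix.cells[("m", "t")] == direct

    def test_perfect_model_gives_all_kappa_one(self):
        model = ColorOracleModel()
        tests = {}
        for name, seed in (("a", 1), ("b", 2)):
            pos = [SourceImage(uniform_image(90, 90, (230, 210, 40)), f"p{name}")]
            neg = [SourceImage(uniform_image(90, 90, MID_GREEN), f"n{name}")]
            tests[name] = build_test_set(pos, neg, ChopConfig(), n_tiles=30, seed=seed)
        matrix = transferability({"m1": model, "m2": model}, tests)
        frame = matrix.kappa_frame()
        assert (frame[["a", "b"]] == 1.0).all().all()
        assert (frame["Average"] == 1.0).all()
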