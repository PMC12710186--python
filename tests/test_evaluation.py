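"""Metric formulas, AUC oracles, PT-PBO, threshold sweeps and
envelope-by-outcome averaging."""

import math

import numpy as np
import pytest

import betaburst as bb
from betaburst.evaluation import OutcomeTimeline, make_timeline
from betaburst.preprocess import BurstAnnotation, EnvelopeSeries
from betaburst.windowing import LabeledSegmentSet


def _timeline(scores, labels, threshold=0.5, end_times=None, source=None):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    return OutcomeTimeline(
        scores=scores,
        decisions=scores >= threshold,
        labels=labels,
        end_times=np.arange(n, dtype=float) if end_times is None
        else np.asarray(end_times, dtype=float),
        source_burst=np.full(n, -1) if source is None else np.asarray(source),
        threshold=threshold,
    )


class TestComputeMetrics:
    def test_formula_arithmetic(self):
        # TP=3 TN=5 FP=1 FN=1
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.1, 0.2, 0.3, 0.1, 0.2, 0.1, 0.9]
        m = bb.compute_metrics(_timeline(scores, labels), test_duration=60.0)
        assert (m.TP, m.TN, m.FP, m.FN) == (3, 5, 1, 1)
        assert m.ACC == pytest.approx(0.8)
        assert m.PRC == pytest.approx(0.75)
        assert m.SEN == pytest.approx(0.75)
        assert m.SPC == pytest.approx(5 / 6)

    def test_fp_rate_per_minute(self):
        labels = [0] * 6 + [1]
        scores = [0.9] * 6 + [0.9]
        m = bb.compute_metrics(_timeline(scores, labels), test_duration=120.0)
        assert m.FP == 6
        assert m.FP_per_min == pytest.approx(3.0)

    def test_zero_denominators_flagged_not_zeroed(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.2, 0.3, 0.4]  # threshold .5: nothing positive
        m = bb.compute_metrics(_timeline(scores, labels), test_duration=60.0)
        assert math.isnan(m.PRC)
        assert "PRC" in m.flags

    def test_random_timelines_match_naive_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            scores = rng.random(n)
            thr = rng.random()
            tl = _timeline(scores, labels, threshold=thr)
            dur = float(rng.uniform(10, 600))
            m = bb.compute_metrics(tl, dur)
            tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 1)
            fp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 0)
            fn = sum(1 for s, y in zip(scores, labels) if s < thr and y == 1)
            tn = sum(1 for s, y in zip(scores, labels) if s < thr and y == 0)
            assert (m.TP, m.FP, m.FN, m.TN) == (tp, fp, fn, tn)
            assert m.ACC == pytest.approx((tp + tn) / n)
            assert m.FP_per_min == pytest.approx(fp / (dur / 60))

    def test_empty_timeline_errors(self):
        with pytest.raises(ValueError):
            bb.compute_metrics(_timeline([], []), 60.0)


def _auc_roc_oracle(scores, labels):
    """Pairwise concordance with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _auc_pr_oracle(scores, labels):
    """Interpolation-free step summation over the descending sweep."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    n1 = y.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n1
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestAUC:
    def test_worked_example(self):
        assert bb.compute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) \
            == pytest.approx(0.75)

    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        assert bb.compute_auc(scores, labels, "roc") == 1.0
        assert bb.compute_auc(scores, labels, "pr") == 1.0

    def test_matches_concordance_oracle_exhaustively(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            assert bb.compute_auc(scores, labels, "roc") == pytest.approx(
                _auc_roc_oracle(scores, labels)
            )

    def test_pr_matches_step_sum_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 100))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = rng.random(n)
            assert bb.compute_auc(scores, labels, "pr") == pytest.approx(
                _auc_pr_oracle(scores, labels)
            )

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(14)
        scores = rng.random(30)
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        aucs = [
            bb.compute_auc(scores, rng.permutation(labels), "roc")
            for _ in range(1000)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            bb.compute_auc([0.1, 0.9], [1, 1])


class TestPTPBO:
    def _bursts(self, onset_times):
        on = (np.asarray(onset_times) * 600).astype(int)
        return BurstAnnotation(on, on + 120, np.full(len(on), 0.2),
                               0.0, 1.0, 75.0, 600.0)

    def test_mean_interval_arithmetic(self):
        # earliest positive windows end at 9.950 and 19.910 s for bursts
        # at 10.0 and 20.0 s -> PT-PBO = 70 ms
        tl = _timeline(
            scores=[0.9, 0.9, 0.2, 0.9],
            labels=[1, 1, 1, 1],
            end_times=[9.950, 9.970, 19.880, 19.910],
            source=[0, 0, 1, 1],
        )
        assert bb.prediction_time_pbo(tl, self._bursts([10.0, 20.0])) \
            == pytest.approx(70.0)

    def test_all_negative_flagged_nan(self):
        tl = _timeline([0.1, 0.1], [1, 1], end_times=[9.9, 19.9],
                       source=[0, 1])
        assert math.isnan(bb.prediction_time_pbo(tl, self._bursts([10.0, 20.0])))

    def test_unpredicted_bursts_do_not_contribute(self):
        tl = _timeline(
            scores=[0.9, 0.1],
            labels=[1, 1],
            end_times=[9.950, 19.880],
            source=[0, 1],
        )
        assert bb.prediction_time_pbo(tl, self._bursts([10.0, 20.0])) \
            == pytest.approx(50.0)


class TestThresholdSweep:
    def test_extreme_thresholds(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        curve = bb.threshold_sweep(scores, labels, duration_min=2.0)
        top = curve[curve.threshold == 0.8].iloc[0]
        assert top.SEN == 0.5 and top.FP_per_min == 0.0
        bottom = curve[curve.threshold == 0.2].iloc[0]
        assert bottom.SEN == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        scores = np.round(rng.random(8), 1)
        labels = rng.integers(0, 2, size=8)
        labels[0], labels[1] = 0, 1
        curve = bb.threshold_sweep(scores, labels, duration_min=1.0)
        for t in np.unique(scores):
            row = curve[curve.threshold == t].iloc[0]
            d = scores >= t
            assert row.SEN == pytest.approx(
                np.sum(d & (labels == 1)) / labels.sum()
            )
            assert row.FP_per_min == pytest.approx(np.sum(d & (labels == 0)))

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(22)
        scores = rng.random(300)
        labels = rng.integers(0, 2, size=300)
        curve = bb.threshold_sweep(scores, labels, duration_min=5.0)
        assert np.all(np.diff(curve.SEN.values) <= 1e-12)
        assert np.all(np.diff(curve.FP_per_min.values) <= 1e-12)


class TestMeanEnvelopeByOutcome:
    def test_identical_tp_segments_give_zero_sem(self):
        fs = 600.0
        L = 120
        env_vals = np.tile(np.linspace(1, 2, 300), 10)
        env = EnvelopeSeries(env_vals, env_vals, fs)
        onsets = np.array([600, 1500, 2400])
        bursts = BurstAnnotation(onsets, onsets + 150,
                                 np.full(3, 0.25), 0.0, 1.0, 75.0, fs)
        ends = onsets - 18  # all at -30 ms
        segset = LabeledSegmentSet(
            segments=np.zeros((3, L)),
            labels=np.ones(3, dtype=np.int8),
            end_offsets_ms=np.full(3, -30.0),
            end_samples=ends,
            source_burst=np.arange(3),
            sampling_rate=fs,
        )
        tl = make_timeline(segset, np.array([0.9, 0.9, 0.9]), 0.5)
        groups = bb.mean_envelope_by_outcome(segset, tl, env, bursts)
        assert set(groups) == {"TP"}
        tp = groups["TP"]
        assert tp.n == 3
        # envelope slices repeat every 300 samples -> identical traces
        np.testing.assert_allclose(tp.sem, 0.0, atol=1e-12)
        np.testing.assert_allclose(tp.mean, env_vals[ends[0] - L : ends[0]])
        assert tp.time_ms[-1] == pytest.approx(-1000 / fs * 19, rel=0.1)

    def test_groups_split_by_decision_of_latest_window(self):
        fs = 600.0
        env_vals = np.ones(3000)
        env = EnvelopeSeries(env_vals, env_vals, fs)
        onsets = np.array([900, 1800, 2700])
        bursts = BurstAnnotation(onsets, onsets + 100,
                                 np.full(3, 1 / 6), 0.0, 1.0, 75.0, fs)
        ends = onsets - 18
        segset = LabeledSegmentSet(
            segments=np.zeros((3, 120)),
            labels=np.ones(3, dtype=np.int8),
            end_offsets_ms=np.full(3, -30.0),
            end_samples=ends,
            source_burst=np.arange(3),
            sampling_rate=fs,
        )
        tl = make_timeline(segset, np.array([0.9, 0.2, 0.9]), 0.5)
        groups = bb.mean_envelope_by_outcome(segset, tl, env, bursts)
        assert groups["TP"].n == 2
        assert groups["FN"].n == 1
        assert "FP" not in groups
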