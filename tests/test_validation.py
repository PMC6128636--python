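import numpy as np
import pytest

from spikelink import (ConfusionCounts, confusion, degree_distributions,
                       delay_length_distributions, matthews, mcc_curve,
                       roc_auc)
from spikelink.validation import _box_summary, accuracy, class_scores


def matrix_from_links(n, links):
    m = np.zeros((n, n))
    for i, j, v in links:
        m[i, j] = v
    return m


class TestConfusion:
    def test_perfect_prediction(self):
        truth = matrix_from_links(4, [(0, 1, 0.5), (2, 0, -0.3)])
        c = confusion(truth, truth, "all")
        assert c.fp == 0 and c.fn == 0
        assert c.total == 12

    def test_empty_prediction_counts_all_misses(self):
        truth = matrix_from_links(4, [(0, 1, 1.0), (2, 3, -1.0)])
        pred = np.zeros((4, 4))
        c = confusion(pred, truth, "all")
        assert c.tp == 0 and c.fp == 0
        assert c.fn == 2

    def test_wrong_polarity_counts_against_both_classes(self):
        # truth: 1->2 excitatory, 3->1 inhibitory
        # pred:  1->2 excitatory, 3->1 excitatory, 2->4 inhibitory
        truth = matrix_from_links(5, [(1, 2, 2.0), (3, 1, -1.5)])
        pred = matrix_from_links(5, [(1, 2, 0.8), (3, 1, 0.4), (2, 4, -0.6)])
        exc = confusion(pred, truth, "excitatory")
        assert (exc.tp, exc.fp, exc.fn) == (1, 1, 0)
        inh = confusion(pred, truth, "inhibitory")
        assert (inh.tp, inh.fp, inh.fn) == (0, 1, 1)

    def test_counts_partition_all_ordered_pairs(self, rng):
        for _ in range(10):
            truth = rng.normal(size=(8, 8)) * (rng.random((8, 8)) < 0.4)
            pred = rng.normal(size=(8, 8)) * (rng.random((8, 8)) < 0.4)
            np.fill_diagonal(truth, 0)
            np.fill_diagonal(pred, 0)
            for cls in ("excitatory", "inhibitory", "all"):
                assert confusion(pred, truth, cls).total == 56

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((3, 3)), np.zeros((4, 4)))


class TestAccuracyAndMcc:
    def test_worked_confusion_values(self):
        c = ConfusionCounts(tp=8, tn=85, fp=5, fn=2)
        assert matthews(c) == pytest.approx(670 / np.sqrt(13 * 10 * 90 * 87))
        assert accuracy(c) == pytest.approx(0.93)

    def test_degenerate_denominator_is_zero(self):
        assert matthews(ConfusionCounts(0, 100, 0, 5)) == 0.0


class TestRocAuc:
    def test_perfect_scorer_auc_one(self):
        truth = matrix_from_links(5, [(0, 1, 0.9), (1, 2, 0.3)])
        assert roc_auc(truth, truth, "excitatory").auc == pytest.approx(1.0)

    def test_hand_swept_auc(self):
        # 2 positives scored .9/.4, 2 negatives scored .6/.1 on a 2x2
        # off-diagonal universe: exhaustive sweep gives AUC = 0.75
        truth = np.array([[0, 1.0, 0, 0],
                          [0, 0, 1.0, 0],
                          [0, 0, 0, 0],
                          [0, 0, 0, 0.0]])
        scores = np.array([[0, 0.9, 0, 0.6],
                           [0, 0, 0.4, 0.1],
                           [0, 0, 0, 0],
                           [0, 0, 0, 0.0]])
        # remaining 8 off-diagonal pairs are score-0 true negatives; the
        # exhaustive pairwise count gives the same ranking answer
        curve = roc_auc(scores, truth, "excitatory")
        pos = [0.9, 0.4]
        neg = [0.6, 0.1] + [0.0] * 8
        greater = sum(p > q for p in pos for q in neg)
        ties = sum(p == q for p in pos for q in neg)
        expected = (greater + 0.5 * ties) / (len(pos) * len(neg))
        assert curve.auc == pytest.approx(expected)

    def test_curve_endpoints(self):
        truth = matrix_from_links(5, [(0, 1, 1.0)])
        curve = roc_auc(np.abs(np.random.default_rng(0).normal(size=(5, 5))),
                        truth, "excitatory")
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1

    def test_random_scores_near_half(self, rng):
        n = 200
        truth = (rng.random((n, n)) < 0.1).astype(float)
        np.fill_diagonal(truth, 0)
        scores = rng.random((n, n))
        np.fill_diagonal(scores, 0)
        auc = roc_auc(scores, truth, "excitatory").auc
        assert abs(auc - 0.5) < 0.05

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        n = 30
        truth = rng.normal(size=(n, n)) * (rng.random((n, n)) < 0.2)
        scores = np.abs(rng.normal(size=(n, n))) * (rng.random((n, n)) < 0.5)
        np.fill_diagonal(truth, 0)
        np.fill_diagonal(scores, 0)
        off = ~np.eye(n, dtype=bool)
        expected = roc_auc_score((truth > 0)[off].ravel(),
                                 class_scores(scores, "excitatory")[off].ravel())
        assert roc_auc(scores, truth, "excitatory").auc == pytest.approx(expected)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.zeros((3, 3)), np.zeros((3, 3)), "excitatory")


class TestMccCurve:
    def test_perfect_prediction_reaches_one(self):
        truth = matrix_from_links(5, [(0, 1, 0.9), (1, 2, 0.3)])
        assert mcc_curve(truth, truth, "excitatory").max_mcc == pytest.approx(1.0)

    def test_all_negative_prediction_yields_zero(self):
        truth = matrix_from_links(4, [(0, 1, 1.0)])
        scores = np.zeros((4, 4))
        curve = mcc_curve(scores, truth, "excitatory")
        assert curve.max_mcc == 0.0

    def test_mcc_bounded(self, rng):
        truth = rng.normal(size=(20, 20)) * (rng.random((20, 20)) < 0.3)
        scores = np.abs(rng.normal(size=(20, 20)))
        np.fill_diagonal(truth, 0)
        np.fill_diagonal(scores, 0)
        curve = mcc_curve(scores, truth, "all")
        assert np.all(curve.mcc >= -1) and np.all(curve.mcc <= 1)


class TestDegreeDistributions:
    def test_gaussian_parameter_recovery(self, rng):
        samples = rng.normal(80, 19.6, size=1000)
        fit = degree_distributions(None, samples=samples, fit=("gaussian",))
        se = 19.6 / np.sqrt(1000)
        assert abs(fit.gaussian["mean"] - 80) < 3 * se
        assert fit.gaussian["r2"] > 0.8

    def test_power_law_self_test(self, rng):
        samples = np.round(rng.pareto(1.5, size=2000) + 1)
        fit = degree_distributions(None, samples=samples, fit=("powerlaw",))
        assert fit.powerlaw["r2"] > 0.95

    def test_regular_graph_degenerate_flagged(self):
        tcm = np.zeros((6, 6))
        with pytest.raises(ValueError):
            degree_distributions(tcm, "all")

    def test_in_degree_counted_per_column(self):
        tcm = matrix_from_links(4, [(0, 1, 1.0), (2, 1, 1.0), (3, 2, 1.0)])
        fit = degree_distributions(tcm, "excitatory", fit=())
        assert sorted(fit.degrees.tolist()) == [0, 0, 1, 2]


class TestBoxSummaries:
    def test_degenerate_box(self):
        s = _box_summary(np.full(5, 3.0))
        assert s["median"] == s["q25"] == s["q75"] == 3.0

    def test_quartiles_linear_interpolation(self):
        s = _box_summary(np.arange(1.0, 10.0))
        assert s["median"] == 5.0
        assert s["q25"] == 3.0
        assert s["q75"] == 7.0

    def test_delay_length_table(self):
        from spikelink.connectivity import ConnectivityResults
        from spikelink import ElectrodeLayout
        fcm = matrix_from_links(3, [(0, 1, 0.5), (1, 2, -0.4)])
        delays = matrix_from_links(3, [(0, 1, 2.0), (1, 2, 3.0)])
        layout = ElectrodeLayout([f"c{i}" for i in range(3)],
                                 np.zeros(3, dtype=int), np.arange(3),
                                 np.arange(3) * 100.0, np.zeros(3), 100.0)
        res = ConnectivityResults(fcm=fcm, delays_ms=delays,
                                  channel_ids=["c0", "c1", "c2"], params={})
        table = delay_length_distributions(res, layout)
        exc_delay = table[(table["class"] == "excitatory")
                          & (table.quantity == "delay_ms")].iloc[0]
        assert exc_delay["median"] == 2.0
        exc_len = table[(table["class"] == "excitatory")
                        & (table.quantity == "length_um")].iloc[0]
        assert exc_len["median"] == 100.0


class TestInhibitoryFractionVsTime:
    def test_full_duration_matches_direct_pipeline(self, rng):
        from conftest import poisson_train
        from spikelink import (NcchConnectivity, PruningParams,
                               inhibitory_fraction_vs_time)
        from spikelink import SpikeTrainSet
        spikes = {f"c{i}": poisson_train(8.0, 30.0, rng) for i in range(5)}
        s = SpikeTrainSet(spikes, 10_000.0, 30.0)
        table = inhibitory_fraction_vs_time(s, [15.0, 30.0])
        direct = NcchConnectivity(s).fit().hard_threshold(PruningParams())
        assert table.iloc[-1]["inhibitory_fraction"] == pytest.approx(
            direct.inhibitory_fraction())

    def test_durations_validated(self, two_channel_set):
        from spikelink import inhibitory_fraction_vs_time
        with pytest.raises(ValueError):
            inhibitory_fraction_vs_time(two_channel_set, [1000.0])
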