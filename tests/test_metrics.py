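"""Confusion counting, metric formulas, aggregation, curves, baselines."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hypbench.assembly import ReplicaSet
from hypbench.metrics import (ConfusionCounts, aggregate, calls_by_key, confusion,
                              consensus, curves, metrics, random_baseline)

POS = tuple(("p", i) for i in range(1, 8))
NEG = tuple(("n", i) for i in range(1, 8))
REPLICA = ReplicaSet(index=0, positives=POS, negatives=NEG, seed=0)


def exact_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, Fraction | float]:
    """Independent exact-rational evaluation of the six standard formulas."""
    def ratio(num, den):
        return Fraction(num, den) if den else Fraction(0)
    sn, sp = ratio(tp, tp + fn), ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return {"Sn": sn, "Sp": sp, "WACC": (sn + sp) / 2, "F1": f1, "PREC": prec,
            "MCC": mcc}


class TestConfusion:
    def test_perfect_calls(self):
        calls = {k: 1 for k in POS} | {k: 0 for k in NEG}
        assert confusion(calls, REPLICA) == ConfusionCounts(TP=7, FP=0, TN=7, FN=0)

    def test_all_positive_predictor(self):
        calls = {k: 1 for k in POS + NEG}
        assert confusion(calls, REPLICA) == ConfusionCounts(TP=7, FP=7, TN=0, FN=0)

    def test_inverted_predictor(self):
        calls = {k: 0 for k in POS} | {k: 1 for k in NEG}
        assert confusion(calls, REPLICA) == ConfusionCounts(TP=0, FP=7, TN=0, FN=7)

    def test_sites_outside_replica_ignored(self):
        calls = {k: 1 for k in POS} | {k: 0 for k in NEG} | {("x", 1): 1}
        assert confusion(calls, REPLICA).total == 14

    def test_missing_prediction_policies(self):
        calls = {k: 1 for k in POS[1:]} | {k: 0 for k in NEG}
        with pytest.raises(KeyError):
            confusion(calls, REPLICA)
        c = confusion(calls, REPLICA, missing="negative")
        assert c.FN == 1 and c.TP == 6


class TestMetrics:
    def test_perfect_predictor(self):
        m = metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
        assert (m.MCC, m.WACC, m.F1) == (1.0, 1.0, 1.0)

    def test_coin_flip_on_balanced_data(self):
        m = metrics(ConfusionCounts(TP=25, FP=25, TN=25, FN=25))
        assert (m.MCC, m.WACC) == (0.0, 0.5)

    def test_frozen_table_against_exact_oracle(self):
        m = metrics(ConfusionCounts(TP=40, FP=10, TN=35, FN=15))
        oracle = exact_metrics(40, 10, 35, 15)
        for name, expected in oracle.items():
            assert getattr(m, name) == pytest.approx(float(expected), abs=1e-12)

    def test_zero_over_zero_convention(self):
        # no positive calls at all: PREC and MCC undefined -> 0
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert m.PREC == 0.0 and m.MCC == 0.0 and m.Sp == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


class TestAggregate:
    def test_identical_replicas_have_zero_stdev(self):
        sets = [metrics(ConfusionCounts(3, 1, 4, 1))] * 5
        agg = aggregate(sets)
        assert all(v["stdev"] == 0.0 for v in agg.values())

    def test_two_replica_closed_form(self):
        m0 = metrics(ConfusionCounts(TP=25, FP=25, TN=25, FN=25))  # MCC 0
        m1 = metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))    # MCC 1
        agg = aggregate([m0, m1])
        assert agg["MCC"]["mean"] == 0.5
        assert agg["MCC"]["stdev"] == pytest.approx(math.sqrt(0.5))

    def test_single_replica_rejected(self):
        with pytest.raises(ValueError):
            aggregate([metrics(ConfusionCounts(1, 1, 1, 1))])


class TestCurves:
    truth = {("s", i): int(i <= 10) for i in range(1, 21)}

    def test_scores_equal_to_labels_give_auc_one(self):
        scores = {k: float(v) for k, v in self.truth.items()}
        assert curves(scores, self.truth).auc == 1.0

    def test_reversed_scores_mirror_auc(self):
        rng = np.random.default_rng(1)
        scores = {k: rng.normal() + v for k, v in self.truth.items()}
        auc = curves(scores, self.truth).auc
        flipped = curves({k: -s for k, s in scores.items()}, self.truth).auc
        assert flipped == pytest.approx(1.0 - auc)

    def test_identical_scores_degenerate_with_warning(self):
        scores = {k: 0.5 for k in self.truth}
        with pytest.warns(UserWarning, match="identical"):
            result = curves(scores, self.truth)
        assert result.auc == 0.5

    def test_informative_scores_beat_label_permutations(self):
        rng = np.random.default_rng(2)
        truth = {("s", i): int(i <= 100) for i in range(1, 201)}
        scores = {k: rng.normal() + 1.5 * v for k, v in truth.items()}
        real_auc = curves(scores, truth).auc
        labels = np.array(list(truth.values()))
        perm_aucs = []
        for _ in range(100):
            perm = rng.permutation(labels)
            perm_truth = dict(zip(truth.keys(), (int(x) for x in perm)))
            perm_aucs.append(curves(scores, perm_truth).auc)
        assert real_auc > np.median(perm_aucs)

    def test_missing_scores_rejected(self):
        with pytest.raises(KeyError):
            curves({("s", 1): 0.5}, self.truth)


class TestRandomBaseline:
    def test_degenerate_probabilities(self):
        sites = [("s", i) for i in range(50)]
        assert all(r.call == 1 for r in random_baseline(sites, p=1.0, seed=0))
        assert all(r.call == 0 for r in random_baseline(sites, p=0.0, seed=0))

    def test_positive_fraction_near_half(self):
        sites = [("s", i) for i in range(10_000)]
        calls = [r.call for r in random_baseline(sites, p=0.5, seed=3)]
        assert abs(np.mean(calls) - 0.5) < 0.02  # binomial 99% interval ~ ±0.013

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            random_baseline([("s", 1)], p=1.5)


class TestConsensus:
    def test_majority_and_tie_rules(self):
        key = ("s", 1)
        assert consensus([{key: 1}, {key: 1}, {key: 0}])[0].call == 1
        assert consensus([{key: 1}, {key: 0}])[0].call == 0  # tie -> negative
        assert consensus([{key: 1}])[0].call == 1            # single method

    def test_coverage_gap_rejected(self):
        with pytest.raises(KeyError):
            consensus([{("s", 1): 1, ("s", 2): 1}, {("s", 1): 0}])


@given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                 st.integers(0, 500), st.integers(0, 500)))
def test_metrics_match_exact_oracle(counts):
    """Property: the implementation equals exact-rational formula evaluation."""
    tp, fp, tn, fn = counts
    if tp + fp + tn + fn == 0:
        return
    m = metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
    for name, expected in exact_metrics(tp, fp, tn, fn).items():
        assert getattr(m, name) == pytest.approx(float(expected), abs=1e-10)


def test_calls_by_key_rejects_duplicates():
    recs = random_baseline([("s", 1)], seed=0) * 2
    with pytest.raises(ValueError, match="multiple"):
        calls_by_key(recs)
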