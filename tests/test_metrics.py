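"""Majority voting and the diagnostic metric panel."""

import math

import numpy as np
import pytest

from margincnn import (
    ADENOMA,
    CARCINOMA,
    ConfusionCounts,
    compute_metrics,
    confusion,
    decide_nodule,
)
from margincnn.metrics import NoduleDecision, format_metric_table


def make_decision(case_id, label):
    return NoduleDecision(case_id, 10, 10 if label == CARCINOMA else 0,
                          0 if label == CARCINOMA else 10, label, False)


class TestDecideNodule:
    def test_majority_worked_example(self):
        votes = [CARCINOMA] * 255 + [ADENOMA] * 245
        d = decide_nodule(votes)
        assert d.final_label == CARCINOMA
        assert (d.votes_carcinoma, d.votes_adenoma) == (255, 245)
        assert not d.tie
        assert d.benign_percentage == pytest.approx(49.0)

    def test_unanimous_benign(self):
        d = decide_nodule([ADENOMA] * 10)
        assert d.final_label == ADENOMA
        assert d.benign_percentage == 100.0

    def test_tie_goes_to_configured_rule(self):
        votes = [CARCINOMA] * 250 + [ADENOMA] * 250
        d = decide_nodule(votes)
        assert d.final_label == CARCINOMA and d.tie
        d2 = decide_nodule(votes, tie_rule=ADENOMA)
        assert d2.final_label == ADENOMA and d2.tie

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        votes = [CARCINOMA] * 7 + [ADENOMA] * 5
        base = decide_nodule(votes)
        for _ in range(5):
            shuffled = list(rng.permutation(votes))
            d = decide_nodule(shuffled)
            assert (d.final_label, d.votes_carcinoma) == (base.final_label, base.votes_carcinoma)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            decide_nodule([])
        with pytest.raises(ValueError):
            decide_nodule([ADENOMA], tie_rule="benign")


class TestConfusion:
    def test_all_correct(self):
        decisions = [make_decision(f"c{i}", CARCINOMA) for i in range(3)]
        decisions += [make_decision(f"a{i}", ADENOMA) for i in range(5)]
        truth = {d.case_id: d.final_label for d in decisions}
        c = confusion(decisions, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 5, 0, 0)

    def test_flipped_predictions_swap_cells(self):
        truth = [CARCINOMA] * 4 + [ADENOMA] * 6
        right = [make_decision(str(i), t) for i, t in enumerate(truth)]
        flip = {CARCINOMA: ADENOMA, ADENOMA: CARCINOMA}
        wrong = [make_decision(str(i), flip[t]) for i, t in enumerate(truth)]
        cr, cw = confusion(right, truth), confusion(wrong, truth)
        assert (cr.tp, cr.fn) == (cw.fn, cw.tp)
        assert (cr.tn, cr.fp) == (cw.fp, cw.tn)

    def test_empty_is_all_zero(self):
        c = confusion([], [])
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 0, 0)

    def test_missing_truth_id(self):
        with pytest.raises(ValueError):
            confusion([make_decision("x", ADENOMA)], {"y": ADENOMA})


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=4, fp=0, tn=9, fn=0))
        for v in (r.sensitivity, r.specificity, r.ppv, r.npv, r.accuracy, r.g_mean):
            assert v == 1.0
        assert all(v == 1.0 for v in r.f_beta.values())
        assert r.false_omission_rate == 0.0

    def test_zero_denominators_are_undefined(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert r.sensitivity is None and r.ppv is None and r.g_mean is None
        assert r.specificity == 1.0
        txt = format_metric_table(ConfusionCounts(0, 0, 5, 0), r)
        assert "-" in txt  # undefined entries rendered as dashes

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_fbeta_ordering_when_precision_exceeds_recall(self):
        # ppv = 0.76 > sensitivity = 0.7308
        r = compute_metrics(ConfusionCounts(tp=19, fp=6, tn=17, fn=7))
        assert r.f_beta[0.5] > r.f_beta[1.0] > r.f_beta[2.0]
        for f in r.f_beta.values():
            assert min(r.ppv, r.sensitivity) <= f <= max(r.ppv, r.sensitivity)

    def test_gmean_is_precision_recall_geometric_mean(self):
        r = compute_metrics(ConfusionCounts(tp=19, fp=6, tn=17, fn=7))
        assert r.g_mean == pytest.approx(math.sqrt(r.ppv * r.sensitivity), abs=1e-15)


class TestOracleEquivalence:
    def test_panel_matches_sklearn_on_random_tables(self):
        """Independent cross-check against sklearn.metrics on 1,000 tables."""
        from sklearn.metrics import (
            accuracy_score,
            fbeta_score,
            precision_score,
            recall_score,
        )

        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fn == 0 or tn + fp == 0 or tp + fp == 0 or tn + fn == 0:
                continue
            r = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            assert abs(r.sensitivity - recall_score(y_true, y_pred)) < 1e-12
            assert abs(r.specificity - recall_score(y_true, y_pred, pos_label=0)) < 1e-12
            assert abs(r.ppv - precision_score(y_true, y_pred)) < 1e-12
            assert abs(r.npv - precision_score(y_true, y_pred, pos_label=0)) < 1e-12
            assert abs(r.accuracy - accuracy_score(y_true, y_pred)) < 1e-12
            if tp == 0:  # ppv = sensitivity = 0: F-beta is 0/0, kept undefined
                assert all(v is None for v in r.f_beta.values())
            else:
                for beta in (0.5, 1.0, 2.0):
                    assert abs(r.f_beta[beta] - fbeta_score(y_true, y_pred, beta=beta)) < 1e-12
            assert abs(r.g_mean - math.sqrt(r.ppv * r.sensitivity)) < 1e-12
            assert abs(r.false_omission_rate - fn / (fn + tn)) < 1e-12
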