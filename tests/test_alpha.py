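"""Alpha sweep, operating points and ROC assembly."""

import numpy as np
import pytest

from margincnn import (
    ADENOMA,
    CARCINOMA,
    AlphaGrid,
    assemble_roc,
    benign_curve,
    evaluate_at_alpha,
    generate_case,
    mean_curves,
    roc_from_alpha,
    sweep_cases,
    trapezoid_auc,
)


@pytest.fixture(scope="module")
def mini_cases(small_config):
    cases = []
    for i, label in enumerate([ADENOMA, ADENOMA, CARCINOMA, CARCINOMA]):
        c = generate_case(label, "A", small_config, seed=40 + i)
        c.case_id = f"m{i}"
        cases.append(c)
    return cases


class TestAlphaGrid:
    def test_defaults(self):
        assert len(AlphaGrid.sweep_default()) == 11
        assert AlphaGrid.sweep_default().values[0] == pytest.approx(-1.5)
        assert len(AlphaGrid.roc_default()) == 25

    def test_validation(self):
        with pytest.raises(ValueError):
            AlphaGrid((0.3, 0.2))
        with pytest.raises(ValueError):
            AlphaGrid((0.0, np.inf))


class TestBenignCurve:
    def test_always_benign_model_is_flat_100(self, mini_cases, stub_model_factory):
        model = stub_model_factory(bias=ADENOMA)
        curve = benign_curve(model, mini_cases[0])
        assert len(curve) == 11
        assert np.all(curve == 100.0)

    def test_threshold_model_monotone_votes(self, mini_cases, stub_model_factory):
        # alpha shifts every normalized pixel up, so mean-threshold carcinoma
        # votes can only grow: benign percentage is nonincreasing in alpha
        model = stub_model_factory(threshold=0.55)
        curve = benign_curve(model, mini_cases[0])
        assert np.all(np.diff(curve) <= 1e-9)


class TestMeanCurves:
    def test_single_case_group_equals_own_curve(self, mini_cases, stub_model_factory):
        model = stub_model_factory(threshold=0.55)
        grid = AlphaGrid((-0.5, 0.0, 0.5))
        sweep = sweep_cases(model, mini_cases[:1], grid)
        means = mean_curves(sweep)
        curve = benign_curve(model, mini_cases[0], grid)
        assert np.allclose(means["benign_percentage"].to_numpy(), curve)

    def test_mean_and_bounds(self, mini_cases, stub_model_factory):
        model = stub_model_factory(threshold=0.55)
        grid = AlphaGrid((0.0, 0.3))
        sweep = sweep_cases(model, mini_cases, grid)
        means = mean_curves(sweep)
        for (label, alpha), grp in sweep.table.groupby(["label", "alpha"]):
            m = means[(means["label"] == label) & (means["alpha"] == alpha)]
            v = m["benign_percentage"].iloc[0]
            assert v == pytest.approx(grp["benign_percentage"].mean())
            assert grp["benign_percentage"].min() - 1e-9 <= v <= grp["benign_percentage"].max() + 1e-9


class TestEvaluateAtAlpha:
    def test_perfect_model_perfect_accuracy(self, mini_cases, stub_model_factory):
        class Oracle(stub_model_factory):
            def __init__(self, truth):
                super().__init__()
                self.truth = truth
                self._i = 0

        # per-case dispatch: evaluate one case at a time with a biased stub
        for case in mini_cases:
            model = stub_model_factory(bias=case.label)
            _, counts, report = evaluate_at_alpha(model, [case], 0.0)
            assert report.accuracy == 1.0

    def test_cohort_alpha_map_matches_scalar(self, mini_cases, stub_model_factory):
        model = stub_model_factory(threshold=0.55)
        _, c1, r1 = evaluate_at_alpha(model, mini_cases, 0.15)
        _, c2, r2 = evaluate_at_alpha(model, mini_cases, {"A": 0.15})
        assert (c1.tp, c1.fp, c1.tn, c1.fn) == (c2.tp, c2.fp, c2.tn, c2.fn)
        assert r1.as_dict() == r2.as_dict()

    def test_unlabeled_case_rejected(self, mini_cases, stub_model_factory):
        bad = type(mini_cases[0])(
            "u", mini_cases[0].image, mini_cases[0].contour, "unknown", "A"
        )
        with pytest.raises(ValueError):
            evaluate_at_alpha(stub_model_factory(), [bad], 0.0)


class TestRoc:
    def test_hand_integrated_three_point_curve(self):
        curve = assemble_roc([(0.2, 0.6, -0.3), (0.5, 0.8, 0.0), (1.0, 1.0, 0.3)])
        # trapezoids: 0.2*0.3 + 0.3*0.7 + 0.5*0.9 = 0.72
        assert curve.auc == pytest.approx(0.72, abs=1e-12)
        assert curve.points.iloc[0].tolist()[:2] == [0.0, 0.0]
        assert curve.points.iloc[-1].tolist()[:2] == [1.0, 1.0]

    def test_trapezoid_matches_manual_sum(self):
        fpr = np.array([0.0, 0.25, 0.75, 1.0])
        tpr = np.array([0.0, 0.5, 0.9, 1.0])
        manual = sum(
            (fpr[i + 1] - fpr[i]) * (tpr[i + 1] + tpr[i]) / 2 for i in range(3)
        )
        assert trapezoid_auc(fpr, tpr) == pytest.approx(manual, abs=1e-15)

    def test_constant_decision_model_gives_diagonal(self, mini_cases, stub_model_factory):
        model = stub_model_factory(bias=CARCINOMA)
        curve = roc_from_alpha(model, mini_cases, AlphaGrid((-0.3, 0.0, 0.3)))
        assert curve.auc == pytest.approx(0.5)

    def test_single_class_rejected(self, mini_cases, stub_model_factory):
        with pytest.raises(ValueError):
            roc_from_alpha(stub_model_factory(), mini_cases[:2], AlphaGrid((0.0,)))

    def test_auc_stable_under_grid_refinement(self, mini_cases, stub_model_factory):
        model = stub_model_factory(threshold=0.55)
        coarse = roc_from_alpha(model, mini_cases, AlphaGrid(tuple(np.linspace(-0.6, 0.6, 5))))
        fine = roc_from_alpha(model, mini_cases, AlphaGrid(tuple(np.linspace(-0.6, 0.6, 9))))
        # refinement may add operating points but cannot move existing ones
        coarse_pts = set(map(tuple, coarse.points[["fpr", "tpr"]].to_numpy().tolist()))
        fine_pts = set(map(tuple, fine.points[["fpr", "tpr"]].to_numpy().tolist()))
        assert coarse_pts <= fine_pts
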