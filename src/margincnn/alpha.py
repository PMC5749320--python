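"""Alpha-sweep analysis: benign-percentage curves, operating points and ROC.

The test-time normalization carries a scaling parameter alpha; sweeping it
shifts every normalized pixel by ``alpha * mean / (max - min)`` and thereby
moves the patch classifier's votes, which makes alpha a one-dimensional
operating-point control. This module computes, for a trained patch
classifier and a set of labeled nodule cases:

* per-nodule benign-vote-percentage curves over an alpha grid,
* group mean curves (true-adenoma vs. carcinoma nodules),
* confusion table + metric panel at a chosen alpha (optionally a distinct
  alpha per cohort),
* an ROC curve whose operating points are generated by the alpha sweep,
  with trapezoidal AUC.

Margin patches are extracted and cached once per case and reused across the
whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .case import ADENOMA, CARCINOMA, NoduleCase
from .metrics import (
    ConfusionCounts,
    MetricReport,
    NoduleDecision,
    compute_metrics,
    confusion,
    decide_nodule,
)
from .normalization import normalize_batch
from .patches import extract_test_patches


@dataclass(frozen=True)
class AlphaGrid:
    """Strictly increasing, finite grid of alpha values."""

    values: tuple = tuple(np.round(np.arange(-1.5, 1.5 + 1e-9, 0.3), 10))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0 or not np.all(np.isfinite(v)):
            raise ValueError("alpha grid must be a finite 1-D sequence")
        if not np.all(np.diff(v) > 0):
            raise ValueError("alpha grid must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def sweep_default(cls) -> "AlphaGrid":
        """[-1.5, 1.5] in steps of 0.3 (mean-curve analysis)."""
        return cls()

    @classmethod
    def roc_default(cls, step: float = 0.05) -> "AlphaGrid":
        """[-0.6, 0.6] at the given step (ROC construction)."""
        return cls(tuple(np.round(np.arange(-0.6, 0.6 + 1e-9, step), 10)))


@dataclass
class SweepResult:
    """Tidy per-(case, alpha) benign percentages plus case metadata."""

    table: pd.DataFrame  # columns: case_id, cohort, label, alpha, benign_percentage
    grid: AlphaGrid

    def group_means(self) -> pd.DataFrame:
        return (
            self.table.groupby(["label", "alpha"])["benign_percentage"]
            .mean()
            .reset_index()
        )


@dataclass
class RocCurve:
    points: pd.DataFrame  # columns: fpr, tpr, alpha (alpha NaN for anchors)
    auc: float


class _PatchCache:
    """Extract each case's margin patches once; reuse across alphas."""

    def __init__(self, patch_size: int = 50):
        self.patch_size = patch_size
        self._store: dict[str, np.ndarray] = {}

    def raw(self, case: NoduleCase) -> np.ndarray:
        if case.case_id not in self._store:
            patches, _ = extract_test_patches(case, self.patch_size)
            arrs = [p.pixels for p in patches]
            self._store[case.case_id] = (
                np.stack(arrs) if arrs else np.empty((0, self.patch_size, self.patch_size))
            )
        return self._store[case.case_id]


def _case_decision(model, raw: np.ndarray, alpha: float, tie_rule: str, case_id: str) -> NoduleDecision:
    X, _dropped = normalize_batch(raw, mode="test", alpha=alpha)
    if len(X) == 0:
        raise ValueError(f"case {case_id!r}: no usable (non-degenerate) patches")
    labels = model.predict(X)
    d = decide_nodule(list(labels), tie_rule=tie_rule)
    d.case_id = case_id
    return d


def benign_curve(
    model, case: NoduleCase, grid: AlphaGrid | None = None, patch_size: int = 50,
    _cache: _PatchCache | None = None,
) -> np.ndarray:
    """Percentage of margin patches voted benign, at each grid alpha."""
    grid = grid or AlphaGrid.sweep_default()
    cache = _cache or _PatchCache(patch_size)
    raw = cache.raw(case)
    out = []
    for alpha in grid.values:
        d = _case_decision(model, raw, alpha, CARCINOMA, case.case_id)
        out.append(d.benign_percentage)
    return np.asarray(out)


def sweep_cases(
    model, cases, grid: AlphaGrid | None = None, patch_size: int = 50
) -> SweepResult:
    """Benign-percentage curves for every case over the grid."""
    grid = grid or AlphaGrid.sweep_default()
    cache = _PatchCache(patch_size)
    rows = []
    for case in cases:
        curve = benign_curve(model, case, grid, patch_size, _cache=cache)
        for alpha, pct in zip(grid.values, curve):
            rows.append(
                {
                    "case_id": case.case_id,
                    "cohort": case.cohort,
                    "label": case.label,
                    "alpha": alpha,
                    "benign_percentage": pct,
                }
            )
    return SweepResult(pd.DataFrame(rows), grid)


def mean_curves(sweep: SweepResult) -> pd.DataFrame:
    """Arithmetic mean of per-nodule benign percentages per (label, alpha)."""
    if sweep.table.empty:
        raise ValueError("empty sweep result")
    return sweep.group_means()


def evaluate_at_alpha(
    model,
    cases,
    alpha,
    tie_rule: str = CARCINOMA,
    patch_size: int = 50,
    _cache: _PatchCache | None = None,
) -> tuple[list[NoduleDecision], ConfusionCounts, MetricReport]:
    """Nodule decisions, confusion table and metric panel at a given alpha.

    ``alpha`` may be a scalar or a ``cohort tag -> alpha`` mapping (distinct
    normalization per acquiring clinic).
    """
    cases = list(cases)
    for case in cases:
        if case.label not in (ADENOMA, CARCINOMA):
            raise ValueError(f"case {case.case_id!r} is unlabeled")
    cache = _cache or _PatchCache(patch_size)
    decisions = []
    for case in cases:
        a = alpha[case.cohort] if isinstance(alpha, dict) else float(alpha)
        decisions.append(_case_decision(model, cache.raw(case), a, tie_rule, case.case_id))
    counts = confusion(decisions, {c.case_id: c.label for c in cases})
    return decisions, counts, compute_metrics(counts)


def best_alpha_by_accuracy(model, cases, grid: AlphaGrid, patch_size: int = 50):
    """Exhaustive scan: the grid alpha maximizing overall nodule accuracy."""
    cache = _PatchCache(patch_size)
    best = None
    for alpha in grid.values:
        _, counts, report = evaluate_at_alpha(
            model, cases, alpha, patch_size=patch_size, _cache=cache
        )
        if best is None or report.accuracy > best[1]:
            best = (alpha, report.accuracy)
    return best


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area under a curve sorted by FPR."""
    return float(np.trapezoid(tpr, fpr))


def assemble_roc(points) -> RocCurve:
    """Assemble operating points into an anchored, sorted ROC with its AUC.

    ``points`` is a sequence of ``(fpr, tpr, alpha)`` triples. Duplicate
    (fpr, tpr) pairs are collapsed, the anchors (0, 0) and (1, 1) added,
    points sorted by FPR (ties by TPR), and the AUC integrated by the
    trapezoidal rule.
    """
    df = pd.DataFrame(points, columns=["fpr", "tpr", "alpha"])
    df = df.drop_duplicates(subset=["fpr", "tpr"])
    anchors = pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0], "alpha": [np.nan, np.nan]})
    df = pd.concat([df, anchors], ignore_index=True)
    df = df.drop_duplicates(subset=["fpr", "tpr"]).sort_values(
        ["fpr", "tpr"], kind="mergesort", ignore_index=True
    )
    auc = trapezoid_auc(df["fpr"].to_numpy(), df["tpr"].to_numpy())
    return RocCurve(df, auc)


def roc_from_alpha(
    model, cases, grid: AlphaGrid | None = None, tie_rule: str = CARCINOMA,
    patch_size: int = 50,
) -> RocCurve:
    """ROC whose operating points come from nodule decisions across the grid."""
    cases = list(cases)
    labels = {c.label for c in cases}
    if labels != {ADENOMA, CARCINOMA}:
        raise ValueError("ROC needs both classes present in the case set")
    grid = grid or AlphaGrid.roc_default()
    cache = _PatchCache(patch_size)
    pts = []
    for alpha in grid.values:
        _, counts, _ = evaluate_at_alpha(
            model, cases, alpha, tie_rule=tie_rule, patch_size=patch_size, _cache=cache
        )
        fpr = counts.fp / (counts.fp + counts.tn)
        tpr = counts.tp / (counts.tp + counts.fn)
        pts.append((fpr, tpr, alpha))
    return assemble_roc(pts)


def plot_mean_curves(sweep: SweepResult, ax=None):
    """Mean benign-percentage curves per true class (optional figure)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, sub in mean_curves(sweep).groupby("label"):
        ax.plot(sub["alpha"], sub["benign_percentage"], marker="o", label=label)
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel("mean benign percentage (%)")
    ax.legend()
    return ax


def plot_roc(curve: RocCurve, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.points["fpr"], curve.points["tpr"], marker="o")
    ax.plot([0, 1], [0, 1], ls="--", color="gray")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {curve.auc:.4f}")
    return ax
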