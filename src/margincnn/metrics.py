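"""Nodule-level majority voting and the diagnostic metric panel.

The positive class is carcinoma throughout; adenoma is the benign/negative
class. A nodule's label is the class receiving more per-patch hard votes;
an exact tie goes to the configurable ``tie_rule`` (default carcinoma — the
clinically conservative call) and is flagged.

The panel reports sensitivity (TPR), specificity (TNR), PPV, NPV, false
omission rate FN/(FN+TN), accuracy, the F-beta family for beta in
{0.5, 1, 2}, and the G-mean. G-mean here is the geometric mean of precision
and recall, sqrt(PPV * TPR) — the Fowlkes–Mallows index — not the also-common
sqrt(TPR * TNR). Metrics with a zero denominator are reported as undefined
(``None``), never coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .case import ADENOMA, CARCINOMA

F_BETAS = (0.5, 1.0, 2.0)


@dataclass
class NoduleDecision:
    """Majority-vote outcome for one nodule."""

    case_id: str
    n_patches: int
    votes_carcinoma: int
    votes_adenoma: int
    final_label: str
    tie: bool

    @property
    def benign_percentage(self) -> float:
        return 100.0 * self.votes_adenoma / self.n_patches


@dataclass
class ConfusionCounts:
    """2x2 confusion table with carcinoma as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Diagnostic panel; undefined entries (zero denominator) are ``None``."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    false_omission_rate: float | None
    accuracy: float | None
    f_beta: dict[float, float | None] = field(default_factory=dict)
    g_mean: float | None = None

    @property
    def accuracy_percent(self) -> float | None:
        return None if self.accuracy is None else 100.0 * self.accuracy

    def as_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "false_omission_rate": self.false_omission_rate,
            "accuracy": self.accuracy,
            "g_mean": self.g_mean,
        }
        for beta, v in self.f_beta.items():
            d[f"f{beta:g}"] = v
        return d


def decide_nodule(predictions, tie_rule: str = CARCINOMA) -> NoduleDecision:
    """Majority vote over per-patch hard labels.

    ``predictions`` is a sequence of :class:`~margincnn.classifier.PatchPrediction`
    (or anything with a ``hard_label`` attribute, or plain label strings).
    """
    if tie_rule not in (ADENOMA, CARCINOMA):
        raise ValueError(f"tie_rule must be adenoma or carcinoma, got {tie_rule!r}")
    labels = [getattr(p, "hard_label", p) for p in predictions]
    if not labels:
        raise ValueError("cannot decide a nodule from zero patch predictions")
    case_id = next(
        (p.case_id for p in predictions if hasattr(p, "case_id")), ""
    )
    unknown = [l for l in labels if l not in (ADENOMA, CARCINOMA)]
    if unknown:
        raise ValueError(f"unknown patch label {unknown[0]!r}")
    n_car = sum(l == CARCINOMA for l in labels)
    n_ade = len(labels) - n_car
    tie = n_car == n_ade
    if tie:
        final = tie_rule
    else:
        final = CARCINOMA if n_car > n_ade else ADENOMA
    return NoduleDecision(case_id, len(labels), n_car, n_ade, final, tie)


def confusion(decisions, truth) -> ConfusionCounts:
    """Count the 2x2 table from aligned decisions and true labels.

    ``truth`` may be a sequence of labels aligned with ``decisions`` or a
    mapping ``case_id -> label``.
    """
    decisions = list(decisions)
    if isinstance(truth, dict):
        labels = []
        for d in decisions:
            if d.case_id not in truth:
                raise ValueError(f"no true label for case {d.case_id!r}")
            labels.append(truth[d.case_id])
    else:
        labels = list(truth)
        if len(labels) != len(decisions):
            raise ValueError("decisions and truth have different lengths")
    tp = fp = tn = fn = 0
    for d, t in zip(decisions, labels):
        if t == CARCINOMA:
            if d.final_label == CARCINOMA:
                tp += 1
            else:
                fn += 1
        elif t == ADENOMA:
            if d.final_label == ADENOMA:
                tn += 1
            else:
                fp += 1
        else:
            raise ValueError(f"unknown true label {t!r}")
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Full diagnostic panel from a confusion table."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    fomr = _ratio(fn, fn + tn)
    acc = _ratio(tp + tn, counts.total)
    f_beta: dict[float, float | None] = {}
    for beta in F_BETAS:
        if ppv is None or sens is None or (beta**2 * ppv + sens) == 0:
            f_beta[beta] = None
        else:
            f_beta[beta] = (1 + beta**2) * ppv * sens / (beta**2 * ppv + sens)
    g_mean = None if (ppv is None or sens is None) else math.sqrt(ppv * sens)
    return MetricReport(sens, spec, ppv, npv, fomr, acc, f_beta, g_mean)


def decisions_frame(decisions, truth=None) -> pd.DataFrame:
    rows = []
    for d in decisions:
        rows.append(
            {
                "case_id": d.case_id,
                "n_patches": d.n_patches,
                "votes_carcinoma": d.votes_carcinoma,
                "votes_adenoma": d.votes_adenoma,
                "benign_percentage": d.benign_percentage,
                "final_label": d.final_label,
                "tie": d.tie,
            }
        )
    df = pd.DataFrame(rows)
    if truth is not None and len(df):
        if isinstance(truth, dict):
            df["true_label"] = [truth[c] for c in df["case_id"]]
        else:
            df["true_label"] = list(truth)
    return df


def _fmt(v: float | None, pct: bool = False, nd: int = 4) -> str:
    if v is None:
        return "-"
    return f"{100 * v:.2f}%" if pct else f"{v:.{nd}f}"


def format_metric_table(counts: ConfusionCounts, report: MetricReport, title: str = "") -> str:
    """Plain-text panel mirroring the familiar confusion-table layout."""
    lines = []
    if title:
        lines.append(title)
    lines += [
        f"                    Predicted_Adenoma   Predicted_Carcinoma",
        f"True_Adenoma        {counts.tn:<19d} {counts.fp:<19d}",
        f"True_Carcinoma      {counts.fn:<19d} {counts.tp:<19d}",
        f"True negative rate (specificity): {_fmt(report.specificity, pct=True)}",
        f"True positive rate (sensitivity): {_fmt(report.sensitivity, pct=True)}",
        f"False omission rate: {_fmt(report.false_omission_rate)}",
        f"Positive predictive value: {_fmt(report.ppv)}",
        f"Negative predictive value: {_fmt(report.npv)}",
        f"F0.5-score: {_fmt(report.f_beta.get(0.5))}",
        f"F1-score: {_fmt(report.f_beta.get(1.0))}",
        f"F2-score: {_fmt(report.f_beta.get(2.0))}",
        f"G-mean: {_fmt(report.g_mean)}",
        f"Overall accuracy: {_fmt(report.accuracy, pct=True)}",
    ]
    return "\n".join(lines)
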