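"""Fairness evaluation suite.

Disparity is the sample standard deviation of per-group accuracy —
smaller is fairer.  Two harmonic combination rules are deliberately
distinct: disparities at different levels are combined by the
reciprocal-sum inverse 1/(1/a + 1/b) (no factor 2), while worst-case
accuracies are combined by the ordinary harmonic mean 2/(1/a + 1/b).
Algorithmic-fairness quantities for a binary task with a binary
sensitive attribute: an equal-opportunity-style gap and the worst
within-group true-positive rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .data import TabularDataset, _attribute_codes
from .predictor import PredictorState, predict


def disparity(accuracies) -> float:
    """Sample standard deviation of per-group accuracies.

    sqrt( sum_i (Acc_i - mean)^2 / (|G| - 1) ): the dispersion of the
    model's accuracy across groups; 0 means perfectly uniform service.
    """
    a = np.asarray(accuracies, float)
    if a.size < 2:
        raise ValueError("disparity needs at least two groups")
    if np.ptp(a) == 0:  # exactly uniform service
        return 0.0
    return float(np.std(a, ddof=1))


def harmonic_disparity(a: float, b: float) -> float:
    """Reciprocal-sum inverse of two disparities: 1/(1/a + 1/b).

    Combines fairness at two levels into one number dominated by the
    *smaller* (better) disparity; note there is deliberately no factor 2.
    """
    if a <= 0 or b <= 0:
        raise ValueError("disparities must be positive to combine")
    return 1.0 / (1.0 / a + 1.0 / b)


def harmonic_accuracy(a: float, b: float) -> float:
    """Standard harmonic mean of two accuracies: 2/(1/a + 1/b)."""
    if a <= 0 or b <= 0:
        raise ValueError("accuracies must be positive to combine")
    return 2.0 / (1.0 / a + 1.0 / b)


def overall_accuracy(predictions, labels) -> float:
    """Sample-size-weighted accuracy: total correct / total rows."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.size == 0 or p.shape != y.shape:
        raise ValueError("predictions and labels must be non-empty and aligned")
    return float(np.mean(p == y))


def overall_accuracy_from_groups(accuracies, group_sizes) -> float:
    """The same quantity from per-group accuracies and group sizes."""
    a = np.asarray(accuracies, float)
    s = np.asarray(group_sizes, float)
    if a.shape != s.shape or s.sum() <= 0:
        raise ValueError("need aligned accuracies and positive sizes")
    return float(np.dot(a, s) / s.sum())


def relative_improvement(baseline: float, new: float) -> float:
    """Percent reduction relative to the baseline: 100*(baseline - new)/baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (baseline - new) / baseline


def eo_gap(
    predictions, labels, attribute, mode: str = "as_printed"
) -> float | None:
    """Equal-opportunity-style gap between two attribute groups.

    ``as_printed`` (default) conditions on the *prediction*:
    |P(Y=1 | Yhat=1, A=0) - P(Y=1 | Yhat=1, A=1)| — a predictive-parity
    style quantity.  ``standard`` conditions on the label:
    |TPR_0 - TPR_1|.  Returns None when a conditioning cell is empty
    (the gap is undefined, not zero).
    """
    p = np.asarray(predictions, int)
    y = np.asarray(labels, int)
    a = np.asarray(attribute, int)
    if set(np.unique(y)) - {0, 1} or set(np.unique(p)) - {0, 1}:
        raise ValueError("eo_gap needs binary labels and predictions")
    vals = []
    for g in (0, 1):
        if mode == "as_printed":
            cond = (p == 1) & (a == g)
            if not cond.any():
                return None
            vals.append(float(np.mean(y[cond] == 1)))
        elif mode == "standard":
            cond = (y == 1) & (a == g)
            if not cond.any():
                return None
            vals.append(float(np.mean(p[cond] == 1)))
        else:
            raise ValueError(f"unknown eo_gap mode {mode!r}")
    return abs(vals[0] - vals[1])


def worst_tpr(predictions, labels, attribute) -> float | None:
    """Minimum over attribute values of the within-group true-positive rate."""
    p = np.asarray(predictions, int)
    y = np.asarray(labels, int)
    a = np.asarray(attribute, int)
    rates = []
    for g in np.unique(a):
        cond = (y == 1) & (a == g)
        if not cond.any():
            return None
        rates.append(float(np.mean(p[cond] == 1)))
    return min(rates)


@dataclass
class MetricsReport:
    """One model's full fairness scorecard on one evaluation grouping."""

    client_accuracies: list[float]
    attribute_accuracies: list[float]
    disparity_client: float
    disparity_attribute: float
    harmonic_disparity: float | None
    worst_client_acc: float
    worst_attribute_acc: float
    harmonic_worst_acc: float
    overall_acc: float
    eo_gap: float | None = None
    eo_mode: str = "as_printed"
    worst_tpr: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            k: v for k, v in self.__dict__.items()
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def format_table(self) -> str:
        lines = [
            f"{'overall accuracy':30s} {self.overall_acc:8.4f}",
            f"{'disparity over clients':30s} {self.disparity_client:8.4f}",
            f"{'disparity over attributes':30s} {self.disparity_attribute:8.4f}",
        ]
        if self.harmonic_disparity is not None:
            lines.append(
                f"{'harmonic disparity':30s} {self.harmonic_disparity:8.4f}"
            )
        lines += [
            f"{'worst client accuracy':30s} {self.worst_client_acc:8.4f}",
            f"{'worst attribute accuracy':30s} {self.worst_attribute_acc:8.4f}",
            f"{'harmonic worst accuracy':30s} {self.harmonic_worst_acc:8.4f}",
        ]
        if self.eo_gap is not None:
            lines.append(f"{'EO gap (' + self.eo_mode + ')':30s} {self.eo_gap:8.4f}")
        if self.worst_tpr is not None:
            lines.append(f"{'worst TPR':30s} {self.worst_tpr:8.4f}")
        return "\n".join(lines)


def evaluate_suite(
    state: PredictorState,
    dataset: TabularDataset,
    rows_by_client: list[np.ndarray],
    attribute_columns: list[str],
    eo_mode: str = "as_printed",
    eo_attribute: str | None = None,
) -> MetricsReport:
    """Score a model on a client partition of evaluation rows.

    Per-client and per-attribute-group accuracies, both disparities and
    their reciprocal-sum combination, worst-case accuracies and their
    harmonic mean, and the pooled accuracy.  EO gap and worst TPR are
    filled in only for a binary task with a binary (first) attribute.
    """
    all_rows = np.sort(np.concatenate([np.asarray(r, int) for r in rows_by_client]))
    preds_all = predict(state, dataset.features[all_rows])
    pred_of_row = np.full(dataset.n_rows, -1, dtype=int)
    pred_of_row[all_rows] = preds_all

    client_acc = []
    for rows in rows_by_client:
        rows = np.asarray(rows, int)
        if len(rows) == 0:
            raise ValueError("a client has no evaluation rows")
        client_acc.append(float(np.mean(pred_of_row[rows] == dataset.labels[rows])))

    attr_codes, _ = _attribute_codes(dataset, list(attribute_columns))
    attr_eval = attr_codes[all_rows]
    attr_acc = []
    for g in np.unique(attr_eval):
        mask = attr_eval == g
        attr_acc.append(
            float(np.mean(preds_all[mask] == dataset.labels[all_rows][mask]))
        )

    disp_c = disparity(client_acc) if len(client_acc) >= 2 else math.nan
    disp_a = disparity(attr_acc) if len(attr_acc) >= 2 else math.nan
    harm = (
        harmonic_disparity(disp_c, disp_a)
        if disp_c > 0 and disp_a > 0
        else (0.0 if disp_c == 0 or disp_a == 0 else None)
    )
    worst_c = float(min(client_acc))
    worst_a = float(min(attr_acc))
    harm_acc = (
        harmonic_accuracy(worst_c, worst_a) if worst_c > 0 and worst_a > 0 else 0.0
    )
    overall = overall_accuracy(preds_all, dataset.labels[all_rows])

    gap, wtpr = None, None
    eo_col = eo_attribute or (attribute_columns[0] if attribute_columns else None)
    if dataset.n_classes == 2 and eo_col is not None:
        attr = dataset.attributes[eo_col][all_rows]
        if len(np.unique(attr)) == 2:
            gap = eo_gap(preds_all, dataset.labels[all_rows], attr, mode=eo_mode)
            wtpr = worst_tpr(preds_all, dataset.labels[all_rows], attr)

    return MetricsReport(
        client_accuracies=client_acc,
        attribute_accuracies=attr_acc,
        disparity_client=disp_c,
        disparity_attribute=disp_a,
        harmonic_disparity=harm,
        worst_client_acc=worst_c,
        worst_attribute_acc=worst_a,
        harmonic_worst_acc=harm_acc,
        overall_acc=overall,
        eo_gap=gap,
        eo_mode=eo_mode,
        worst_tpr=wtpr,
    )
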