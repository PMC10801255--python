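"""Frozen worked examples for the evaluation metrics.

Each entry applies one metric to fixed published benchmark inputs and
records the value reported alongside them, at its printed precision.
``verify_reference_arithmetic`` recomputes every entry through the
package's own metric functions — a fast end-to-end consistency check
that the implemented conventions (sample-SD disparity, the two distinct
harmonic rules, percent improvements) are the ones the reported numbers
actually follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metrics import (
    disparity,
    harmonic_accuracy,
    harmonic_disparity,
    relative_improvement,
)

_METRICS = {
    "disparity": lambda args: disparity(list(args)),
    "harmonic_disparity": lambda args: harmonic_disparity(*args),
    "harmonic_accuracy": lambda args: harmonic_accuracy(*args),
    "relative_improvement": lambda args: relative_improvement(*args),
}


@dataclass(frozen=True)
class WorkedExample:
    """One metric evaluation frozen at its printed precision."""

    key: str
    metric: str
    inputs: tuple[float, ...]
    expected: float
    decimals: int

    def compute(self) -> float:
        return _METRICS[self.metric](self.inputs)

    @property
    def tolerance(self) -> float:
        # half a unit in the last printed place (plus float fuzz)
        return 0.5 * 10.0 ** (-self.decimals) + 1e-12


WORKED_EXAMPLES: tuple[WorkedExample, ...] = (
    # two-client accuracy spread -> client disparity
    WorkedExample(
        "support_fedavg_client_disparity",
        "disparity", (0.6880, 0.5429), 0.1026, 4,
    ),
    # binary-outcome accuracy spread -> attribute disparity
    WorkedExample(
        "covid_fedavg_attribute_disparity",
        "disparity", (0.1733, 0.5411), 0.2601, 4,
    ),
    # client + attribute disparities -> multilevel (reciprocal-sum) figure
    WorkedExample(
        "support_fedavg_harmonic_disparity",
        "harmonic_disparity", (0.1026, 0.1078), 0.0526, 4,
    ),
    WorkedExample(
        "fetal_fedavg_harmonic_disparity",
        "harmonic_disparity", (0.0205, 0.0778), 0.0162, 4,
    ),
    WorkedExample(
        "covid_fedavg_harmonic_disparity",
        "harmonic_disparity", (0.0306, 0.2601), 0.0274, 4,
    ),
    WorkedExample(
        "prostate_fedavg_harmonic_disparity",
        "harmonic_disparity", (0.0240, 0.2420), 0.0218, 4,
    ),
    # worst-client + worst-attribute accuracy -> harmonic mean (percent scale)
    WorkedExample(
        "fetal_fedavg_harmonic_worst_acc",
        "harmonic_accuracy", (95.32, 75.00), 83.95, 2,
    ),
    WorkedExample(
        "support_fedavg_harmonic_worst_acc",
        "harmonic_accuracy", (54.29, 60.19), 57.09, 2,
    ),
    WorkedExample(
        "prostate_fedavg_harmonic_worst_acc",
        "harmonic_accuracy", (79.11, 17.71), 28.94, 2,
    ),
    # disparity reductions quoted as percent improvements
    WorkedExample(
        "covid_client_fairness_improvement_pct",
        "relative_improvement", (0.0109, 0.0010), 90.83, 2,
    ),
    WorkedExample(
        "fetal_client_fairness_improvement_pct",
        "relative_improvement", (0.0324, 0.0081), 75.00, 2,
    ),
)


def verify_reference_arithmetic() -> pd.DataFrame:
    """Recompute every worked example; columns: key, computed, expected, passed."""
    rows = []
    for ex in WORKED_EXAMPLES:
        value = ex.compute()
        rows.append(
            {
                "key": ex.key,
                "metric": ex.metric,
                "computed": value,
                "expected": ex.expected,
                "tolerance": ex.tolerance,
                "passed": abs(value - ex.expected) <= ex.tolerance,
            }
        )
    return pd.DataFrame(rows)
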