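"""Group-risk bookkeeping and the fairness objectives.

Three ways of scoring a model against a grouping of the data:

* the variance-penalized fairness risk  R_fair = R_bar + C * Var(group risks)/|G|,
* the weighted risk  F(theta, lambda) = sum_i lambda_i f_i,
* the distributionally robust risk  R_dro = max of F over group-weight
  vectors lambda in a chi-square ball of radius rho around uniform.

The chi-square generator f(t) = (t-1)^2 gives
D_f(|G| lambda || 1) = (1/|G|) sum_i (|G| lambda_i - 1)^2 = |G| * ||lambda - u||^2,
so the uncertainty set is the Euclidean ball of radius sqrt(rho/|G|)
around the uniform vector u, intersected with the simplex — which makes
the inner maximization a linear program over a spherical cap, solvable
by bisection on the ball's dual variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .predictor import PredictorState, cross_entropy

WEIGHT_FLOOR = 1e-12


@dataclass(frozen=True)
class UncertaintySetSpec:
    """Fairness level plus the geometry of the uncertainty set.

    ``rho`` is the chi-square ball radius (0 = plain ERM, large = worst
    group); ``beta`` mixes client- vs attribute-level weight usage at the
    multilevel setting and is ignored otherwise.
    """

    level: str
    rho: float
    beta: float = 0.5
    divergence: str = "chi2"

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        if self.divergence != "chi2":
            raise ValueError("only the chi2 f-divergence ball is supported")


@dataclass
class GroupRiskVector:
    """Per-group empirical risks with the sample counts behind them."""

    risks: np.ndarray
    counts: np.ndarray
    level: str = ""

    def __post_init__(self) -> None:
        self.risks = np.asarray(self.risks, float)
        self.counts = np.asarray(self.counts, int)
        if self.risks.shape != self.counts.shape:
            raise ValueError("risks and counts must align")
        if not np.isfinite(self.risks).all() or (self.risks < 0).any():
            raise ValueError("group risks must be finite and non-negative")
        if (self.counts < 1).any():
            raise ValueError("every group needs at least one sample")

    def __len__(self) -> int:
        return len(self.risks)


@dataclass
class GroupWeights:
    """Simplex weight vector(s) constrained to the chi-square ball.

    ``lambda_client`` always present; ``lambda_attribute`` only at the
    multilevel setting.  Entries are floored at a tiny epsilon so the
    multiplicative update can never extinguish a group permanently.
    """

    lambda_client: np.ndarray
    lambda_attribute: np.ndarray | None = None
    rho: float = 0.0
    level: str = "client"

    def __post_init__(self) -> None:
        self.lambda_client = np.asarray(self.lambda_client, float)
        if self.lambda_attribute is not None:
            self.lambda_attribute = np.asarray(self.lambda_attribute, float)

    def validate(self, tol: float = 1e-7) -> None:
        for vec in filter(lambda v: v is not None,
                          (self.lambda_client, self.lambda_attribute)):
            if abs(vec.sum() - 1.0) > 1e-9 or (vec < 0).any():
                raise ValueError("weights must lie on the simplex")
            if chi2_divergence(vec) > self.rho + tol:
                raise ValueError("weights violate the uncertainty-set radius")

    @staticmethod
    def uniform(n_client: int, n_attribute: int | None = None,
                rho: float = 0.0, level: str = "client") -> "GroupWeights":
        return GroupWeights(
            lambda_client=np.full(n_client, 1.0 / n_client),
            lambda_attribute=(
                None if n_attribute is None else np.full(n_attribute, 1.0 / n_attribute)
            ),
            rho=rho,
            level=level,
        )


def chi2_divergence(weights: np.ndarray) -> float:
    """D_f(|G| * lambda || 1) with f(t) = (t-1)^2."""
    w = np.asarray(weights, float)
    G = len(w)
    return float(np.sum((G * w - 1.0) ** 2) / G)


def ball_radius_euclidean(n_groups: int, rho: float) -> float:
    """Euclidean radius around uniform equivalent to the chi2 radius rho."""
    return float(np.sqrt(rho / n_groups))


def group_risks(
    state: PredictorState,
    features: np.ndarray,
    labels: np.ndarray,
    group_of_row: np.ndarray,
    n_groups: int,
    level: str = "",
) -> GroupRiskVector:
    """Mean cross-entropy of the model within each group of the given rows."""
    group_of_row = np.asarray(group_of_row, int)
    counts = np.bincount(group_of_row, minlength=n_groups)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"group(s) {empty} have no rows in the evaluated subset")
    ce = cross_entropy(state, features, labels)
    sums = np.bincount(group_of_row, weights=ce, minlength=n_groups)
    return GroupRiskVector(risks=sums / counts, counts=counts, level=level)


def weighted_risk(risks: GroupRiskVector | np.ndarray, weights: np.ndarray) -> float:
    """F(theta, lambda) = sum_i lambda_i f_i."""
    f = risks.risks if isinstance(risks, GroupRiskVector) else np.asarray(risks, float)
    w = np.asarray(weights, float)
    if f.shape != w.shape:
        raise ValueError("risks and weights must have equal length")
    return float(f @ w)


def variance_penalized_risk(risks: GroupRiskVector, C: float) -> float:
    """R_fair = count-weighted overall mean + C * Var(group risks) / |G|.

    The variance is the population variance over the group risks; the
    overall term weights groups by their sample counts so it equals the
    pooled empirical risk.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    G = len(risks)
    if C > 0 and G < 2:
        raise ValueError("variance penalty needs at least two groups")
    overall = float(np.dot(risks.counts, risks.risks) / risks.counts.sum())
    if C == 0:
        return overall
    var = float(np.var(risks.risks))
    return overall + C * var / G


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of v onto the probability simplex (sort-based)."""
    v = np.asarray(v, float)
    n = len(v)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ind = np.arange(1, n + 1)
    cond = u - css / ind > 0
    k = ind[cond][-1]
    tau = css[k - 1] / k
    return np.maximum(v - tau, 0.0)


def dro_risk(
    risks: GroupRiskVector | np.ndarray,
    spec: UncertaintySetSpec | float,
    tol: float = 1e-12,
) -> tuple[float, np.ndarray]:
    """Worst-case weighted risk over the chi-square ball, with its argmax.

    Maximizes sum_i lambda_i f_i over {lambda on the simplex with
    ||lambda - u|| <= sqrt(rho/|G|)}.  The maximizer is the simplex
    projection of u + f/(2 mu) for the dual variable mu of the ball
    constraint, located by bisection; when the ball already contains a
    maximizing vertex the vertex is returned directly.
    """
    f = risks.risks if isinstance(risks, GroupRiskVector) else np.asarray(risks, float)
    rho = spec.rho if isinstance(spec, UncertaintySetSpec) else float(spec)
    if rho < 0:
        raise ValueError("rho must be >= 0")
    G = len(f)
    uni = np.full(G, 1.0 / G)
    if rho == 0 or G == 1 or np.ptp(f) < 1e-15:
        return float(f.mean()), uni
    r = ball_radius_euclidean(G, rho)
    # vertex of a maximizing coordinate: feasible iff the ball covers it
    j = int(np.argmax(f))
    vertex = np.zeros(G)
    vertex[j] = 1.0
    if np.linalg.norm(vertex - uni) <= r:
        return float(f[j]), vertex
    # bisection on the ball's dual variable mu > 0
    def lam(mu: float) -> np.ndarray:
        return project_to_simplex(uni + f / (2.0 * mu))

    def excess(mu: float) -> float:
        return float(np.linalg.norm(lam(mu) - uni)) - r

    lo, hi = 1e-12, 1.0
    while excess(hi) > 0:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - f is bounded, cannot trigger
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    best = lam(hi)
    return float(f @ best), best
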