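"""Exponentiated weight updates and projection onto the radius-constrained simplex.

The weight player maximizes the weighted group risk by mirror ascent
under the negative-entropy mirror map, whose proximal step has the
closed form lambda_i <- lambda_i * exp(gamma * v_i) (renormalized).
After each ascent step the weights are pulled back into the chi-square
uncertainty set by a Bregman (KL) projection, computed through the dual
of the ball constraint: the KKT system reduces to a Lambert-W expression
per coordinate, leaving two nested scalar bisections (simplex multiplier
inside, ball multiplier outside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .objectives import (
    WEIGHT_FLOOR,
    chi2_divergence,
    group_risks,
)
from .predictor import apply_update, init_predictor, weighted_loss_grad


def exponentiated_update(
    weights: np.ndarray, v: np.ndarray, gamma: float, scale: int = 1
) -> np.ndarray:
    """Multiplicative ascent step: lambda_i * exp(gamma * scale * v_i), renormalized.

    ``scale`` carries the local-iteration count E in the federated variant,
    where one server update stands in for E mirror steps.  Stabilized by
    subtracting the max exponent; entries floored at a tiny epsilon so no
    group is ever absorbed at zero.
    """
    w = np.asarray(weights, float)
    v = np.asarray(v, float)
    if w.shape != v.shape:
        raise ValueError("weights and losses must have equal length")
    if not np.isfinite(v).all():
        raise ValueError("loss vector contains non-finite entries")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    z = gamma * scale * v
    z = z - z.max()
    out = w * np.exp(z)
    out = out / out.sum()
    out = np.maximum(out, WEIGHT_FLOOR)
    return out / out.sum()


def _wexp(x: np.ndarray) -> np.ndarray:
    """W0(e^x): the y > 0 solving y + ln(y) = x, overflow-safe for large x.

    Newton on z = ln(y): h(z) = e^z + z - x is convex increasing, so the
    iteration is globally convergent; steps are clipped for safety.
    """
    x = np.asarray(x, float)
    z = np.where(x < 1.0, x - 1.0, np.log(np.maximum(x, 1.0)))
    for _ in range(40):
        ez = np.exp(np.clip(z, -745.0, 700.0))
        step = (ez + z - x) / (ez + 1.0)
        z = z - np.clip(step, -50.0, 50.0)
        if np.max(np.abs(step)) < 1e-15:
            break
    return np.exp(z)


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def _kl_ball_lambda(w: np.ndarray, uni: np.ndarray, mu: float) -> np.ndarray:
    """Minimizer of KL(lambda || w) + mu * ||lambda - u||^2 on the simplex.

    Stationarity gives 2 mu lambda_i = W0(exp(c_i + nu)) with
    c_i = ln(2 mu) + ln w_i - 1 + 2 mu u_i; the simplex multiplier nu
    solves sum(lambda) = 1 and is found by safeguarded Newton (the sum
    is strictly increasing in nu, with analytic derivative
    d lambda_i / d nu = t_i / ((1 + t_i) 2 mu) for t_i = 2 mu lambda_i).
    """
    two_mu = 2.0 * mu
    c = np.log(two_mu) + np.log(w) - 1.0 + two_mu * uni

    def t_of(nu: float) -> np.ndarray:
        return _wexp(c + nu)

    # small-t limit (t ~ e^{c+nu}) gives a good starting point
    nu = np.log(two_mu) - _logsumexp(c)
    lo, hi = -np.inf, np.inf
    for _ in range(80):
        t = t_of(nu)
        s = t.sum() / two_mu - 1.0
        if abs(s) < 1e-14:
            break
        if s > 0:
            hi = nu
        else:
            lo = nu
        ds = np.sum(t / (1.0 + t)) / two_mu
        step = s / max(ds, 1e-300)
        cand = nu - step
        if not (lo < cand < hi):  # Newton left the bracket: bisect instead
            if np.isfinite(lo) and np.isfinite(hi):
                cand = 0.5 * (lo + hi)
            else:
                cand = nu - np.sign(s) * max(1.0, abs(step) if np.isfinite(step) else 1.0)
        nu = cand
    lam = t_of(nu) / two_mu
    return lam / lam.sum()


def project_weights(weights: np.ndarray, rho: float) -> np.ndarray:
    """KL-closest point of the chi-square ball (radius rho) to ``weights``.

    Already-feasible inputs are returned unchanged; rho = 0 collapses to
    the uniform vector (the ball's only point).  Otherwise the projection
    min KL(lambda || weights) s.t. ||lambda - u||^2 <= rho/|G| is solved
    by bisection on the ball's dual variable, each dual evaluation being
    the Lambert-W inner solve above.  The output satisfies the radius
    constraint within 1e-7.
    """
    w = np.asarray(weights, float)
    if rho < 0:
        raise ValueError("rho must be >= 0")
    G = len(w)
    uni = np.full(G, 1.0 / G)
    if chi2_divergence(w) <= rho:
        return w.copy()
    if rho == 0:
        return uni.copy()
    w = np.maximum(w, WEIGHT_FLOOR)
    w = w / w.sum()
    r2 = rho / G

    def excess(log_mu: float) -> float:
        lam = _kl_ball_lambda(w, uni, np.exp(log_mu))
        return float(np.sum((lam - uni) ** 2)) - r2

    # bracket the ball's dual variable in log scale, then Brent
    lo, hi = 0.0, 0.0
    if excess(0.0) > 0:  # mu = 1 too weak a pull toward uniform
        hi = np.log(2.0)
        while excess(hi) > 0:
            lo, hi = hi, hi + np.log(4.0)
    else:
        lo = -np.log(2.0)
        while excess(lo) < 0:
            hi, lo = lo, lo - np.log(4.0)
            if lo < -700:
                break
    log_mu = brentq(excess, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    lam = _kl_ball_lambda(w, uni, np.exp(log_mu))
    lam = np.maximum(lam, WEIGHT_FLOOR)
    return lam / lam.sum()


@dataclass(frozen=True)
class SMDASchedule:
    """Centralized stochastic mirror descent ascent loop parameters."""

    T: int
    eta: float
    gamma: float
    batch_size: int = 32
    optimizer: str = "sgd"
    hidden_width: int = 64


def smda_run(
    features: np.ndarray,
    labels: np.ndarray,
    group_of_row: np.ndarray,
    n_groups: int,
    rho: float,
    schedule: SMDASchedule,
    seed: int,
    literal_weights: bool = False,
) -> tuple:
    """Centralized SMDA: alternate weighted descent on theta, mirror ascent on lambda.

    Each iteration samples a uniform minibatch, descends theta with
    per-sample multiplier |G| * lambda_g (so uniform weights reproduce
    plain training at the same stepsize; ``literal_weights`` restores the
    unscaled rule), then updates lambda by an exponentiated step on the
    current per-group losses followed by projection into the rho-ball.

    Returns (final PredictorState, final weights, trace DataFrame).
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels, int)
    group_of_row = np.asarray(group_of_row, int)
    n = len(labels)
    K = int(labels.max()) + 1
    root = np.random.SeedSequence([seed, 0x53DA])
    s_init, s_batch = root.spawn(2)
    state = init_predictor(
        features.shape[1], schedule.hidden_width, K,
        seed=int(s_init.generate_state(1)[0] % 2**31),
    )
    rng_batch = np.random.default_rng(s_batch)
    lam = np.full(n_groups, 1.0 / n_groups)
    rows = []
    for t in range(schedule.T):
        batch = rng_batch.integers(0, n, size=schedule.batch_size)
        mult = lam[group_of_row[batch]]
        if not literal_weights:
            mult = n_groups * mult
        loss, grad = weighted_loss_grad(
            state, features[batch], labels[batch], mult
        )
        state = apply_update(state, grad, schedule.eta, schedule.optimizer)
        v = group_risks(state, features, labels, group_of_row, n_groups).risks
        if schedule.gamma > 0:
            lam = project_weights(
                exponentiated_update(lam, v, schedule.gamma), rho
            )
        rows.append(
            {"iteration": t, "loss": loss}
            | {f"risk_{i}": v[i] for i in range(n_groups)}
            | {f"weight_{i}": lam[i] for i in range(n_groups)}
        )
    return state, lam, pd.DataFrame(rows)
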