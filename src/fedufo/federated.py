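"""Federated mirror descent ascent: the round loop, snapshot losses,
server aggregation and weight updates, plus FedAvg / local / centralized
baselines and the agnostic-distribution evaluation protocol.

Communication pattern per round: the server broadcasts the global model
and weights; each client runs E weighted minibatch iterations locally
and, on the *snapshot* (round-start) model, measures its full local loss
and per-attribute-subgroup losses; the server averages the returned
models and pushes the weight vectors through an exponentiated step
(exponent gamma * E, one server step standing in for E mirror steps)
followed by projection into the chi-square ball.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import partition_dirichlet
from .metrics import MetricsReport, evaluate_suite
from .mirror import exponentiated_update, project_weights
from .objectives import GroupWeights, UncertaintySetSpec
from .predictor import (
    PredictorState,
    apply_update,
    cross_entropy,
    init_predictor,
    weighted_loss_grad,
)
from .synth import Benchmark

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingSchedule:
    """Round structure and optimization hyperparameters.

    ``rounds`` (R) communications of ``local_iters`` (E) minibatch
    iterations each; total iteration budget T = R * E.  ``local_epochs``
    is a convenience: when set, E = local_epochs * ceil(client_rows /
    batch_size) is resolved per run from the median client size.
    """

    rounds: int = 10
    local_iters: int = 30
    eta: float = 0.01
    gamma: float = 1.0
    batch_size: int = 32
    optimizer: str = "sgd"
    hidden_width: int = 64
    checkpoint_every: int = 5
    literal_weights: bool = False
    size_weighted_agg: bool = False

    def __post_init__(self) -> None:
        if min(self.rounds, self.batch_size) < 1 or self.local_iters < 0:
            raise ValueError("rounds and batch_size must be positive, local_iters >= 0")
        if self.eta <= 0 or self.gamma < 0:
            raise ValueError("eta must be > 0 and gamma >= 0")

    @property
    def total_iters(self) -> int:
        return self.rounds * self.local_iters


@dataclass
class FederatedRunResult:
    """Everything a finished run leaves behind."""

    final_state: PredictorState
    checkpoints: list[tuple[int, PredictorState]]
    weights: GroupWeights
    weights_history: list[GroupWeights]
    trace: pd.DataFrame
    config: dict
    seed: int
    accessed_rows: list[set] = field(default_factory=list)


def _client_streams(seed: int, n_clients: int, tag: int):
    """Independent per-client substreams so any component replays alone."""
    batch = [
        np.random.default_rng(np.random.SeedSequence([seed, tag, 0xBA, i]))
        for i in range(n_clients)
    ]
    beta = [
        np.random.default_rng(np.random.SeedSequence([seed, tag, 0xBE, i]))
        for i in range(n_clients)
    ]
    return batch, beta


def _snapshot_losses(
    state: PredictorState,
    features: np.ndarray,
    labels: np.ndarray,
    rows: np.ndarray,
    attr_of_row: np.ndarray | None,
    n_attr: int | None,
) -> tuple[float, np.ndarray | None]:
    """Client loss and per-subgroup losses of the round-start model."""
    ce = cross_entropy(state, features[rows], labels[rows])
    v_client = float(ce.mean())
    if attr_of_row is None:
        return v_client, None
    v_attr = np.full(n_attr, np.nan)
    local_attr = attr_of_row[rows]
    for k in range(n_attr):
        mask = local_attr == k
        if mask.any():
            v_attr[k] = float(ce[mask].mean())
    return v_client, v_attr


def local_update(
    broadcast: PredictorState,
    features: np.ndarray,
    labels: np.ndarray,
    rows: np.ndarray,
    schedule: TrainingSchedule,
    client_multiplier: float,
    attr_multipliers: np.ndarray | None,
    attr_of_row: np.ndarray | None,
    n_attr: int | None,
    beta: float,
    rng_batch: np.random.Generator,
    rng_beta: np.random.Generator,
) -> tuple[PredictorState, float, np.ndarray | None, set]:
    """E weighted iterations from the broadcast model, plus snapshot losses.

    Each sampled row's loss multiplier is the client weight with
    probability beta, else the weight of the row's attribute subgroup
    (Bernoulli per row per iteration; the endpoints beta in {0, 1} skip
    the draw entirely so the random stream stays comparable across
    methods).  Snapshot losses are measured on the *broadcast* model
    before any local step, which is what lets one communication carry
    the whole round's weight information.
    """
    if len(rows) == 0:
        raise ValueError("client has no training rows")
    v_client, v_attr = _snapshot_losses(
        broadcast, features, labels, rows, attr_of_row, n_attr
    )
    state = broadcast.copy()
    accessed: set = set()
    for _ in range(schedule.local_iters):
        idx = rng_batch.integers(0, len(rows), size=schedule.batch_size)
        sel = rows[idx]
        accessed.update(sel.tolist())
        if beta >= 1.0 or attr_multipliers is None:
            mult = np.full(len(sel), client_multiplier)
        elif beta <= 0.0:
            mult = attr_multipliers[attr_of_row[sel]]
        else:
            use_client = rng_beta.random(len(sel)) < beta
            mult = np.where(
                use_client, client_multiplier, attr_multipliers[attr_of_row[sel]]
            )
        loss, grad = weighted_loss_grad(state, features[sel], labels[sel], mult)
        state = apply_update(state, grad, schedule.eta, schedule.optimizer)
    return state, v_client, v_attr, accessed


def aggregate(
    states: list[PredictorState], sizes: list[int] | None = None
) -> PredictorState:
    """Parameter-wise mean of the client models (optionally size-weighted)."""
    if not states:
        raise ValueError("nothing to aggregate")
    ref = states[0]
    for s in states[1:]:
        for k in ref.params:
            if s.params[k].shape != ref.params[k].shape:
                raise ValueError("cannot aggregate models of different shapes")
    if sizes is None:
        w = np.full(len(states), 1.0 / len(states))
    else:
        w = np.asarray(sizes, float)
        w = w / w.sum()
    out = ref.copy()
    out.opt_m, out.opt_v = {}, {}
    for k in ref.params:
        out.params[k] = sum(wi * s.params[k] for wi, s in zip(w, states))
    return out


def server_update_weights(
    weights: GroupWeights,
    v_client: np.ndarray | None,
    v_attr_by_client: np.ndarray | None,
    gamma: float,
    E: int,
    rho: float,
) -> GroupWeights:
    """Exponentiated step (exponent gamma*E) then ball projection, per vector.

    Attribute losses are *summed* over clients in the exponent; a
    (client, subgroup) cell absent from a client's data contributes zero
    to its column sum (logged); an all-missing column is an error.
    """
    lam_c = weights.lambda_client
    lam_a = weights.lambda_attribute
    if v_client is not None and lam_c is not None:
        lam_c = project_weights(
            exponentiated_update(lam_c, np.asarray(v_client, float), gamma, E), rho
        )
    if v_attr_by_client is not None:
        if lam_a is None:
            raise ValueError("attribute losses supplied but no attribute weights")
        mat = np.asarray(v_attr_by_client, float)
        all_missing = np.isnan(mat).all(axis=0)
        if all_missing.any():
            raise ValueError(
                f"attribute subgroup(s) {np.flatnonzero(all_missing).tolist()} "
                "are missing on every client"
            )
        if np.isnan(mat).any():
            logger.debug(
                "%d empty (client, subgroup) cells contribute 0 to the exponent",
                int(np.isnan(mat).sum()),
            )
        colsum = np.nansum(mat, axis=0)
        lam_a = project_weights(exponentiated_update(lam_a, colsum, gamma, E), rho)
    return GroupWeights(
        lambda_client=lam_c,
        lambda_attribute=lam_a,
        rho=rho,
        level=weights.level,
    )


def _resolve_level(benchmark: Benchmark, spec: UncertaintySetSpec):
    """Per-level wiring: which weight vectors exist, what the attribute map is,
    and the effective Bernoulli mixing probability."""
    grouping = benchmark.groupings[spec.level]
    N = benchmark.train.n_clients
    if spec.level == "client":
        return N, None, None, 1.0, grouping
    if spec.level == "attribute":
        return N, grouping.group_of_row, grouping.n_groups, 0.0, grouping
    if spec.level == "multilevel":
        return (
            N,
            grouping.attribute_group_of_row,
            grouping.n_attribute_groups,
            spec.beta,
            grouping,
        )
    # agnostic: the occupied client x attribute cells act as the single
    # weight vector, reached through the attribute path (beta = 0)
    return N, grouping.group_of_row, grouping.n_groups, 0.0, grouping


def _run_rounds(
    benchmark: Benchmark,
    spec: UncertaintySetSpec | None,
    schedule: TrainingSchedule,
    seed: int,
    freeze_weights: bool,
) -> FederatedRunResult:
    """Shared Algorithm-1 loop; FedAvg is the frozen-uniform-weights case."""
    ds = benchmark.dataset
    features, labels = ds.features, ds.labels
    train_rows = benchmark.train.client_rows
    N = len(train_rows)
    if spec is None:
        spec = UncertaintySetSpec(level="client", rho=0.0)
    N_, attr_of_row, n_attr, beta, grouping = _resolve_level(benchmark, spec)
    use_client_vec = spec.level in ("client", "multilevel")
    use_attr_vec = attr_of_row is not None

    root = np.random.SeedSequence([seed, 0xFED])
    s_init = root.spawn(1)[0]
    state = init_predictor(
        ds.n_features, schedule.hidden_width, ds.n_classes,
        seed=int(s_init.generate_state(1)[0] % 2**31),
    )
    rng_batch, rng_beta = _client_streams(seed, N, 0xFED)

    weights = GroupWeights.uniform(
        N, n_attr if use_attr_vec else None, rho=spec.rho, level=spec.level
    )
    checkpoints: list[tuple[int, PredictorState]] = []
    weights_history = [weights]
    trace_rows = []
    accessed_rows: list[set] = [set() for _ in range(N)]

    for r in range(schedule.rounds):
        locals_, v_clients, v_attr_rows = [], [], []
        for i in range(N):
            if freeze_weights:
                c_mult = 1.0
                a_mults = None
            else:
                c_mult = (
                    weights.lambda_client[i]
                    if schedule.literal_weights
                    else N * weights.lambda_client[i]
                )
                if use_attr_vec:
                    a_mults = (
                        weights.lambda_attribute
                        if schedule.literal_weights
                        else n_attr * weights.lambda_attribute
                    )
                else:
                    a_mults = None
            local, v_c, v_a, accessed = local_update(
                state,
                features,
                labels,
                train_rows[i],
                schedule,
                c_mult,
                a_mults,
                attr_of_row,
                n_attr,
                beta if not freeze_weights else 1.0,
                rng_batch[i],
                rng_beta[i],
            )
            locals_.append(local)
            v_clients.append(v_c)
            v_attr_rows.append(v_a)
            accessed_rows[i] |= accessed
        sizes = [len(rw) for rw in train_rows] if schedule.size_weighted_agg else None
        state = aggregate(locals_, sizes)
        if not freeze_weights:
            weights = server_update_weights(
                weights,
                np.asarray(v_clients) if use_client_vec else None,
                np.vstack(v_attr_rows) if use_attr_vec else None,
                schedule.gamma,
                schedule.local_iters,
                spec.rho,
            )
            weights_history.append(weights)
        row = {"round": r, "mean_client_loss": float(np.mean(v_clients))}
        row |= {f"v_client_{i}": v_clients[i] for i in range(N)}
        row |= {f"lambda_client_{i}": weights.lambda_client[i] for i in range(N)}
        trace_rows.append(row)
        if (r + 1) % schedule.checkpoint_every == 0:
            checkpoints.append((r + 1, state.copy()))

    return FederatedRunResult(
        final_state=state,
        checkpoints=checkpoints,
        weights=weights,
        weights_history=weights_history,
        trace=pd.DataFrame(trace_rows),
        config={
            "method": "fedavg" if freeze_weights else "fedufo",
            "level": spec.level,
            "rho": spec.rho,
            "beta": spec.beta,
            "schedule": schedule.__dict__,
        },
        seed=seed,
        accessed_rows=accessed_rows,
    )


def run_fedufo(
    benchmark: Benchmark,
    spec: UncertaintySetSpec,
    schedule: TrainingSchedule,
    seed: int,
) -> FederatedRunResult:
    """The fair federated algorithm at the level named in ``spec``."""
    return _run_rounds(benchmark, spec, schedule, seed, freeze_weights=False)


def run_fedavg(
    benchmark: Benchmark, schedule: TrainingSchedule, seed: int
) -> FederatedRunResult:
    """Plain federated averaging: the same loop with frozen uniform weights."""
    return _run_rounds(benchmark, None, schedule, seed, freeze_weights=True)


def run_local(
    benchmark: Benchmark, schedule: TrainingSchedule, seed: int
) -> list[FederatedRunResult]:
    """Per-client training with no communication (R*E iterations each)."""
    ds = benchmark.dataset
    out = []
    rng_batch, rng_beta = _client_streams(seed, benchmark.train.n_clients, 0x10CA1)
    root = np.random.SeedSequence([seed, 0x10CA1])
    s_init = root.spawn(1)[0]
    init_seed = int(s_init.generate_state(1)[0] % 2**31)
    solo = TrainingSchedule(
        rounds=1,
        local_iters=schedule.total_iters,
        eta=schedule.eta,
        gamma=schedule.gamma,
        batch_size=schedule.batch_size,
        optimizer=schedule.optimizer,
        hidden_width=schedule.hidden_width,
        checkpoint_every=schedule.checkpoint_every,
    )
    for i, rows in enumerate(benchmark.train.client_rows):
        state = init_predictor(
            ds.n_features, schedule.hidden_width, ds.n_classes, seed=init_seed
        )
        local, v_c, _, accessed = local_update(
            state, ds.features, ds.labels, rows, solo,
            1.0, None, None, None, 1.0, rng_batch[i], rng_beta[i],
        )
        out.append(
            FederatedRunResult(
                final_state=local,
                checkpoints=[(schedule.rounds, local.copy())],
                weights=GroupWeights.uniform(1),
                weights_history=[],
                trace=pd.DataFrame([{"round": 0, "v_client_0": v_c}]),
                config={"method": "local", "client": i},
                seed=seed,
                accessed_rows=[accessed],
            )
        )
    return out


def run_centralized(
    benchmark: Benchmark, schedule: TrainingSchedule, seed: int
) -> FederatedRunResult:
    """Pooled training on the union of all clients' training rows."""
    ds = benchmark.dataset
    pooled = np.sort(np.concatenate(benchmark.train.client_rows))
    root = np.random.SeedSequence([seed, 0xCE27])
    s_init, s_batch = root.spawn(2)
    state = init_predictor(
        ds.n_features, schedule.hidden_width, ds.n_classes,
        seed=int(s_init.generate_state(1)[0] % 2**31),
    )
    rng = np.random.default_rng(s_batch)
    checkpoints = []
    trace_rows = []
    per_round = schedule.local_iters
    for r in range(schedule.rounds):
        for _ in range(per_round):
            idx = rng.integers(0, len(pooled), size=schedule.batch_size)
            sel = pooled[idx]
            loss, grad = weighted_loss_grad(
                state, ds.features[sel], ds.labels[sel], np.ones(len(sel))
            )
            state = apply_update(state, grad, schedule.eta, schedule.optimizer)
        pooled_loss = float(
            cross_entropy(state, ds.features[pooled], ds.labels[pooled]).mean()
        )
        trace_rows.append({"round": r, "pooled_loss": pooled_loss})
        if (r + 1) % schedule.checkpoint_every == 0:
            checkpoints.append((r + 1, state.copy()))
    return FederatedRunResult(
        final_state=state,
        checkpoints=checkpoints,
        weights=GroupWeights.uniform(1),
        weights_history=[],
        trace=pd.DataFrame(trace_rows),
        config={"method": "centralized", "schedule": schedule.__dict__},
        seed=seed,
    )


def select_checkpoint(
    result: FederatedRunResult,
    features: np.ndarray,
    labels: np.ndarray,
    rows: np.ndarray,
) -> PredictorState:
    """The stored checkpoint with the lowest pooled training loss (earliest tie)."""
    if not result.checkpoints:
        raise ValueError("run stored no checkpoints")
    losses = [
        float(cross_entropy(st, features[rows], labels[rows]).mean())
        for _, st in result.checkpoints
    ]
    return result.checkpoints[int(np.argmin(losses))][1]


def agnostic_evaluate(
    state: PredictorState,
    benchmark: Benchmark,
    alpha_eval: float,
    attribute_columns: list[str] | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Re-partition the held-out rows at a new heterogeneity and re-score.

    Simulates deployment to a federation whose client mix was never seen
    in training: the pooled test rows are re-assigned to clients by a
    fresh Dirichlet draw with concentration ``alpha_eval`` and the whole
    metric suite is recomputed on the new grouping.
    """
    if alpha_eval <= 0:
        raise ValueError("alpha_eval must be positive")
    ds = benchmark.dataset
    test_rows = np.sort(np.concatenate(benchmark.test.client_rows))
    new_part = partition_dirichlet(
        ds,
        benchmark.train.n_clients,
        alpha_eval,
        seed=seed,
        rows=test_rows,
    )
    cols = attribute_columns or benchmark.attribute_columns
    return evaluate_suite(state, ds, new_part.client_rows, cols)
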