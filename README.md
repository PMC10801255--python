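# fedufo

Fair federated learning over simulated clients: train one shared
classifier across hospitals (clients) that never exchange raw data,
while enforcing *uniform performance* across subpopulations — the
clients themselves, groups defined by a sensitive attribute, both at
once, or client × attribute cells that stand in for deployment sites
never seen in training.

The package is aimed at researchers in clinical risk prediction and
federated/fair machine learning who want a small, fully reproducible
simulation: a synthetic clinical-tabular benchmark generator with
controllable non-IID client skew and attribute shift, the robust
training algorithm, the FedAvg / local / centralized baselines, and the
fairness evaluation suite, all behind one library and CLI.

## The objective

Plain federated averaging minimizes the pooled empirical risk and
routinely serves some clients or demographic groups much worse than
others. Here the trainer instead minimizes a group distributionally
robust risk: with per-group mean losses f_g(θ) over a grouping G,

    R_dro(θ) = max { Σ_g λ_g f_g(θ) : λ ∈ Δ^{|G|−1},
                     D_χ²(|G|·λ ‖ 1) ≤ ρ },

a worst-case reweighting of group risks over a χ²-divergence ball of
radius ρ around the uniform weighting. ρ = 0 is exactly empirical risk
minimization (FedAvg); ρ ≥ |G|² is worst-group minimization; in
between, ρ is the single dial trading overall accuracy against
fairness.

The saddle point is found by **federated mirror descent ascent**: each
round, clients run E locally weighted SGD iterations from the broadcast
model (each sampled row weighted by its group's current λ, scaled by
|G| so uniform weights reproduce FedAvg exactly) and report snapshot
losses measured on the round-start model; the server averages the local
models, pushes λ through a multiplicative (exponentiated-gradient) step
with exponent γ·E, and projects it back into the ρ-ball by a KL
(Bregman) projection. One upload per client per round.

Fairness is measured as **disparity** — the sample standard deviation
of per-group accuracy (smaller is fairer) — plus worst-group
accuracies, two harmonic combination rules for multilevel summaries,
and equal-opportunity / worst-TPR diagnostics for binary tasks.
`docs/methods.md` has the full model description, numerical choices,
and limitations.

## Worked example

Train the client-level robust model and FedAvg on the same synthetic
heterogeneous benchmark (4 clients, Dirichlet α = 0.1, one shifted
binary attribute) and score both on the held-out rows:

```python
import numpy as np
from fedufo import (SyntheticSpec, TrainingSchedule, UncertaintySetSpec,
                    evaluate_suite, make_benchmark, run_fedavg, run_fedufo,
                    select_checkpoint)

bm = make_benchmark(SyntheticSpec(seed=0))
sched = TrainingSchedule(rounds=10, local_iters=30, eta=0.05, gamma=1.0,
                         optimizer="sgd", checkpoint_every=5)
ds = bm.dataset
train_rows = np.concatenate(bm.train.client_rows)

for name, result in [
    ("FedUFO (client level, rho=0.1)",
     run_fedufo(bm, UncertaintySetSpec("client", rho=0.1), sched, seed=0)),
    ("FedAvg", run_fedavg(bm, sched, seed=0)),
]:
    model = select_checkpoint(result, ds.features, ds.labels, train_rows)
    rep = evaluate_suite(model, ds, bm.test.client_rows, bm.attribute_columns)
    print(f"--- {name}")
    print(rep.format_table())
```

prints

```
--- FedUFO (client level, rho=0.1)
overall accuracy                 0.7456
disparity over clients           0.0427
disparity over attributes        0.0058
harmonic disparity               0.0051
worst client accuracy            0.7037
worst attribute accuracy         0.7418
harmonic worst accuracy          0.7222
--- FedAvg
overall accuracy                 0.7406
disparity over clients           0.0499
disparity over attributes        0.0017
harmonic disparity               0.0017
worst client accuracy            0.6815
worst attribute accuracy         0.7394
harmonic worst accuracy          0.7092
```

On this seed the robust run cuts the spread of per-client accuracy
(disparity over clients 0.0427 vs 0.0499) and lifts the worst client by
two points (0.7037 vs 0.6815) at no cost in overall accuracy — the
qualitative pattern the method is built for. Attribute-level disparity
is not targeted by the client-level run and may move either way; choose
`level="attribute"`, `"multilevel"`, or `"agnostic"` in
`UncertaintySetSpec` to constrain other groupings.

The same experiment from the shell:

```
fedufo run --level client --rho 0.1 --optimizer sgd --eta 0.05 \
           --seed 0 --out runs/demo
fedufo sweep --rhos 1e-8,1e-4,1e-1 --seeds 0,1,2 --out runs/sweep
fedufo verify
```

`fedufo synth` writes a benchmark to disk, `fedufo evaluate` re-scores a
saved model (optionally after re-partitioning the held-out rows at a new
heterogeneity, the agnostic protocol), and `fedufo verify` recomputes
the frozen metric worked examples.

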