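# Methods

## Problem and model

`fedufo` simulates federated training of a tabular classifier across N
clients that never pool raw data, while enforcing *uniform performance*
over a configurable family of subpopulations. The base predictor is a
one-hidden-layer fully connected network (ReLU hidden layer, softmax
output, cross-entropy loss), the standard backbone for small clinical
tables. Fairness is phrased distributionally: instead of minimizing the
pooled empirical risk

    R(θ) = mean over samples of ℓ(θ; (x, y)),

the trainer minimizes the worst reweighting of per-group risks

    R_dro(θ) = max over λ ∈ Δ, D_f(|G|·λ ‖ 1) ≤ ρ  of  Σ_g λ_g f_g(θ),

where f_g is the mean loss of group g, Δ the probability simplex, and
the f-divergence ball (we fix f(t) = (t−1)², the χ² divergence) has
radius ρ around the uniform weighting. ρ = 0 recovers ordinary
empirical risk minimization; ρ → |G|² (large enough to contain every
vertex of the simplex) recovers worst-group minimization. This
objective upper-bounds the variance-penalized fairness risk
R̄ + C·Var(group risks)/|G| (also implemented, for diagnostics), with C
and ρ playing interchangeable roles; only ρ is exposed as the training
dial.

The group family G realizes the fairness level:

* **client** — the N clients themselves;
* **attribute** — observed value-combinations of named categorical
  columns (sex, race, an outcome flag, …);
* **multilevel** — both of the above simultaneously, mixed by a
  Bernoulli coefficient β per sampled row;
* **agnostic** — occupied (client × attribute-combination) cells, a
  deliberately wide family that hedges against deployment to client
  mixes never seen in training.

With the χ² generator, D_f(|G|·λ ‖ 1) = |G|·‖λ − u‖², so the
uncertainty set is the Euclidean ball of radius √(ρ/|G|) around the
uniform vector intersected with the simplex. This is what makes the
inner maximization and the projection tractable without a generic
convex solver.

## Optimization

**Centralized (SMDA).** The saddle point is approached by alternating
stochastic steps: descent on θ with per-sample weight |G|·λ_{g(sample)},
and mirror ascent on λ under the negative-entropy mirror map, whose
proximal step has the closed form λ_g ∝ λ_g·exp(γ·f_g), followed by
projection back into the ρ-ball.

**Federated (the round loop).** Per communication round the server
broadcasts (θ, λ); each client runs E weighted minibatch iterations and
measures, *on the round-start snapshot model*, its full local loss and
its per-attribute-subgroup losses; the server averages the returned
models parameter-wise and updates the weights by one exponentiated step
with exponent γ·E (one server step standing in for the E mirror steps
the centralized algorithm would have taken), then projects. The
snapshot convention is what keeps communication at one upload per round:
weight gradients are evaluated at a common, already-broadcast iterate.
Attribute losses are *summed*, not averaged, over clients in the
exponent; a (client, subgroup) cell with no rows contributes zero and
is logged, and an all-empty subgroup is an error.

FedAvg is the identical loop with the weights frozen at uniform; local
training runs R·E iterations per client with no communication;
centralized training pools all training rows. Model selection follows
the checkpoint protocol: a checkpoint is stored every 5 rounds and the
one with the lowest pooled training loss is evaluated (earliest on
ties).

### Numerical choices

* **Weight rescaling.** The per-sample multiplier is |G|·λ_g rather
  than the literal λ_g, so that uniform weights multiply every gradient
  by exactly 1 and the ρ = 0 run reproduces FedAvg *bitwise* at the
  same stepsize (verified parameter-wise in the tests; group counts
  that are powers of two make |G|·(1/|G|) exact in floating point).
  `literal_weights=True` restores the unscaled rule.
* **DRO inner maximization.** Maximizing a linear function over
  ball ∩ simplex: if the ball contains a maximizing vertex, that vertex
  is returned; otherwise the maximizer is the simplex projection of
  u + f/(2μ) with the ball's dual variable μ located by bisection
  (monotone in μ). Agreement with an SLSQP/trust-constr oracle is ~1e−8.
* **Projection geometry.** Weights are pulled back into the ball by the
  Bregman (KL) projection consistent with the negative-entropy mirror
  map: min KL(λ‖λ̃) subject to the ball. The KKT system reduces to
  λ_i = W₀(exp(c_i + ν))/(2μ) per coordinate (Lambert W, computed by a
  safeguarded Newton iteration on z = ln y that never exponentiates
  large arguments), with the simplex multiplier ν solved by safeguarded
  Newton and the ball multiplier μ by Brent root-finding in log scale.
  Feasible inputs are returned unchanged; ρ = 0 returns uniform; the
  output satisfies the radius within 1e−7 and the projection is
  idempotent to ~1e−9.
* **Weight floor.** Entries are floored at 1e−12: a multiplicative
  update can never resurrect an exact zero, so zeros are forbidden.
* **Optimizer.** Plain SGD is the reference rule: the fairness
  mechanism works by *scaling* per-sample gradients, and SGD transmits
  that scale to the parameter update exactly. Adam is available
  (standard (0.9, 0.999, 1e−8) moments) but its per-parameter RMS
  normalization absorbs a uniform per-client multiplier almost
  completely, which mutes client-level reweighting; the synthetic
  experiments therefore default to SGD. This is a property of the
  update algebra, not a bug: weighted-loss methods compose cleanly with
  scale-equivariant optimizers only.
* **Hidden activation.** ReLU (configurable width, default 64; 256 is
  conventional for much larger tables). Initialization is
  Normal(0, 1/fan-in) weights with zero biases.
* **β endpoints.** β = 1 (client-only) and β = 0 (attribute-only) skip
  the Bernoulli draw entirely, so runs at the endpoints consume the
  same random streams as FedAvg and remain pairwise comparable.
* **Random streams.** One master seed fans out through named
  `SeedSequence` substreams (initialization, per-client batching,
  per-client β draws, partition, split), so any component replays
  independently and adding draws to one component cannot shift another.

## Evaluation metrics

*Disparity* is the sample standard deviation (ddof = 1) of per-group
accuracy — the dispersion of service quality; 0 is perfect uniformity.
Two-level summaries use two deliberately different combination rules,
both implemented and named separately because published usage fixes
them numerically: disparities combine by the reciprocal-sum inverse
1/(1/a + 1/b) (no factor 2), worst-case accuracies by the ordinary
harmonic mean 2/(1/a + 1/b). Overall accuracy is total-correct over
total-rows. For binary tasks with a binary sensitive attribute the
suite adds an equal-opportunity-style gap — by default the as-printed
convention conditioning on the *prediction*, |P(Y=1|Ŷ=1,A=0) −
P(Y=1|Ŷ=1,A=1)|, with a `standard` mode giving the textbook
|TPR₀ − TPR₁| — and the worst within-group true-positive rate.
Undefined conditionals (an empty conditioning cell) are reported as
missing, never as zero. `fedufo verify` recomputes a frozen table of
worked examples for these metrics against published benchmark values at
their printed precision.

The *agnostic evaluation protocol* re-partitions the held-out rows by a
fresh Dirichlet draw at a new concentration α_eval and recomputes the
whole suite, simulating deployment to a federation whose client mix was
never seen in training.

## Synthetic benchmark generator

No clinical tables ship with the package; the generator produces
structurally analogous ones. Rows are drawn i.i.d.: attribute values
from specified mixing proportions, labels from a uniform class prior,
features as class mean + attribute displacement + standard Gaussian
noise, with optional uniform label flips. Class means sit at the
vertices of a regular simplex scaled so every pairwise distance equals
`class_separation` exactly (needs d ≥ K−1); each attribute value adds a
fixed unit displacement vector (drawn once per seed) scaled by
`attribute_shift`, so some attribute groups are genuinely harder and
plain training shows non-trivial disparity. Client heterogeneity is
Dirichlet label skew: for each class, a proportion vector over clients
is drawn from the symmetric Dirichlet(α) and the class's rows are
allocated by largest-remainder rounding (ties broken by client index);
allocation is retried (up to 100 times) until every client has the
minimum row count. Per-client 80/20 train/test splits are stratified by
label where cells permit, with exact per-client totals.

Default study conditions — chosen once as a realistic, moderately
separable clinical-tabular analogue and then left alone — are n = 2000,
d = 12, K = 3, N = 4 clients, α = 0.1 (strong heterogeneity), one
balanced binary attribute, class separation 2.5 (pooled accuracy in the
mid-80s rather than saturated), attribute shift 1.5, label noise 0.05,
and a minimum of 10 rows per client so both split sides stay non-empty.
The experiment schedule is 10 communication rounds of E = 30 minibatch
iterations (≈ 5 epochs of a typical ~400-row client at batch 32),
SGD step 0.05, weight step γ = 1.0, checkpoints every 5 rounds.

What the generator does *not* emulate: real covariate semantics and
scales (ICD codes, monitor channels), correlated or missing features,
label noise that depends on group membership, client-specific feature
(rather than label) distributions, and sample sizes beyond a few
thousand. Passing tests on this benchmark therefore demonstrate that
the optimization machinery does what the theory says under controlled
heterogeneity — not that any particular clinical deployment will see
the same disparity reductions.

## Known limitations

* Single-process simulation only: no transport, stragglers, client
  sampling, compression, or secure aggregation.
* Server aggregation is the unweighted client mean by default (the
  literal specification of the round loop); `size_weighted_agg=True`
  gives the conventional n_i/n-weighted variant.
* Client-level fairness effects require a scale-equivariant optimizer
  (SGD); under Adam the client weighting is largely neutralized (see
  above).
* The quantitative correspondence between the variance-penalty constant
  C and the radius ρ is not implemented; ρ is the only dial.
* The χ² ball is the only uncertainty-set geometry provided.
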