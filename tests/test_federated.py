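import numpy as np
import pytest

from fedufo import (
    GroupWeights,
    SyntheticSpec,
    TrainingSchedule,
    UncertaintySetSpec,
    agnostic_evaluate,
    aggregate,
    chi2_divergence,
    evaluate_suite,
    exponentiated_update,
    init_predictor,
    make_benchmark,
    run_centralized,
    run_fedavg,
    run_fedufo,
    run_local,
    select_checkpoint,
    server_update_weights,
)
from fedufo.data import partition_dirichlet
from fedufo.federated import _client_streams, local_update
from fedufo.predictor import apply_update, cross_entropy, weighted_loss_grad

from .test_mirror import oracle_projection

FAST = TrainingSchedule(rounds=4, local_iters=8, eta=0.05, gamma=1.0,
                        batch_size=16, optimizer="sgd", checkpoint_every=2)


def _params_equal(a, b):
    return all(np.array_equal(a.params[k], b.params[k]) for k in a.params)


class TestLocalUpdate:
    @pytest.fixture()
    def setting(self, small_benchmark):
        ds = small_benchmark.dataset
        rows = small_benchmark.train.client_rows[0]
        state = init_predictor(ds.n_features, 16, ds.n_classes, seed=0)
        attr = small_benchmark.dataset.attributes["sex"]
        return ds, rows, state, attr

    def _run(self, ds, rows, state, attr, beta, c_mult, a_mults, seed=3, iters=5):
        sched = TrainingSchedule(rounds=1, local_iters=iters, eta=0.05,
                                 batch_size=8, optimizer="sgd")
        rb = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        rg = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        return local_update(state, ds.features, ds.labels, rows, sched,
                            c_mult, a_mults, attr, 2, beta, rb, rg)

    def test_beta_one_ignores_attribute_weights(self, setting):
        ds, rows, state, attr = setting
        out1, *_ = self._run(ds, rows, state, attr, 1.0, 1.3, np.array([9.0, 0.1]))
        out2, *_ = self._run(ds, rows, state, attr, 1.0, 1.3, np.array([0.5, 7.0]))
        assert _params_equal(out1, out2)

    def test_beta_zero_ignores_client_weight(self, setting):
        ds, rows, state, attr = setting
        out1, *_ = self._run(ds, rows, state, attr, 0.0, 99.0, np.array([1.1, 0.9]))
        out2, *_ = self._run(ds, rows, state, attr, 0.0, 0.01, np.array([1.1, 0.9]))
        assert _params_equal(out1, out2)

    def test_zero_iterations_returns_broadcast(self, setting):
        ds, rows, state, attr = setting
        out, v_c, v_a, _ = self._run(ds, rows, state, attr, 1.0, 1.0, None, iters=0)
        assert _params_equal(out, state)
        assert v_c == pytest.approx(
            float(cross_entropy(state, ds.features[rows], ds.labels[rows]).mean())
        )

    def test_snapshot_losses_do_not_depend_on_local_iterations(self, setting):
        # v is measured on the broadcast model, so varying E must not move it
        ds, rows, state, attr = setting
        _, v1, va1, _ = self._run(ds, rows, state, attr, 0.5, 1.0,
                                  np.array([1.0, 1.0]), iters=1)
        _, v5, va5, _ = self._run(ds, rows, state, attr, 0.5, 1.0,
                                  np.array([1.0, 1.0]), iters=5)
        assert v1 == v5
        assert np.array_equal(va1, va5, equal_nan=True)

    def test_accessed_rows_stay_inside_client(self, setting):
        ds, rows, state, attr = setting
        _, _, _, accessed = self._run(ds, rows, state, attr, 1.0, 1.0, None)
        assert accessed <= set(rows.tolist())

    def test_empty_client_rejected(self, setting):
        ds, _, state, attr = setting
        with pytest.raises(ValueError, match="no training rows"):
            self._run(ds, np.array([], int), state, attr, 1.0, 1.0, None)


class TestAggregate:
    def test_identical_models_average_to_themselves(self):
        s = init_predictor(3, 4, 2, seed=0)
        out = aggregate([s.copy(), s.copy(), s.copy()])
        for k in out.params:
            assert np.allclose(out.params[k], s.params[k], rtol=0, atol=1e-15)

    def test_opposite_models_cancel(self):
        a = init_predictor(3, 4, 2, seed=1)
        b = a.copy()
        for k in b.params:
            b.params[k] = -b.params[k]
        out = aggregate([a, b])
        assert all(np.allclose(v, 0) for v in out.params.values())

    def test_matches_elementwise_mean(self):
        states = [init_predictor(3, 4, 2, seed=s) for s in range(3)]
        out = aggregate(states)
        for k in out.params:
            mean = np.mean([s.params[k] for s in states], axis=0)
            assert np.allclose(out.params[k], mean, atol=1e-15)

    def test_size_weighting(self):
        a, b = init_predictor(2, 2, 2, seed=0), init_predictor(2, 2, 2, seed=5)
        out = aggregate([a, b], sizes=[3, 1])
        for k in out.params:
            assert np.allclose(
                out.params[k], 0.75 * a.params[k] + 0.25 * b.params[k]
            )


class TestServerUpdateWeights:
    def test_equal_losses_fix_weights(self):
        w = GroupWeights.uniform(3, 4, rho=0.5)
        out = server_update_weights(
            w, np.full(3, 0.4), np.tile([0.2, 0.2, 0.2, 0.2], (3, 1)),
            gamma=1.0, E=5, rho=0.5,
        )
        assert np.allclose(out.lambda_client, 1 / 3)
        assert np.allclose(out.lambda_attribute, 1 / 4)

    def test_zero_gamma_fixes_weights(self, rng):
        w = GroupWeights.uniform(4, rho=0.2)
        out = server_update_weights(w, rng.random(4), None, gamma=0.0, E=5, rho=0.2)
        assert np.allclose(out.lambda_client, 0.25)

    def test_matches_composition_with_solver_projection(self, rng):
        # server update == exponentiated step then projection, where the
        # projection is checked against the convex-solver oracle
        lam = rng.dirichlet(np.ones(4))
        lam /= lam.sum()
        v = rng.random(4)
        w = GroupWeights(lambda_client=lam, rho=0.05)
        out = server_update_weights(w, v, None, gamma=1.5, E=3, rho=0.05)
        tilde = exponentiated_update(lam, v, 1.5, scale=3)
        expected = (
            oracle_projection(tilde, 0.05)
            if chi2_divergence(tilde) > 0.05
            else tilde
        )
        assert np.abs(out.lambda_client - expected).max() < 1e-5

    def test_missing_cells_contribute_zero(self):
        w = GroupWeights.uniform(2, 2, rho=1.0)
        v_attr = np.array([[0.5, np.nan], [0.5, 1.0]])
        out = server_update_weights(w, np.array([0.1, 0.1]), v_attr,
                                    gamma=1.0, E=1, rho=1.0)
        tilde = exponentiated_update(np.array([0.5, 0.5]), np.array([1.0, 1.0]), 1.0)
        assert np.allclose(out.lambda_attribute, tilde)

    def test_all_missing_column_rejected(self):
        w = GroupWeights.uniform(2, 2, rho=1.0)
        v_attr = np.array([[0.5, np.nan], [0.5, np.nan]])
        with pytest.raises(ValueError, match="missing on every client"):
            server_update_weights(w, np.array([0.1, 0.1]), v_attr,
                                  gamma=1.0, E=1, rho=1.0)


class TestRunFedufo:
    def test_zero_radius_equals_fedavg_roundwise(self, small_benchmark):
        sched = TrainingSchedule(rounds=3, local_iters=6, eta=0.05, gamma=1.0,
                                 batch_size=16, optimizer="sgd", checkpoint_every=1)
        ufo = run_fedufo(small_benchmark, UncertaintySetSpec("client", 0.0),
                         sched, seed=9)
        avg = run_fedavg(small_benchmark, sched, seed=9)
        assert len(ufo.checkpoints) == len(avg.checkpoints) == 3
        for (ru, su), (ra, sa) in zip(ufo.checkpoints, avg.checkpoints):
            assert ru == ra
            assert _params_equal(su, sa)

    def test_single_client_fedavg_is_pooled_sgd(self):
        bm = make_benchmark(
            SyntheticSpec(n=200, d=5, K=2, n_clients=1, alpha=1.0, seed=2)
        )
        sched = TrainingSchedule(rounds=2, local_iters=5, eta=0.05,
                                 batch_size=8, optimizer="sgd", checkpoint_every=1)
        res = run_fedavg(bm, sched, seed=4)
        # oracle: plain pooled SGD replaying the same substreams
        ds = bm.dataset
        rows = bm.train.client_rows[0]
        root = np.random.SeedSequence([4, 0xFED])
        init_seed = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
        state = init_predictor(ds.n_features, sched.hidden_width,
                               ds.n_classes, seed=init_seed)
        rng_b = _client_streams(4, 1, 0xFED)[0][0]
        for _ in range(10):
            idx = rng_b.integers(0, len(rows), size=8)
            sel = rows[idx]
            _, grad = weighted_loss_grad(state, ds.features[sel], ds.labels[sel],
                                         np.ones(8))
            state = apply_update(state, grad, 0.05, "sgd")
        assert _params_equal(res.final_state, state)

    @pytest.mark.parametrize("level", ["client", "attribute", "multilevel", "agnostic"])
    def test_all_levels_run_and_weights_stay_feasible(self, small_benchmark, level):
        spec = UncertaintySetSpec(level, rho=0.2, beta=0.5)
        res = run_fedufo(small_benchmark, spec, FAST, seed=1)
        assert len(res.weights_history) == FAST.rounds + 1
        for w in res.weights_history:
            w.validate()
        assert res.trace.shape[0] == FAST.rounds

    def test_heterogeneous_fairness_beats_fedavg_majority(self):
        # strong heterogeneity: the robust reweighting should reduce client
        # disparity relative to FedAvg in most paired seeds
        sched = TrainingSchedule(rounds=10, local_iters=30, eta=0.05, gamma=1.0,
                                 optimizer="sgd", checkpoint_every=5)
        wins = 0
        for seed in range(5):
            bm = make_benchmark(SyntheticSpec(seed=seed))
            ds = bm.dataset
            tr = np.concatenate(bm.train.client_rows)
            ru = run_fedufo(bm, UncertaintySetSpec("client", 0.1), sched, seed)
            ra = run_fedavg(bm, sched, seed)
            mu = select_checkpoint(ru, ds.features, ds.labels, tr)
            ma = select_checkpoint(ra, ds.features, ds.labels, tr)
            du = evaluate_suite(mu, ds, bm.test.client_rows,
                                bm.attribute_columns).disparity_client
            da = evaluate_suite(ma, ds, bm.test.client_rows,
                                bm.attribute_columns).disparity_client
            wins += du < da
        assert wins >= 3

    def test_deterministic_given_seed(self, small_benchmark):
        a = run_fedufo(small_benchmark, UncertaintySetSpec("client", 0.1),
                       FAST, seed=7)
        b = run_fedufo(small_benchmark, UncertaintySetSpec("client", 0.1),
                       FAST, seed=7)
        assert _params_equal(a.final_state, b.final_state)
        assert np.array_equal(a.weights.lambda_client, b.weights.lambda_client)


class TestBaselines:
    def test_local_models_never_touch_other_clients(self, small_benchmark):
        results = run_local(small_benchmark, FAST, seed=3)
        for res, rows in zip(results, small_benchmark.train.client_rows):
            assert res.accessed_rows[0] <= set(rows.tolist())

    def test_centralized_trace_matches_pooled_oracle(self, small_benchmark):
        res = run_centralized(small_benchmark, FAST, seed=6)
        ds = small_benchmark.dataset
        pooled = np.sort(np.concatenate(small_benchmark.train.client_rows))
        root = np.random.SeedSequence([6, 0xCE27])
        s_init, s_batch = root.spawn(2)
        state = init_predictor(ds.n_features, FAST.hidden_width, ds.n_classes,
                               seed=int(s_init.generate_state(1)[0] % 2**31))
        rng = np.random.default_rng(s_batch)
        losses = []
        for _ in range(FAST.rounds):
            for _ in range(FAST.local_iters):
                idx = rng.integers(0, len(pooled), size=FAST.batch_size)
                sel = pooled[idx]
                _, grad = weighted_loss_grad(
                    state, ds.features[sel], ds.labels[sel],
                    np.ones(FAST.batch_size),
                )
                state = apply_update(state, grad, FAST.eta, "sgd")
            losses.append(float(
                cross_entropy(state, ds.features[pooled], ds.labels[pooled]).mean()
            ))
        assert np.allclose(res.trace["pooled_loss"].to_numpy(), losses)


class TestSelectCheckpoint:
    def test_single_checkpoint_returned(self, small_benchmark):
        res = run_fedavg(
            small_benchmark,
            TrainingSchedule(rounds=2, local_iters=4, eta=0.05,
                             optimizer="sgd", checkpoint_every=2),
            seed=0,
        )
        ds = small_benchmark.dataset
        rows = np.concatenate(small_benchmark.train.client_rows)
        assert len(res.checkpoints) == 1
        assert _params_equal(
            select_checkpoint(res, ds.features, ds.labels, rows),
            res.checkpoints[0][1],
        )

    def test_argmin_over_checkpoints(self, small_benchmark):
        res = run_fedavg(small_benchmark, FAST, seed=1)
        ds = small_benchmark.dataset
        rows = np.concatenate(small_benchmark.train.client_rows)
        losses = [
            float(cross_entropy(st, ds.features[rows], ds.labels[rows]).mean())
            for _, st in res.checkpoints
        ]
        chosen = select_checkpoint(res, ds.features, ds.labels, rows)
        assert _params_equal(chosen, res.checkpoints[int(np.argmin(losses))][1])


class TestAgnosticEvaluate:
    def test_deterministic_and_matches_manual_recount(self, small_benchmark):
        ds = small_benchmark.dataset
        state = init_predictor(ds.n_features, 16, ds.n_classes, seed=0)
        rep1 = agnostic_evaluate(state, small_benchmark, alpha_eval=0.5, seed=11)
        rep2 = agnostic_evaluate(state, small_benchmark, alpha_eval=0.5, seed=11)
        assert rep1.to_dict() == rep2.to_dict()
        # manual recount on the same repartition
        test_rows = np.sort(np.concatenate(small_benchmark.test.client_rows))
        part = partition_dirichlet(ds, small_benchmark.train.n_clients, 0.5,
                                   seed=11, rows=test_rows)
        manual = evaluate_suite(state, ds, part.client_rows,
                                small_benchmark.attribute_columns)
        assert rep1.client_accuracies == manual.client_accuracies
        assert rep1.overall_acc == manual.overall_acc

    def test_bad_alpha_rejected(self, small_benchmark):
        ds = small_benchmark.dataset
        state = init_predictor(ds.n_features, 16, ds.n_classes, seed=0)
        with pytest.raises(ValueError, match="alpha_eval"):
            agnostic_evaluate(state, small_benchmark, alpha_eval=0.0)
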