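import numpy as np
import pytest

from fedufo import SyntheticSpec, TrainingSchedule, make_benchmark

# Study conditions for the stochastic federated experiments: 4 clients at
# strong heterogeneity (alpha = 0.1) with a genuine attribute shift, trained
# with the literal weighted-SGD rule for 10 communications of 30 local
# minibatch iterations (~5 epochs of a typical client at batch 32).
STUDY_SCHEDULE = TrainingSchedule(
    rounds=10,
    local_iters=30,
    eta=0.05,
    gamma=1.0,
    batch_size=32,
    optimizer="sgd",
    checkpoint_every=5,
)


@pytest.fixture(scope="session")
def benchmark():
    """One default synthetic benchmark shared by read-only tests."""
    return make_benchmark(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_benchmark():
    """A small, mild-heterogeneity benchmark for fast federated runs."""
    return make_benchmark(
        SyntheticSpec(n=400, d=6, K=2, n_clients=2, alpha=5.0, seed=1)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
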