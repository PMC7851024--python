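import numpy as np
import pytest
from hypothesis import settings

import teushmm as tm

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_pair():
    return tm.make_toy_pair()


@pytest.fixture(scope="session")
def toy_sequences(toy_pair):
    """A small bundle of sequences from toy model 1 for training tests."""
    return tm.sample_hmm(toy_pair[0], length=60, n_sequences=30, seed=9)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick-to-train labeled cohort (4 patients, both classes)."""
    spec = tm.CohortSpec(
        n_patients=4, rois_per_patient_per_class=3, n_frames=64, seed=11
    )
    return tm.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_config():
    return tm.TrainConfig(n_states=3, alphabet_size=10, seed=11)


@pytest.fixture(scope="session")
def small_pair(small_cohort, small_config):
    return tm.train_pair(small_cohort, small_config)


def random_model(rng, n_states, n_symbols):
    """A random valid DiscreteHMM (rows renormalized)."""
    a = rng.random((n_states, n_states)) + 0.05
    b = rng.random((n_states, n_symbols)) + 0.05
    return tm.DiscreteHMM(
        n_states=n_states,
        n_symbols=n_symbols,
        transition=a / a.sum(axis=1, keepdims=True),
        emission=b / b.sum(axis=1, keepdims=True),
    )


def brute_force_loglik(model, symbols):
    """Exhaustive path-sum oracle for Pr(O | lambda), vectorized over paths."""
    import itertools

    o = np.asarray(symbols) - 1
    paths = np.array(
        list(itertools.product(range(model.n_states), repeat=o.size)), dtype=int
    )
    p = model.start[paths[:, 0]] * model.emission[paths[:, 0], o[0]]
    for i in range(1, o.size):
        p = p * model.transition[paths[:, i - 1], paths[:, i]]
        p = p * model.emission[paths[:, i], o[i]]
    return float(np.log(p.sum()))
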