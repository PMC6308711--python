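import numpy as np
import pytest

import vfinsole as vf


@pytest.fixture(scope="session")
def geometry():
    return vf.AreaGeometry()


@pytest.fixture(scope="session")
def short_trials():
    """One short trial per task, shared across tests that only read them."""
    return [vf.simulate_trial(task, 12.0, seed=i) for i, task in enumerate(vf.TASKS)]


@pytest.fixture(scope="session")
def small_model(short_trials):
    """A quickly trained model (reduced widths) for pipeline-level tests."""
    X, Y, _ = vf.make_training_set(short_trials, 2500, seed=0)
    return vf.VfaModel.train(
        X,
        Y,
        force_spec=vf.RegressorSpec(n_hidden=6, seed=0, max_epochs=150),
        coord_spec=vf.RegressorSpec(n_hidden=20, seed=0, max_epochs=150),
    )


@pytest.fixture(scope="session")
def noise_free_model():
    """Model trained on noise-free trials: zero input implies zero force."""
    params = vf.SimulatorParams(noise_frac=0.0)
    trials = [
        vf.simulate_trial(task, 25.0, seed=i, params=params)
        for i, task in enumerate(vf.TASKS)
    ]
    X, Y, _ = vf.make_training_set(trials, 5000, seed=0)
    return vf.VfaModel.train(
        X,
        Y,
        force_spec=vf.RegressorSpec(n_hidden=10, seed=0),
        coord_spec=vf.RegressorSpec(n_hidden=20, seed=0, max_epochs=150),
    )


@pytest.fixture(scope="session")
def trained_bundle():
    """The full-size study model: 15,000 balanced frames, widths 10/200.

    Session-scoped because training all 18 regressors is the expensive part
    of the suite; every test that needs the trained estimator shares it.
    """
    trials = [vf.simulate_trial(task, 70.0, seed=i) for i, task in enumerate(vf.TASKS)]
    X, Y, _ = vf.make_training_set(trials, 15000, seed=0)
    model = vf.VfaModel.train(
        X,
        Y,
        force_spec=vf.RegressorSpec(n_hidden=10, seed=0),
        coord_spec=vf.RegressorSpec(n_hidden=200, seed=0, max_epochs=300),
    )
    return model


@pytest.fixture(scope="session")
def heldout_trials():
    """Evaluation trials never seen in training (different seeds)."""
    return [
        vf.simulate_trial(task, 25.0, seed=100 + i)
        for i, task in enumerate(vf.TASKS)
    ]


@pytest.fixture(scope="session")
def evaluation_report(trained_bundle, heldout_trials):
    return vf.evaluate_suite(trained_bundle, heldout_trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
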