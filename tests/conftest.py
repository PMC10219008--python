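import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TOY_SEED = 7


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """One full end-to-end experiment (corpus -> train -> TMTF -> compare ->
    neurophysiology), shared across the tests that inspect its artifacts."""
    from modsense.pipeline import RunConfig, run_experiment

    out = tmp_path_factory.mktemp("toy_run")
    return run_experiment(RunConfig(out_dir=str(out), seed=TOY_SEED, n_trials=16))


@pytest.fixture(scope="session")
def toy_model(toy_run):
    """The frozen recognizer trained during the shared end-to-end run."""
    from modsense.model import DilatedConvNet

    return DilatedConvNet.load(toy_run / "checkpoint.npz")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
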