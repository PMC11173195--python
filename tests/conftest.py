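import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from socialmap import dataprep, synth
from socialmap.volume import default_grid

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def concept_set():
    return synth.make_concept_set()


@pytest.fixture(scope="session")
def grid12():
    return default_grid(12)


@pytest.fixture(scope="session")
def embeddings_small(concept_set):
    """Small, strongly class-structured embedding matrix (width 16, 4 tokens)."""
    return synth.simulate_embeddings(
        concept_set, max_tokens=4, width=16, class_effect=4.0, seed=11
    )


@pytest.fixture(scope="session")
def signal_spec(grid12, concept_set, embeddings_small):
    """Ground truth with implanted affect/desirability/RSA regions."""
    return synth.make_signal_spec(
        grid12,
        concept_set,
        seed=5,
        effect_scale=3.0,
        noise_sd=1.0,
        roi_radius_mm=4.0,
        embeddings=embeddings_small,
    )


@pytest.fixture(scope="session")
def example_set(grid12, concept_set, signal_spec):
    """Prepared examples from one 2-run simulated subject with signal."""
    runs, schedule = synth.simulate_subject(
        concept_set, grid=grid12, spec=signal_spec, n_runs=2, seed=7
    )
    return dataprep.prepare_examples(runs, schedule)


@pytest.fixture(scope="session")
def null_example_set(grid12, concept_set):
    """Examples from a pure-noise (zero effect) subject."""
    spec = synth.SignalSpec(rois=[], effect_scale=0.0, noise_sd=1.0)
    runs, schedule = synth.simulate_subject(
        concept_set, grid=grid12, spec=spec, n_runs=2, seed=13
    )
    return dataprep.prepare_examples(runs, schedule)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
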