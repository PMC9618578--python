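import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small paired bulk/single-cell dataset with planted truth."""
    from scxfer.synthetic import generate

    return generate(n_lines=150, n_cells=150, n_genes=300, n_sig=20, seed=7)


@pytest.fixture(scope="session")
def tiny_bundle():
    """A compact untrained model for shape/contract tests."""
    from scxfer.networks import NetConfig, build_bundle

    cfg = NetConfig(
        n_genes=40,
        encoder_hidden=[16],
        bottleneck_dim=8,
        predictor_hidden=[8],
        dropout=0.0,
        noise_prob_bulk=0.0,
        noise_prob_sc=0.0,
    )
    return build_bundle(cfg, seed=3)


@pytest.fixture(scope="session")
def trained_small_model():
    """A model trained on the desk benchmark (seed 0), with its data."""
    from scxfer.bench import run_desk_benchmark

    return run_desk_benchmark(seed=0)
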