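import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("sidls", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("sidls")

from sidls import SecretomeKinetics, SimulationConfig, make_toy_fixture, simulate_secretome
from sidls.model import PipelineConfig


@pytest.fixture(scope="session")
def toy():
    """Hand-enumerated miniature evidence table with expected outcomes."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def toy_results(toy):
    evidence, signalp, _ = toy
    return SecretomeKinetics.from_frames(evidence, signalp).fit()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic secretome (50/50/5, fixed seed)."""
    cfg = SimulationConfig(seed=1234)
    evidence, signalp, truth = simulate_secretome(cfg)
    return cfg, evidence, signalp, truth


@pytest.fixture(scope="session")
def default_sim_results(default_sim):
    _, evidence, signalp, truth = default_sim
    res = SecretomeKinetics.from_frames(
        evidence, signalp, config=PipelineConfig(cutoff_strategy="association")
    ).fit()
    return res, truth
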