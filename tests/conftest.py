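import numpy as np
import pytest

from openmsm import (
    PipelineConfig,
    ToyComplexSpec,
    build_fixture,
    build_toy_complex,
    run_pipeline,
    simulate_latent,
)


@pytest.fixture(scope="session")
def popc_fixture():
    return build_fixture("popc", 1.0)


@pytest.fixture(scope="session")
def pops_fixture():
    return build_fixture("pops", 1.0)


@pytest.fixture(scope="session")
def small_latents(popc_fixture):
    """A modest POPC dataset reused by several estimator tests."""
    return simulate_latent(popc_fixture, n_frames=5000, n_traj=10, seed=42)


@pytest.fixture(scope="session")
def toy_complex():
    spec = ToyComplexSpec(fab_size=12)
    return build_toy_complex(spec, seed=3)


@pytest.fixture(scope="session")
def popc_run():
    """Full-scale POPC pipeline run shared by the recovery tests."""
    cfg = PipelineConfig(fixture="popc", n_traj=50, n_frames=20_000, seed=1, k_microstates=50)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def pops_run():
    """Full-scale POPC:POPS pipeline run shared by the recovery tests."""
    cfg = PipelineConfig(fixture="pops", n_traj=50, n_frames=20_000, seed=101, k_microstates=50)
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
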