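import numpy as np
import pytest

from metquant.imgio import PipelineConfig
from metquant.synthcell import SimConfig, simulate_field


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def highres_field():
    """One noiseless high-resolution field with puncta, shared across tests."""
    cfg = SimConfig.high_res(staining_stage_probs=(0.25, 0.25, 0.25, 0.25)).noiseless()
    stack, truth = simulate_field(cfg, 7)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def lowmag_field():
    """One noiseless low-magnification field (200 cells, METs, no puncta)."""
    cfg = SimConfig(n_cells=200).noiseless()
    stack, truth = simulate_field(cfg, 0)
    return cfg, stack, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
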