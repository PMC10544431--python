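import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from admixmr import PipelineConfig, SimulationConfig, simulate_case_control_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A compact study: enough SNPs/individuals to drive every stage."""
    return SimulationConfig(
        n_snps=1500,
        n_cases=500,
        n_controls=500,
        pool_size=8000,
        conf_anc_corr=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_sim_config):
    """(cohort, panels, true_freqs, catalog) reused across read-only tests."""
    return simulate_case_control_study(small_sim_config)


@pytest.fixture(scope="session")
def small_pipeline_config(small_sim_config) -> PipelineConfig:
    return PipelineConfig(simulation=small_sim_config, top_k=500, strata=())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
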