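import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def simulated_dataset(tmp_path_factory):
    """One shared two-condition synthetic dataset (strong vs weak termination)."""
    from riboterm.simulate import SimulationSpec, generate_dataset

    outdir = tmp_path_factory.mktemp("simdata")
    return generate_dataset(SimulationSpec(seed=7), outdir)


@pytest.fixture(scope="session")
def pipeline_result(simulated_dataset):
    from riboterm.config import PipelineConfig
    from riboterm.pipeline import run_pipeline

    ds = simulated_dataset
    return run_pipeline(
        PipelineConfig(),
        [ds.window],
        ds.sam_paths,
        ds.condition_map,
        make_plots=False,
    )
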