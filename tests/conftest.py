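import warnings

import pytest

from mirpair.pipeline import PipelineConfig, run_pipeline
from mirpair.synthetic import SimulationConfig, simulate_study

# the homoscedastic generator legitimately drives the moderated fit to its
# d0 = inf branch; silence that expected warning suite-wide
warnings.filterwarnings("ignore", message="moment estimate of d0 is non-positive")


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the default design, shared across tests."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A full pipeline run on the default simulated study."""
    outdir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(outdir=str(outdir), seed=1)
    manifest = run_pipeline(config)
    return config, manifest, outdir
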