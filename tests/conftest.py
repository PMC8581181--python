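import numpy as np
import pytest

from phenonet.pipeline import PipelineConfig, run_pipeline
from phenonet.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the generator's default study conditions."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_bundle():
    """Full end-to-end run at the default conditions (seed 1, 100 reps).

    Session-scoped: several tests interrogate different outputs of the same
    run.
    """
    return run_pipeline(PipelineConfig(seed=1, reps=100), write=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)



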