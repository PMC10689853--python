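import numpy as np
import pytest

from smkinetics import REFERENCE_CONFIGS, RunConfig, run_pipeline, simulate_dataset

#: Full-size analysis runs shared by the end-to-end recovery tests.  One run
#: per reference condition at a fixed seed; session-scoped because each takes
#: a few seconds.
_PIPELINE_SPECS = {
    "cfg_apo_wt": 2,
    "cfg_neca_wt": 3,
    "cfg_neca_wt_minigs": 3,
    "cfg_keq24": 2,
    "cfg_cam": 3,
}


@pytest.fixture(scope="session")
def pipeline_reports():
    reports = {}
    for name, n_states in _PIPELINE_SPECS.items():
        reports[name] = run_pipeline(
            RunConfig(source=name, n_states=n_states, seed=1, write_artifacts=False)
        )
    return reports


@pytest.fixture(scope="session")
def apo_dataset():
    """A moderate simulated apo-like dataset with ground truth attached."""
    return simulate_dataset(REFERENCE_CONFIGS["cfg_apo_wt"], seed=3, n_traces=120)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
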