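import numpy as np
import pytest

from thermoconn import edgenet, preprocess, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def recovery_design():
    """Default planted-effect study: 15 vs 17 subjects, 10 edges at |dz|=0.5."""
    edges = synthdata.default_altered_edges(n_edges=10, delta_z=0.5, seed=0)
    return synthdata.SimulationDesign(altered_edges=edges, seed=11)


def clean_connectivity(study_design, group, subject):
    """Simulate one subject and run the standard cleaning chain."""
    series = synthdata.simulate_regional_bold(study_design, group, subject)
    return edgenet.connectivity_matrix(preprocess.clean_series(series))


@pytest.fixture(scope="session")
def recovery_matrices(recovery_design):
    d = recovery_design
    return {
        "HT": [clean_connectivity(d, "HT", s) for s in range(d.n_ht)],
        "NC": [clean_connectivity(d, "NC", s) for s in range(d.n_nc)],
    }
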