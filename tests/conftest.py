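import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import flightlearn as fl
from flightlearn import cluster_perm

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def layout():
    return fl.load_layout()


@pytest.fixture(scope="session")
def adjacency(layout):
    return cluster_perm.build_adjacency(layout)


@pytest.fixture(scope="session")
def autopilot():
    return fl.autopilot_reference()


@pytest.fixture(scope="session")
def small_design():
    """A two-subjects-per-group miniature of the study design for fast tests."""
    return fl.StudyDesign(groups=(("DLPFC_stim", 2), ("DLPFC_sham", 2),
                                  ("M1_stim", 2), ("M1_sham", 2)),
                          n_days=4)


@pytest.fixture(scope="session")
def small_study(small_design):
    from flightlearn.synthetic_data import generate_study
    return generate_study(small_design, seed=7)
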