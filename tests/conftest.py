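import numpy as np
import pandas as pd
import pytest

import stoptask as st


@pytest.fixture(scope="session")
def design():
    return st.default_design()


@pytest.fixture(scope="session")
def schedule(design):
    return st.build_schedule(design, np.random.default_rng(0))


@pytest.fixture(scope="session")
def default_subject():
    """Control-group subject at the group-level default means."""
    return st.SubjectParams(
        subject_id="s001", group="control",
        go_mu=760.0, go_sigma=60.0, go_tau=100.0,
        proactive_gain=600.0, ssrt_true_mu=200.0, ssrt_true_sigma=30.0,
        p_miss_lapse=0.05, p_choice_error=0.02,
    )


@pytest.fixture(scope="session")
def subject_trials(default_subject, schedule, design):
    return st.simulate_subject(default_subject, schedule, np.random.default_rng(0), design)


@pytest.fixture(scope="session")
def cohort():
    """Study-sized cohort: 14 controls + 14 poker players, seed 0."""
    return st.simulate_cohort(14, seed=0)
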