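import warnings

import numpy as np
import pytest

import dmdgait as dg
from dmdgait.core_io import Activity, Group, Participant


@pytest.fixture()
def participant():
    return Participant(id="TD01", group=Group.TD, age=9.0, height=1.28,
                       weight=30.0, nsaa=34)


@pytest.fixture()
def clean_session(participant):
    """Noise-free 2 steps/s session, 10 s, known shares (0.4, 0.3, 0.3)."""
    params = dg.GaitParams(
        cadence=2.0, sl_fraction=0.4, axial_shares=(0.4, 0.3, 0.3),
        amp=2.0, noise_sd=0.0, duration=10.0,
    )
    sess, meta, truth = dg.generate_session(params, participant, Activity.SC_L3, seed=7)
    return sess, meta, truth


@pytest.fixture(scope="session")
def small_cohort():
    """3+3 participants, one activity — fast end-to-end fixture."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, truth = dg.generate_cohort(3, 3, [Activity.SC_L3], seed=11)
    return cohort, truth


@pytest.fixture(scope="session")
def contrast_table():
    """Feature table of a full 15+15 single-activity cohort."""
    cohort, _ = dg.generate_cohort(15, 15, [Activity.SC_L3], seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dg.build_feature_table(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
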