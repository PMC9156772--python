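import numpy as np
import pandas as pd
import pytest

from threatdetect.observer import ObserverParams, simulate_cohort
from threatdetect.schedule import DesignConfig, build_cohort, build_session
from threatdetect import sdt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def observer():
    return ObserverParams()


@pytest.fixture
def session():
    return build_session(DesignConfig(), seed=7, subject_id=0)


@pytest.fixture(scope="session")
def classified_cohort():
    """A 20-subject behavioural cohort with classified outcomes (no physio)."""
    frame = build_cohort(DesignConfig(), 20, seed=99)
    observers = [ObserverParams() for _ in range(20)]
    responses = simulate_cohort(observers, frame, np.random.default_rng(99))
    trials = pd.concat([frame, responses], axis=1)
    return sdt.classify_trials(trials)
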