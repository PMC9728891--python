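"""Shared fixtures: small synthetic configurations used across test modules."""

import numpy as np
import pandas as pd
import pytest

from neurodyn import synth
from neurodyn.core import RoiTimeSeriesSet

TR = 0.545


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fixed_rt_trials():
    """Three trials with fixed 12 s response times starting after a 10 s
    lead-in (onsets 10, 22, 34)."""
    return pd.DataFrame({
        "onset": [10.0, 22.0, 34.0],
        "duration": [12.0, 12.0, 12.0],
        "response": ["yes", "no", "yes"],
    })


@pytest.fixture
def small_design():
    return synth.StudyDesign(n_subjects=3, n_trials=6, tr=TR,
                             rt_mean_by_subject=(14.0, 18.0, 22.0),
                             rng_seed=7)


@pytest.fixture
def noise_free():
    return synth.NoiseSpec(white_sd=0.0, ar_coef=0.0, drift_amplitude=0.0)


def make_series(data, tr=TR, subject_id="sub-01"):
    data = np.asarray(data, dtype=float)
    return RoiTimeSeriesSet(subject_id, tuple(range(1, data.shape[0] + 1)),
                            data, tr)


@pytest.fixture
def make_series_fixture():
    return make_series
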