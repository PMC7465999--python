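"""Shared fixtures: one small simulated cohort, reused across modules."""

import warnings

import pytest

from cogload.features import extract_feature_table
from cogload.preprocessing import segment_windows
from cogload.synthetic import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_participants=2, seed=11)


@pytest.fixture(scope="session")
def session_pair(small_config):
    """(recording, ground truth) for one participant of the small cohort."""
    return simulate_session(small_config, "P01")


@pytest.fixture(scope="session")
def small_windows(small_config):
    windows = []
    for i in range(small_config.n_participants):
        rec, truth = simulate_session(small_config, f"P{i + 1:02d}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            windows.extend(segment_windows(rec, truth.event_list()))
    return windows


@pytest.fixture(scope="session")
def small_feature_table(small_windows):
    return extract_feature_table(small_windows)
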