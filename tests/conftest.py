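"""Shared fixtures: a reduced synthetic cohort so every stage is exercised
end to end without the cost of the full 65-subject geometry."""

from __future__ import annotations

import numpy as np
import pytest

import painconn as pc


@pytest.fixture(scope="session")
def small_cfg() -> pc.CohortConfig:
    """3 subjects, 2:4:4 initial trials balanced to 4 per class, short rests."""
    return pc.CohortConfig(n_subjects=3, np_trials_initial=2, lp_trials=4,
                           hp_trials=4, extra_np_trials=2, rest_duration=12.0,
                           seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    sessions, gt = pc.simulate_cohort(small_cfg)
    return sessions, gt


@pytest.fixture(scope="session")
def small_trials(small_cohort):
    sessions, _ = small_cohort
    trials = []
    for sess in sessions:
        trials.extend(pc.preprocess_and_segment(sess))
    return trials


@pytest.fixture(scope="session")
def hbo2_table(small_trials):
    return pc.features_for_dataset(small_trials, "hbo2")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
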