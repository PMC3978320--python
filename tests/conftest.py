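"""Shared fixtures: one trained model, one stimulus set, one default run.

All stage seeds derive from the package's default master seed (0) the
same way the reproduction pipeline derives them, so the fixtures
reproduce exactly what `reproduce(ModelConfig())` simulates.
"""

import warnings

import numpy as np
import pytest

from decicomp.config import ModelConfig, _stage_seeds
from decicomp.model import DecimalComparisonModel
from decicomp.stimuli import generate_stimulus_set

warnings.filterwarnings("ignore", category=RuntimeWarning)

TRAIN_SEED, STIM_SEED, SIM_SEED = _stage_seeds(ModelConfig().seed)


@pytest.fixture(scope="session")
def fitted():
    return DecimalComparisonModel().fit(seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def stimuli_440(fitted):
    pairs, violations = generate_stimulus_set(seed=STIM_SEED)
    assert violations == []
    return pairs


@pytest.fixture(scope="session")
def default_run(fitted, stimuli_440):
    return fitted.simulate(stimuli_440, n_participants=22, seed=SIM_SEED)


@pytest.fixture(scope="session")
def run_summary(default_run):
    return default_run.summarize()


@pytest.fixture(scope="session")
def mini_stimuli():
    from decicomp.stimuli import miniature_set

    return miniature_set(seed=5)
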