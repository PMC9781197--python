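"""Shared fixtures: default configs and a detector trained once per session."""

from dataclasses import replace

import numpy as np
import pytest

from p300home import (
    DetectorConfig,
    ParadigmConfig,
    PreprocConfig,
    SimulationConfig,
    make_schedule,
    simulate_recording,
    train_detector,
)
from p300home.decode import score_epochs, select_symbol
from p300home.preprocess import bandpass, extract_epochs
from p300home.sessions import training_epochs


@pytest.fixture(scope="session")
def paradigm():
    return ParadigmConfig()


@pytest.fixture(scope="session")
def secondary_paradigm():
    return ParadigmConfig.secondary()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def preproc():
    return PreprocConfig()


@pytest.fixture(scope="session")
def default_model(paradigm, sim_config, preproc):
    """Random forest trained on a simulated 10-selection training session."""
    epochs = training_epochs(paradigm, sim_config, preproc, rng=1, n_selections=10)
    return train_detector(epochs, DetectorConfig(seed=1))


def decode_trials(
    model,
    paradigm,
    sim_config,
    preproc,
    n_trials,
    seed,
    repetition_counts=(15,),
):
    """Decode fresh simulated selections, reusing each trial's epoch scores
    across several aggregation depths.

    Returns a (n_trials, len(repetition_counts)) boolean correctness array.
    """
    rng = np.random.default_rng(seed)
    correct = np.zeros((n_trials, len(repetition_counts)), dtype=bool)
    for i in range(n_trials):
        target = int(rng.integers(paradigm.n_symbols))
        schedule = make_schedule(paradigm, rng)
        rec = simulate_recording(schedule, target, sim_config, rng)
        epochs = extract_epochs(bandpass(rec, preproc), preproc)
        scores = score_epochs(model, epochs)
        for j, r in enumerate(repetition_counts):
            res = select_symbol(scores, epochs, r, true_symbol=target)
            correct[i, j] = res.correct
    return correct
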