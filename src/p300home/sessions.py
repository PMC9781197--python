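"""Simulated experimental sessions mirroring the study protocol.

Each simulated subject attends a training session (10 selections, all
epochs labeled) and a test session (fresh selections, decoded with the
trained detector: 20 on the primary appliance display and 20 on the
secondary numbers display).  Subjects differ by random seed and,
optionally, by a subject-specific noise level, standing in for the
human participants the method was designed for.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .decode import DetectorConfig, DetectorModel, run_trial, train_detector
from .paradigm import ParadigmConfig, make_schedule
from .preprocess import EpochSet, PreprocConfig, bandpass, extract_epochs
from .simulate import SimulationConfig, simulate_recording

__all__ = [
    "concat_epochs",
    "training_epochs",
    "run_test_session",
    "simulate_subject",
]


def concat_epochs(epoch_sets: list[EpochSet]) -> EpochSet:
    """Stack epoch sets from several selections into one training set."""
    if not epoch_sets:
        raise ValueError("nothing to concatenate")
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if (es.n_channels, es.samples_per_epoch) != (first.n_channels, first.samples_per_epoch):
            raise ValueError("epoch sets have incompatible shapes")
    return EpochSet(
        features=np.vstack([es.features for es in epoch_sets]),
        labels=np.concatenate([es.labels for es in epoch_sets]),
        symbol_indices=np.concatenate([es.symbol_indices for es in epoch_sets]),
        block_indices=np.concatenate([es.block_indices for es in epoch_sets]),
        n_channels=first.n_channels,
        samples_per_epoch=first.samples_per_epoch,
        sampling_rate=first.sampling_rate,
        channel_names=first.channel_names,
    )


def _one_selection_epochs(
    paradigm: ParadigmConfig,
    sim: SimulationConfig,
    preproc: PreprocConfig,
    rng: np.random.Generator,
    target: int | None = None,
) -> EpochSet:
    if target is None:
        target = int(rng.integers(paradigm.n_symbols))
    schedule = make_schedule(paradigm, rng)
    rec = simulate_recording(schedule, target, sim, rng)
    return extract_epochs(bandpass(rec, preproc), preproc)


def training_epochs(
    paradigm: ParadigmConfig,
    sim: SimulationConfig,
    preproc: PreprocConfig,
    rng: np.random.Generator | int | None = None,
    n_selections: int = 10,
) -> EpochSet:
    """Simulate a training session and pool all its labeled epochs."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return concat_epochs(
        [_one_selection_epochs(paradigm, sim, preproc, rng) for _ in range(n_selections)]
    )


def run_test_session(
    model: DetectorModel,
    paradigm: ParadigmConfig,
    sim: SimulationConfig,
    preproc: PreprocConfig,
    rng: np.random.Generator | int | None = None,
    n_selections: int = 20,
    n_repetitions_used: int | None = None,
):
    """Decode ``n_selections`` fresh simulated selections; return results."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    results = []
    for _ in range(n_selections):
        target = int(rng.integers(paradigm.n_symbols))
        schedule = make_schedule(paradigm, rng)
        rec = simulate_recording(schedule, target, sim, rng)
        results.append(run_trial(rec, preproc, model, n_repetitions_used))
    return results


def simulate_subject(
    seed: int,
    sim: SimulationConfig | None = None,
    preproc: PreprocConfig | None = None,
    detector: DetectorConfig | None = None,
    n_train: int = 10,
    n_test: int = 20,
):
    """One simulated participant: train once, test on both displays.

    Returns ``(primary_results, secondary_results)`` with ``n_test``
    decoded selections each.  The detector is trained on primary-display
    epochs only, as a user would calibrate once.
    """
    sim = sim or SimulationConfig()
    preproc = preproc or PreprocConfig()
    detector = detector or DetectorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    primary = ParadigmConfig()
    secondary = ParadigmConfig.secondary()
    train = training_epochs(primary, sim, preproc, rng, n_selections=n_train)
    model = train_detector(train, replace(detector, seed=seed))
    prim = run_test_session(model, primary, sim, preproc, rng, n_selections=n_test)
    sec = run_test_session(model, secondary, sim, preproc, rng, n_selections=n_test)
    return prim, sec
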